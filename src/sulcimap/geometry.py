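"""Electrode-grid geometry and central-sulcus ground-truth annotations.

Coordinate convention: positions are in millimetres on the cortical surface
plane, ``x`` increasing anterior -> posterior and ``y`` increasing
medial -> lateral.  Channels are indexed row-major: ``index = row * cols +
col`` where the row index runs medial -> lateral (along ``y``) and the
column index runs anterior -> posterior (along ``x``).  The central sulcus
(CS) is a straight line in this plane; channels with ``x`` smaller than the
line's ``x`` at their ``y`` are *anterior* (precentral / M1), the rest
*posterior* (postcentral / S1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "make_grid_geometry"]


@dataclass
class GridGeometry:
    """Electrode positions plus the annotated CS line.

    Attributes
    ----------
    rows, cols : int
        Grid extent; rows run medial->lateral, columns anterior->posterior.
    spacing_mm : float
        Electrode pitch.
    positions_mm : ndarray, shape (n_channels, 2)
        ``(x, y)`` per channel, row-major channel order.
    cs_line : ndarray, shape (>=2, 2)
        Polyline of the central sulcus in the same coordinates.
    region_labels : ndarray of str, shape (n_channels,)
        ``"anterior"`` / ``"posterior"`` / ``"excluded"`` per channel.
    """

    rows: int
    cols: int
    spacing_mm: float
    positions_mm: np.ndarray
    cs_line: np.ndarray
    region_labels: np.ndarray
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.cs_line = np.asarray(self.cs_line, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        n = self.rows * self.cols
        if self.positions_mm.shape != (n, 2):
            raise ValueError(
                f"positions_mm must have shape ({n}, 2), got {self.positions_mm.shape}"
            )
        if len(self.region_labels) != n:
            raise ValueError("region_labels must cover every channel")
        bad = set(self.region_labels) - {"anterior", "posterior", "excluded"}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(n)]

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def ap_strips(self, width: int = 1) -> list[np.ndarray]:
        """Channel-index subsets forming width x N strips along the AP axis.

        ``width=1`` yields every single medial-lateral row (a 1 x cols strip
        running anterior->posterior); ``width=2`` yields every adjacent row
        pair (2 x cols).
        """
        if width < 1 or width > self.rows:
            raise ValueError("width must be in [1, rows]")
        strips = []
        for r0 in range(self.rows - width + 1):
            idx = [
                self.channel_index(r, c)
                for r in range(r0, r0 + width)
                for c in range(self.cols)
            ]
            strips.append(np.array(idx, dtype=int))
        return strips

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "spacing_mm": self.spacing_mm,
            "positions_mm": self.positions_mm.tolist(),
            "cs_line": self.cs_line.tolist(),
            "region_labels": list(self.region_labels),
            "channel_ids": list(self.channel_ids),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            spacing_mm=float(d["spacing_mm"]),
            positions_mm=np.asarray(d["positions_mm"], dtype=float),
            cs_line=np.asarray(d["cs_line"], dtype=float),
            region_labels=np.asarray(d["region_labels"], dtype=object),
            channel_ids=list(d.get("channel_ids", [])),
        )

    @classmethod
    def from_json(cls, path) -> "GridGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def cs_line_x(y: np.ndarray, cs_offset_mm: float, cs_angle_deg: float,
              y_center: float) -> np.ndarray:
    """AP position of the CS line at medial-lateral position ``y``.

    The line passes through ``(cs_offset_mm, y_center)`` and is tilted by
    ``cs_angle_deg`` away from the medial-lateral axis.
    """
    return cs_offset_mm + math.tan(math.radians(cs_angle_deg)) * (
        np.asarray(y, dtype=float) - y_center
    )


def make_grid_geometry(rows: int, cols: int, spacing_mm: float,
                       cs_offset_mm: float, cs_angle_deg: float = 0.0) -> GridGeometry:
    """Build a regular grid and label channels by their side of the CS line."""
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one row and one column")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc.ravel() * spacing_mm          # anterior -> posterior
    y = rr.ravel() * spacing_mm          # medial -> lateral
    positions = np.column_stack([x, y])
    y_center = (rows - 1) * spacing_mm / 2.0
    x_at = cs_line_x(y, cs_offset_mm, cs_angle_deg, y_center)
    labels = np.where(x < x_at, "anterior", "posterior").astype(object)
    # polyline extended slightly beyond the grid for plotting
    y_lo, y_hi = -spacing_mm / 2.0, (rows - 0.5) * spacing_mm
    line = np.array(
        [
            [cs_line_x(y_lo, cs_offset_mm, cs_angle_deg, y_center), y_lo],
            [cs_line_x(y_hi, cs_offset_mm, cs_angle_deg, y_center), y_hi],
        ]
    )
    return GridGeometry(rows, cols, spacing_mm, positions, line, labels)
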