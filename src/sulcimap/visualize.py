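"""Spatial rendering of SSEP fields and clustering output on the grid.

Heat maps use Sibson natural-neighbor interpolation: when a query point is
inserted into the Voronoi diagram of the electrodes, its new cell "steals"
area from the cells of nearby electrodes, and the stolen fractions are the
interpolation weights.  The interpolant is exact at the electrodes, has
linear precision inside the convex hull, and is smooth — the "smooth
transition" wanted for spatial SSEP maps.  Cells are convex, so all the
geometry reduces to half-plane clipping of convex polygons (pure numpy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .cluster import ClusterResult
from .geometry import GridGeometry
from .preprocess import SSEPTrace
from .simulate import GroundTruth

__all__ = [
    "HeatMapFrame",
    "natural_neighbor",
    "heatmap_frame",
    "animate",
    "plot_heatmap",
    "save_animation",
    "cluster_map",
]


# ---------------------------------------------------------------------------
# convex polygon machinery


def _clip_halfplane(verts: np.ndarray, m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Clip a convex polygon to the half-plane {p : (p - m) . n <= 0}."""
    if len(verts) == 0:
        return verts
    d = (verts - m) @ n
    if np.all(d <= 0):
        return verts
    out = []
    k = len(verts)
    for i in range(k):
        j = (i + 1) % k
        if d[i] <= 0:
            out.append(verts[i])
            if d[j] > 0:
                t = d[i] / (d[i] - d[j])
                out.append(verts[i] + t * (verts[j] - verts[i]))
        elif d[j] <= 0:
            t = d[i] / (d[i] - d[j])
            out.append(verts[i] + t * (verts[j] - verts[i]))
    return np.asarray(out) if out else np.empty((0, 2))


def _poly_area(verts: np.ndarray) -> float:
    if len(verts) < 3:
        return 0.0
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _convex_intersection_area(a: np.ndarray, b: np.ndarray) -> float:
    """Area of the intersection of two convex polygons."""
    poly = a
    k = len(b)
    # orient b counter-clockwise
    if _signed_area(b) < 0:
        b = b[::-1]
    for i in range(k):
        p0, p1 = b[i], b[(i + 1) % k]
        edge = p1 - p0
        n = np.array([edge[1], -edge[0]])   # outward normal for CCW polygon
        poly = _clip_halfplane(poly, p0, n)
        if len(poly) == 0:
            return 0.0
    return _poly_area(poly)


def _signed_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _voronoi_cell(i: int, sites: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Voronoi cell of site i clipped to a bounding polygon."""
    poly = box
    q = sites[i]
    for j, s in enumerate(sites):
        if j == i:
            continue
        m = (q + s) / 2.0
        poly = _clip_halfplane(poly, m, s - q)
        if len(poly) == 0:
            break
    return poly


class _SibsonInterpolator:
    """Natural-neighbor interpolation over a fixed electrode layout."""

    def __init__(self, sites: np.ndarray, values: np.ndarray):
        self.sites = np.asarray(sites, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.sites) != len(self.values):
            raise ValueError("one value per site required")
        if len(self.sites) < 3:
            raise ValueError("need at least 3 electrodes")
        lo = self.sites.min(axis=0)
        hi = self.sites.max(axis=0)
        span = max(float(np.max(hi - lo)), 1.0)
        pad = 4.0 * span
        self.box = np.array(
            [
                [lo[0] - pad, lo[1] - pad],
                [hi[0] + pad, lo[1] - pad],
                [hi[0] + pad, hi[1] + pad],
                [lo[0] - pad, hi[1] + pad],
            ]
        )
        self.cells = [_voronoi_cell(i, self.sites, self.box)
                      for i in range(len(self.sites))]
        self.hull = Delaunay(self.sites)
        self.scale = span

    def __call__(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        out = np.full(len(queries), np.nan)
        inside = self.hull.find_simplex(queries) >= 0
        for qi, q in enumerate(queries):
            d = np.linalg.norm(self.sites - q, axis=1)
            nearest = int(np.argmin(d))
            if d[nearest] < 1e-9 * self.scale:
                out[qi] = self.values[nearest]     # node exactness
                continue
            if not inside[qi]:
                continue
            # cell that q would own in the augmented diagram
            poly = self.box
            order = np.argsort(d)
            for j in order:
                s = self.sites[j]
                m = (q + s) / 2.0
                poly = _clip_halfplane(poly, m, s - q)
            r_q = float(np.max(np.linalg.norm(poly - q, axis=1)))
            cand = np.flatnonzero(d <= 2.0 * r_q + d[nearest] + 1e-9)
            weights = np.zeros(len(cand))
            for ci, j in enumerate(cand):
                cell = self.cells[j]
                if len(cell) >= 3:
                    weights[ci] = _convex_intersection_area(poly, cell)
            total = weights.sum()
            if total <= 0:
                out[qi] = self.values[nearest]
            else:
                out[qi] = float(np.dot(weights / total, self.values[cand]))
        return out


def natural_neighbor(sites: np.ndarray, values: np.ndarray,
                     queries: np.ndarray) -> np.ndarray:
    """Sibson natural-neighbor interpolation of scattered 2-D samples.

    Returns NaN outside the convex hull of the sites.  Exact at the sites
    and reproduces planar fields inside the hull.
    """
    return _SibsonInterpolator(sites, values)(queries)


# ---------------------------------------------------------------------------
# heat-map frames


@dataclass
class HeatMapFrame:
    """Dense interpolated SSEP field over the grid at one time point."""

    image: np.ndarray            # (ny, nx), NaN outside the electrode hull
    x_mm: np.ndarray
    y_mm: np.ndarray
    t_ms: float
    scale: str                   # "symmetric" | "asymmetric"
    vmin: float
    vmax: float
    cs_line: np.ndarray | None
    electrode_pos: np.ndarray
    electrode_values: np.ndarray
    is_ribbon: bool = False


def _is_collinear(positions: np.ndarray) -> bool:
    centered = positions - positions.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return len(s) < 2 or s[1] < 1e-9 * max(s[0], 1.0)


def heatmap_frame(trace: SSEPTrace, geometry: GridGeometry, t_ms: float,
                  resolution_mm: float = 0.25,
                  scale: str = "symmetric") -> HeatMapFrame:
    """Interpolated spatial field of the trace at one time point.

    Excluded channels are omitted from the interpolant.  An all-collinear
    layout (1 x N strip) falls back to 1-D linear interpolation rendered
    as a ribbon, with a warning.
    """
    t = trace.time_axis_ms
    if not (t[0] - 1e-9 <= t_ms <= t[-1] + 1e-9):
        raise ValueError(f"t={t_ms} ms outside the trace window")
    idx = int(np.argmin(np.abs(t - t_ms)))
    keep = np.setdiff1d(np.arange(trace.n_channels), trace.excluded_channels)
    pos = geometry.positions_mm[keep]
    vals = trace.values[keep, idx]

    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    x = np.arange(lo[0], hi[0] + resolution_mm / 2, resolution_mm)
    y = np.arange(lo[1], hi[1] + resolution_mm / 2, resolution_mm)

    if _is_collinear(pos):
        warnings.warn("all electrodes collinear; rendering a 1-D ribbon")
        direction = pos[np.argmax(np.linalg.norm(pos - pos[0], axis=1))] - pos[0]
        direction = direction / np.linalg.norm(direction)
        coord = (pos - pos[0]) @ direction
        order = np.argsort(coord)
        n_pix = max(int(round(coord.max() / resolution_mm)) + 1, 2)
        line = np.linspace(0.0, coord.max(), n_pix)
        profile = np.interp(line, coord[order], vals[order])
        image = np.tile(profile, (8, 1))    # ribbon
        x = line
        y = np.arange(8) * resolution_mm
        ribbon = True
    else:
        xx, yy = np.meshgrid(x, y)
        field = natural_neighbor(pos, vals,
                                 np.column_stack([xx.ravel(), yy.ravel()]))
        image = field.reshape(yy.shape)
        ribbon = False

    if scale == "symmetric":
        vmax = float(np.nanmax(np.abs(image))) or 1.0
        vmin = -vmax
    elif scale == "asymmetric":
        vmin = float(np.nanmin(image))
        vmax = float(np.nanmax(image))
    else:
        raise ValueError("scale must be 'symmetric' or 'asymmetric'")
    return HeatMapFrame(
        image=image, x_mm=x, y_mm=y, t_ms=float(t[idx]), scale=scale,
        vmin=vmin, vmax=vmax, cs_line=geometry.cs_line,
        electrode_pos=pos, electrode_values=vals, is_ribbon=ribbon,
    )


def animate(trace: SSEPTrace, geometry: GridGeometry, step_ms: float = 2.0,
            resolution_mm: float = 1.0,
            scale: str = "symmetric") -> list[HeatMapFrame]:
    """Frame sequence at ``step_ms`` intervals across the window on a
    common color scale (global max across frames)."""
    t0, t1 = trace.time_axis_ms[0], trace.time_axis_ms[-1]
    times = np.arange(t0, t1, step_ms)
    frames = [heatmap_frame(trace, geometry, tm, resolution_mm, scale)
              for tm in times]
    if scale == "symmetric":
        gmax = max((abs(f.vmax) for f in frames), default=1.0) or 1.0
        for f in frames:
            f.vmin, f.vmax = -gmax, gmax
    else:
        vmin = min(f.vmin for f in frames)
        vmax = max(f.vmax for f in frames)
        for f in frames:
            f.vmin, f.vmax = vmin, vmax
    return frames


def plot_heatmap(frame: HeatMapFrame, ax=None, cmap: str | None = None):
    """Render one frame (diverging zero-centered palette for symmetric
    scale, sequential for asymmetric)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if cmap is None:
        cmap = "RdBu_r" if frame.scale == "symmetric" else "viridis"
    extent = (frame.x_mm[0], frame.x_mm[-1], frame.y_mm[0], frame.y_mm[-1])
    im = ax.imshow(frame.image, origin="lower", extent=extent, cmap=cmap,
                   vmin=frame.vmin, vmax=frame.vmax, aspect="equal")
    if frame.cs_line is not None and not frame.is_ribbon:
        ax.plot(frame.cs_line[:, 0], frame.cs_line[:, 1], color="gray", lw=2)
    ax.scatter(frame.electrode_pos[:, 0], frame.electrode_pos[:, 1],
               s=8, c="k", marker=".")
    ax.set_xlabel("anterior → posterior (mm)")
    ax.set_ylabel("medial → lateral (mm)")
    ax.set_title(f"t = {frame.t_ms:.1f} ms")
    return im


def save_animation(frames: list[HeatMapFrame], path, fps: int = 4) -> None:
    """Write the frame sequence as an animated GIF."""
    import matplotlib.pyplot as plt
    from matplotlib import animation

    fig, ax = plt.subplots()

    def draw(i):
        ax.clear()
        plot_heatmap(frames[i], ax=ax)
        return []

    anim = animation.FuncAnimation(fig, draw, frames=len(frames), blit=False)
    anim.save(str(path), writer=animation.PillowWriter(fps=fps))
    plt.close(fig)


# ---------------------------------------------------------------------------
# cluster map


def cluster_map(result: ClusterResult, geometry: GridGeometry,
                ground_truth: GroundTruth | None = None, ax=None):
    """Categorical per-electrode map of the clustering outcome.

    Returns ``(categories, ax)``: per-channel category strings
    ("anterior" / "posterior" / "misclassified" / "excluded" / "single")
    and the matplotlib axes.  Excluded channels get a gray cross; a k = 1
    result is a single-color map flagged "no CS crossing detected".
    """
    import matplotlib.pyplot as plt

    n = geometry.n_channels
    categories = np.asarray(["excluded"] * n, dtype=object)
    kept = result.channel_indices
    if result.k == 2 and result.region_map:
        regions = result.regions
        categories[kept] = regions
        if ground_truth is not None:
            true = np.asarray(ground_truth.region_labels, dtype=object)[kept]
            wrong = kept[regions != true]
            categories[wrong] = "misclassified"
    else:
        categories[kept] = "single"

    if ax is None:
        _, ax = plt.subplots()
    palette = {
        "anterior": "tab:red",
        "posterior": "tab:blue",
        "misclassified": "tab:orange",
        "single": "tab:purple",
    }
    pos = geometry.positions_mm
    for cat, color in palette.items():
        m = categories == cat
        if m.any():
            ax.scatter(pos[m, 0], pos[m, 1], c=color, s=80, label=cat)
    m = categories == "excluded"
    if m.any():
        ax.scatter(pos[m, 0], pos[m, 1], c="gray", marker="x", s=80,
                   label="excluded")
    if ground_truth is not None:
        line = ground_truth.cs_line
        ax.plot(line[:, 0], line[:, 1], "--", color="gray", lw=2, label="CS")
    if result.k == 1:
        ax.set_title("no CS crossing detected (single cluster)")
    ax.set_xlabel("anterior → posterior (mm)")
    ax.set_ylabel("medial → lateral (mm)")
    ax.legend(loc="upper right", fontsize=7)
    return categories, ax
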