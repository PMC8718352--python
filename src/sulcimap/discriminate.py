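"""Anterior-vs-posterior separability of the SSEP over time.

Implements the Fisher discriminant ratio per time point,

    F(t) = (mu_A(t) - mu_P(t))^2 / (var_A(t) + var_P(t)),

physiological peak detection (1st negative peak in 17-25 ms, 2nd positive
peak in 27-40 ms), per-time-point ROC/AUC of channel amplitudes as
anterior/posterior scores, and the paired t-test used to compare
separability between trace flavors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .preprocess import SSEPTrace

__all__ = [
    "FisherProfile",
    "PeakSet",
    "fisher_profile",
    "detect_peaks",
    "roc_auc_at_time",
    "paired_ttest",
]

N1_WINDOW_MS = (17.0, 25.0)
P2_WINDOW_MS = (27.0, 40.0)
INTERMEDIATE_WINDOW_MS = (22.0, 30.0)


def _class_masks(labels: np.ndarray, excluded: np.ndarray,
                 n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    if len(labels) != n_channels:
        raise ValueError("labels must cover every channel")
    usable = np.ones(n_channels, dtype=bool)
    usable[np.asarray(excluded, dtype=int)] = False
    usable &= labels != "excluded"
    return (labels == "anterior") & usable, (labels == "posterior") & usable


@dataclass
class FisherProfile:
    """Per-time-point Fisher separability between the two channel classes."""

    F: np.ndarray
    mu_A: np.ndarray
    mu_P: np.ndarray
    var_A: np.ndarray
    var_P: np.ndarray
    t_axis_ms: np.ndarray
    flavor: str = "raw"
    infinite: bool = False           # some timepoint had 0 denominator, != means

    @property
    def argmax_t_ms(self) -> float:
        """Time of the globally most discriminative point (Raw F / Der F)."""
        return float(self.t_axis_ms[int(np.nanargmax(self.F))])

    def windowed_peak(self, window_ms: tuple[float, float]) -> tuple[float, float]:
        """(time, F) of the maximum inside a latency window."""
        m = (self.t_axis_ms >= window_ms[0]) & (self.t_axis_ms <= window_ms[1])
        if not m.any():
            raise ValueError("window outside the time axis")
        idx = np.flatnonzero(m)[int(np.nanargmax(self.F[m]))]
        return float(self.t_axis_ms[idx]), float(self.F[idx])

    @property
    def F_N20(self) -> tuple[float, float]:
        return self.windowed_peak(N1_WINDOW_MS)

    @property
    def F_P30(self) -> tuple[float, float]:
        return self.windowed_peak(P2_WINDOW_MS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_axis_ms,
                "F": self.F,
                "mu_A": self.mu_A,
                "mu_P": self.mu_P,
                "var_A": self.var_A,
                "var_P": self.var_P,
            }
        )


def fisher_profile(trace: SSEPTrace, labels: np.ndarray) -> FisherProfile:
    """Fisher discriminant ratio between anterior and posterior channels at
    every time point (sample variances, n-1 denominator).

    Raises if either class has fewer than 2 usable channels.  Timepoints
    where both class variances vanish yield F = 0 when the class means are
    equal and F = +inf (flagged) otherwise.
    """
    ant, post = _class_masks(labels, trace.excluded_channels, trace.n_channels)
    if ant.sum() < 2 or post.sum() < 2:
        raise ValueError(
            f"need >=2 channels per class, got anterior={int(ant.sum())}, "
            f"posterior={int(post.sum())}"
        )
    a = trace.values[ant]
    p = trace.values[post]
    mu_a, mu_p = a.mean(axis=0), p.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_p = p.var(axis=0, ddof=1)
    num = (mu_a - mu_p) ** 2
    den = var_a + var_p
    F = np.zeros_like(num)
    ok = den > 0
    F[ok] = num[ok] / den[ok]
    degenerate = (~ok) & (num > 0)
    F[degenerate] = np.inf
    return FisherProfile(
        F=F, mu_A=mu_a, mu_P=mu_p, var_A=var_a, var_P=var_p,
        t_axis_ms=trace.time_axis_ms, flavor=trace.flavor,
        infinite=bool(degenerate.any()),
    )


# ---------------------------------------------------------------------------
# physiological peaks


@dataclass
class PeakSet:
    """Per-channel physiological peak latencies and trough-to-peak
    amplitudes of the averaged SSEP."""

    channel_ids: list[str]
    region: np.ndarray
    n1_latency_ms: np.ndarray
    n1_amp_uV: np.ndarray
    n1_flag: np.ndarray              # True: no interior negative extremum
    p2_latency_ms: np.ndarray
    p2_amp_uV: np.ndarray
    p2_flag: np.ndarray
    intermediate_latency_ms: np.ndarray   # 22-30 ms peak, not used in stats
    der_n1_latency_ms: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "channel": self.channel_ids,
            "region": self.region,
            "n1_latency_ms": self.n1_latency_ms,
            "n1_amp_uV": self.n1_amp_uV,
            "n1_low_confidence": self.n1_flag,
            "p2_latency_ms": self.p2_latency_ms,
            "p2_amp_uV": self.p2_amp_uV,
            "p2_low_confidence": self.p2_flag,
            "intermediate_latency_ms": self.intermediate_latency_ms,
        }
        if self.der_n1_latency_ms is not None:
            d["der_n1_latency_ms"] = self.der_n1_latency_ms
        return pd.DataFrame(d)


def _local_extrema(y: np.ndarray, kind: str) -> np.ndarray:
    """Indices of interior local minima or maxima."""
    if kind == "min":
        return np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def _windowed_extremum(y: np.ndarray, t: np.ndarray,
                       window: tuple[float, float], kind: str):
    """Extremum in a latency window; flagged when it sits on the window
    boundary (no interior local extremum of the right polarity)."""
    m = (t >= window[0]) & (t <= window[1])
    idx_w = np.flatnonzero(m)
    seg = y[idx_w]
    rel = int(np.argmin(seg) if kind == "min" else np.argmax(seg))
    idx = idx_w[rel]
    local = _local_extrema(y, kind)
    flag = idx not in local
    return idx, flag


def _preceding_reference(y: np.ndarray, t: np.ndarray, peak_idx: int,
                         kind: str) -> float:
    """Value of the nearest preceding opposite-polarity local extremum,
    or the window-start value when none exists."""
    opposite = "max" if kind == "min" else "min"
    cand = _local_extrema(y, opposite)
    cand = cand[cand < peak_idx]
    if cand.size:
        return float(y[cand[-1]])
    return float(y[0])


def detect_peaks(trace: SSEPTrace, labels: np.ndarray | None = None,
                 derivative: SSEPTrace | None = None) -> PeakSet:
    """Per-channel 1st N (minimum in 17-25 ms) and 2nd P (maximum in
    27-40 ms) with trough-to-peak amplitudes.

    Amplitude = |extremum - preceding opposite-polarity local extremum|
    (window-start value when no such extremum precedes the peak).  The
    intermediate 22-30 ms positivity (anterior P20 / posterior P25
    superposition) is located but carries no statistics.  When a
    ``derivative`` trace is supplied, the first negative derivative peak
    ("Der 1st N") is reported as well.
    """
    t = trace.time_axis_ms
    if t[0] > 10.0 + 1e-9 or t[-1] < 40.0 - 1e-9:
        raise ValueError("trace must cover the 10-50 ms analysis window")
    n = trace.n_channels
    region = (
        np.asarray(labels, dtype=object) if labels is not None
        else np.asarray(["unknown"] * n, dtype=object)
    )
    n1_lat = np.empty(n)
    n1_amp = np.empty(n)
    n1_flag = np.zeros(n, dtype=bool)
    p2_lat = np.empty(n)
    p2_amp = np.empty(n)
    p2_flag = np.zeros(n, dtype=bool)
    inter_lat = np.empty(n)
    for i in range(n):
        y = trace.values[i]
        idx, flag = _windowed_extremum(y, t, N1_WINDOW_MS, "min")
        n1_lat[i] = t[idx]
        n1_flag[i] = flag
        n1_amp[i] = abs(y[idx] - _preceding_reference(y, t, idx, "min"))
        idx, flag = _windowed_extremum(y, t, P2_WINDOW_MS, "max")
        p2_lat[i] = t[idx]
        p2_flag[i] = flag
        p2_amp[i] = abs(y[idx] - _preceding_reference(y, t, idx, "max"))
        idx, _ = _windowed_extremum(y, t, INTERMEDIATE_WINDOW_MS, "max")
        inter_lat[i] = t[idx]
    der_n1 = None
    if derivative is not None:
        der_n1 = np.empty(n)
        for i in range(n):
            idx, _ = _windowed_extremum(
                derivative.values[i], derivative.time_axis_ms, N1_WINDOW_MS, "min"
            )
            der_n1[i] = derivative.time_axis_ms[idx]
    return PeakSet(
        channel_ids=list(trace.channel_ids), region=region,
        n1_latency_ms=n1_lat, n1_amp_uV=n1_amp, n1_flag=n1_flag,
        p2_latency_ms=p2_lat, p2_amp_uV=p2_amp, p2_flag=p2_flag,
        intermediate_latency_ms=inter_lat, der_n1_latency_ms=der_n1,
    )


# ---------------------------------------------------------------------------
# AUC and paired t-test


class AUCResult(NamedTuple):
    auc: float
    orientation: str     # "anterior_high" | "anterior_low"
    t_ms: float


def roc_auc_at_time(trace: SSEPTrace, labels: np.ndarray, t_ms: float) -> AUCResult:
    """AUC of channel amplitudes at one time point as scores separating
    anterior from posterior channels.

    Orientation is chosen so AUC >= 0.5 and reported; ties get midranks, so
    the value equals the Mann-Whitney probability estimate.
    """
    ant, post = _class_masks(labels, trace.excluded_channels, trace.n_channels)
    if ant.sum() == 0 or post.sum() == 0:
        raise ValueError("both classes must be non-empty for AUC")
    idx = int(np.argmin(np.abs(trace.time_axis_ms - t_ms)))
    scores = trace.values[:, idx]
    y = np.concatenate([np.ones(int(ant.sum())), np.zeros(int(post.sum()))])
    s = np.concatenate([scores[ant], scores[post]])
    auc = float(roc_auc_score(y, s))
    if auc >= 0.5:
        return AUCResult(auc, "anterior_high", float(trace.time_axis_ms[idx]))
    return AUCResult(1.0 - auc, "anterior_low", float(trace.time_axis_ms[idx]))


def paired_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test on the differences ``a - b``.

    Identical inputs return ``(0.0, 1.0)``; a constant nonzero difference
    has no finite t and returns ``(+/-inf, 0.0)`` with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        warnings.warn("zero variance of differences: t is infinite")
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
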