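"""Unsupervised grouping of grid channels by SSEP waveform morphology.

Spectral clustering of whole normalized waveforms: a Gaussian affinity
``W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` over channels, the
random-walk normalized graph Laplacian ``L = I - D^-1 W``, cluster-count
selection by the eigengap heuristic, and k-means on the entries of the
second-smallest eigenvector.  A two-cluster solution corresponds to the
anterior (M1) / posterior (S1) split across the central sulcus; a single
cluster signals that the grid does not cross the sulcus.

The estimator :class:`SpectralChannelClusterer` follows scikit-learn
conventions (``fit`` on a channels x timepoints matrix, fitted attributes
with trailing underscores) and composes with sklearn model selection; the
module-level functions are thin wrappers used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .geometry import GridGeometry
from .preprocess import SSEPTrace, drop_excluded
from .simulate import GroundTruth

__all__ = [
    "AffinityGraph",
    "ClusterResult",
    "affinity_matrix",
    "rw_laplacian",
    "choose_k_eigengap",
    "SpectralChannelClusterer",
    "spectral_cluster",
    "assign_regions",
    "clustering_accuracy",
    "resample_grids",
]

N1_WINDOW_MS = (17.0, 25.0)


@dataclass
class AffinityGraph:
    """Gaussian affinity over channels with its random-walk Laplacian."""

    W: np.ndarray
    sigma: float
    D: np.ndarray | None = None             # degree vector
    L: np.ndarray | None = None             # I - D^-1 W
    eigenvalues: np.ndarray | None = None   # ascending
    eigenvectors: np.ndarray | None = None  # columns, of L (random-walk)

    @property
    def eigengaps(self) -> np.ndarray:
        if self.eigenvalues is None:
            raise ValueError("spectrum not computed")
        return np.diff(self.eigenvalues)


def _as_waveform_matrix(traces) -> np.ndarray:
    if isinstance(traces, SSEPTrace):
        if traces.excluded_channels.size:
            raise ValueError(
                "excluded channels present; drop them before clustering"
            )
        return traces.values
    return np.asarray(traces, dtype=float)


def affinity_matrix(traces, sigma: float = 2.0) -> np.ndarray:
    """Gaussian similarity between whole waveforms (Euclidean distance),
    symmetrized, unit diagonal."""
    X = _as_waveform_matrix(traces)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    W = np.exp(-d2 / (2.0 * sigma**2))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return W


def rw_laplacian(W: np.ndarray, clip_tol: float = 1e-10) -> AffinityGraph:
    """Random-walk normalized Laplacian and its spectrum.

    Eigenpairs are computed on the symmetric equivalent
    ``I - D^-1/2 W D^-1/2`` (same eigenvalues; eigenvectors map back via
    ``v = D^-1/2 u``) and sorted ascending, the constant-vector eigenvalue
    ~0 first.  Tiny negative eigenvalues are clipped at ``-clip_tol``.
    """
    W = np.asarray(W, dtype=float)
    W = (W + W.T) / 2.0
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero row sum: disconnected isolated channel")
    L = np.eye(len(W)) - W / d[:, None]
    dmh = 1.0 / np.sqrt(d)
    L_sym = np.eye(len(W)) - (W * dmh[:, None]) * dmh[None, :]
    L_sym = (L_sym + L_sym.T) / 2.0
    vals, U = np.linalg.eigh(L_sym)
    vals = np.where(vals < 0, np.maximum(vals, -clip_tol), vals)
    vals = np.clip(vals, 0.0, None)
    V = dmh[:, None] * U
    # normalize random-walk eigenvectors for reproducible scale
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    return AffinityGraph(W=W, sigma=np.nan, D=d, L=L,
                         eigenvalues=vals, eigenvectors=V)


def choose_k_eigengap(eigenvalues: np.ndarray, k_max: int = 4,
                      gap_floor: float = 0.05) -> int:
    """Cluster count from the largest gap among the smallest eigenvalues.

    ``k = argmax_{k in 1..k_max} (lambda_{k+1} - lambda_k)``; when the
    winning gap exceeds the runner-up by less than ``gap_floor`` the
    smaller k of the two wins (tie-break toward fewer clusters).
    ``k = 1`` signals a single cluster, i.e. no CS crossing.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    k_max = min(k_max, len(vals) - 1)
    if k_max < 1:
        raise ValueError("need at least 2 eigenvalues")
    gaps = vals[1:k_max + 1] - vals[:k_max]
    order = np.argsort(gaps)[::-1]
    best = int(order[0])
    if len(order) > 1:
        second = int(order[1])
        if gaps[best] - gaps[second] < gap_floor:
            best = min(best, second)
    return best + 1


def _kmeans_1d(embedding: np.ndarray, k: int, n_restarts: int,
               seed) -> np.ndarray:
    """k-means on a 1-D embedding: deterministic sorted-quantile init plus
    random restarts; labels relabelled by ascending cluster center."""
    x = embedding.reshape(-1, 1)
    quantiles = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km_q = KMeans(n_clusters=k, init=quantiles, n_init=1).fit(x)
    km_r = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                  random_state=np.random.RandomState(seed)).fit(x)
    km = km_q if km_q.inertia_ <= km_r.inertia_ else km_r
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_]


class SpectralChannelClusterer(ClusterMixin, BaseEstimator):
    """Spectral clustering of electrode channels by waveform morphology.

    Parameters
    ----------
    sigma : float, default=2.0
        Width of the Gaussian affinity on normalized waveforms.
    k_max : int, default=4
        Largest cluster count considered by the eigengap heuristic.
    gap_floor : float, default=0.05
        Margin below which the eigengap tie-break prefers fewer clusters.
    n_restarts : int, default=50
        Random k-means restarts on the 1-D eigenvector embedding (in
        addition to a deterministic quantile initialization).
    random_state : int or None
        Seed for the k-means restarts; fixing it makes ``fit``
        deterministic.

    Attributes
    ----------
    affinity_ : ndarray (n_channels, n_channels)
        Gaussian affinity W.
    eigenvalues_, eigenvectors_ : spectrum of the random-walk Laplacian.
    eigengaps_ : successive differences of the sorted eigenvalues.
    k_ : chosen number of clusters (1 means "no CS crossing detected").
    embedding_ : entries of the second-smallest eigenvector.
    labels_ : per-channel cluster ids.
    """

    def __init__(self, sigma: float = 2.0, k_max: int = 4,
                 gap_floor: float = 0.05, n_restarts: int = 50,
                 random_state: int | None = None):
        self.sigma = sigma
        self.k_max = k_max
        self.gap_floor = gap_floor
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster channels.  X: (n_channels, n_timepoints) normalized
        waveforms (rows are samples in sklearn terms)."""
        X = check_array(X, ensure_min_samples=3)
        self.affinity_ = affinity_matrix(X, self.sigma)
        graph = rw_laplacian(self.affinity_)
        self.eigenvalues_ = graph.eigenvalues
        self.eigenvectors_ = graph.eigenvectors
        self.eigengaps_ = np.diff(graph.eigenvalues)
        self.k_ = choose_k_eigengap(graph.eigenvalues, self.k_max,
                                    self.gap_floor)
        embedding = graph.eigenvectors[:, 1]
        self.embedding_ = embedding
        if self.k_ == 1:
            self.labels_ = np.zeros(X.shape[0], dtype=int)
        elif np.ptp(embedding) < 1e-12:
            warnings.warn("degenerate (constant) second eigenvector; "
                          "falling back to a single cluster")
            self.k_ = 1
            self.labels_ = np.zeros(X.shape[0], dtype=int)
        else:
            self.labels_ = _kmeans_1d(embedding, self.k_, self.n_restarts,
                                      self.random_state)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterResult:
    """Outcome of spectral clustering on one channel set."""

    k: int
    labels: np.ndarray                       # per kept channel
    channel_indices: np.ndarray              # original channel indices kept
    eigenvalues: np.ndarray
    sigma: float
    seed: int | None = None
    region_map: dict = field(default_factory=dict)   # cluster id -> region
    accuracy_pct: float | None = None
    chl_cl: int | None = None                # correctly clustered channels
    confusion: pd.DataFrame | None = None

    @property
    def eigengaps(self) -> np.ndarray:
        return np.diff(self.eigenvalues)

    @property
    def regions(self) -> np.ndarray:
        """Per kept channel region string after assign_regions."""
        if not self.region_map:
            raise ValueError("regions not assigned yet")
        return np.asarray([self.region_map[int(l)] for l in self.labels],
                          dtype=object)

    def to_frame(self) -> pd.DataFrame:
        d = {"channel": self.channel_indices, "cluster": self.labels}
        if self.region_map:
            d["region"] = self.regions
        return pd.DataFrame(d)


def spectral_cluster(traces: SSEPTrace, sigma: float = 2.0,
                     k_max: int = 4, gap_floor: float = 0.05,
                     n_restarts: int = 50, seed: int | None = 0) -> ClusterResult:
    """Cluster the (non-excluded) channels of a normalized trace."""
    clean, keep = drop_excluded(traces)
    if clean.n_channels < 3:
        raise ValueError("need at least 3 channels after exclusions")
    est = SpectralChannelClusterer(sigma=sigma, k_max=k_max,
                                   gap_floor=gap_floor,
                                   n_restarts=n_restarts,
                                   random_state=seed).fit(clean.values)
    return ClusterResult(
        k=est.k_, labels=est.labels_, channel_indices=keep,
        eigenvalues=est.eigenvalues_, sigma=sigma, seed=seed,
    )


def clustering_accuracy(pred_regions: np.ndarray,
                        true_regions: np.ndarray) -> float:
    """Percentage of channels whose cluster-assigned region matches the
    ground truth: 100 * CHL_CL / total channels."""
    pred = np.asarray(pred_regions, dtype=object)
    true = np.asarray(true_regions, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("label arrays must have equal length")
    if pred.size == 0:
        raise ValueError("empty channel set")
    return 100.0 * float(np.mean(pred == true))


def assign_regions(result: ClusterResult, traces: SSEPTrace,
                   ground_truth: GroundTruth | None = None) -> ClusterResult:
    """Map the two clusters to anterior/posterior.

    With ground truth the mapping maximizing the accuracy over the two
    permutations is chosen and accuracy / CHL_CL / confusion are filled in.
    Without ground truth the cluster whose mean trace has the more
    negative extremum in 17-25 ms (the N20 side) becomes posterior.
    For k != 2 the region map degenerates to ``single`` and no accuracy
    is reported.
    """
    if result.k != 2:
        result.region_map = {int(c): "single" for c in np.unique(result.labels)}
        return result
    kept = result.channel_indices
    if ground_truth is not None:
        true = np.asarray(ground_truth.region_labels, dtype=object)[kept]
        best = None
        for mapping in ({0: "anterior", 1: "posterior"},
                        {0: "posterior", 1: "anterior"}):
            pred = np.asarray([mapping[int(l)] for l in result.labels],
                              dtype=object)
            acc = clustering_accuracy(pred, true)
            if best is None or acc > best[0]:
                best = (acc, mapping, pred)
        acc, mapping, pred = best
        result.region_map = mapping
        result.accuracy_pct = acc
        result.chl_cl = int(round(acc / 100.0 * len(pred)))
        result.confusion = pd.crosstab(
            pd.Series(true, name="true"), pd.Series(pred, name="predicted"),
            dropna=False,
        )
        return result
    t = traces.time_axis_ms
    m = (t >= N1_WINDOW_MS[0]) & (t <= N1_WINDOW_MS[1])
    vals = traces.values[kept] if traces.n_channels > len(kept) else traces.values
    mins = [vals[result.labels == c][:, m].mean(axis=0).min() for c in (0, 1)]
    post = int(np.argmin(mins))
    result.region_map = {post: "posterior", 1 - post: "anterior"}
    return result


def _score_subset(result: ClusterResult, true_regions: np.ndarray) -> float:
    """Eq-5-style accuracy for one clustered subset.

    k=2 -> best of the two cluster->region permutations; k=1 -> the
    majority-class fraction (a one-cluster call on a CS-crossing strip is
    penalized); k>2 -> purity (each cluster mapped to its majority region).
    """
    true = np.asarray(true_regions, dtype=object)
    if result.k == 1:
        values, counts = np.unique(true, return_counts=True)
        return 100.0 * counts.max() / len(true)
    if result.k == 2:
        best = 0.0
        for mapping in ({0: "anterior", 1: "posterior"},
                        {0: "posterior", 1: "anterior"}):
            pred = np.asarray([mapping[int(l)] for l in result.labels],
                              dtype=object)
            best = max(best, clustering_accuracy(pred, true))
        return best
    correct = 0
    for c in np.unique(result.labels):
        sub = true[result.labels == c]
        _, counts = np.unique(sub, return_counts=True)
        correct += counts.max()
    return 100.0 * correct / len(true)


def resample_grids(geometry: GridGeometry, traces: SSEPTrace,
                   ground_truth: GroundTruth, sigma: float = 2.0,
                   k_max: int = 4, gap_floor: float = 0.05,
                   n_restarts: int = 50, seed: int | None = 0):
    """Strip / small-grid resampling study.

    Enumerates every 1 x N strip (single medial-lateral row along the
    anterior-posterior axis) and every adjacent 2 x N pair, re-runs
    spectral clustering per subset, scores each against the ground truth,
    and summarizes mean +/- SD accuracy per grid type alongside the full
    ("large") grid.

    Returns
    -------
    per_subset : pandas.DataFrame
        One row per subset: grid_type, subset id, n_channels, k, accuracy.
    summary : pandas.DataFrame
        grid_type, n_subsets, mean_acc, sd_acc.
    skipped : list of str
        Log entries for subsets with fewer than 3 usable channels.
    """
    if geometry.rows < 2 or geometry.cols < 2:
        raise ValueError("resampling needs a grid with >=2 rows and columns")
    true_all = np.asarray(ground_truth.region_labels, dtype=object)
    excluded = set(traces.excluded_channels.tolist())
    rows = []
    skipped: list[str] = []

    def run(channel_idx: np.ndarray, grid_type: str, name: str) -> None:
        usable = np.array([i for i in channel_idx if i not in excluded], int)
        if len(usable) < 3:
            skipped.append(f"{name}: only {len(usable)} usable channels, skipped")
            return
        sub = traces.copy_with(
            values=traces.values[usable],
            excluded_channels=np.array([], int),
            channel_ids=[traces.channel_ids[i] for i in usable],
        )
        res = spectral_cluster(sub, sigma=sigma, k_max=k_max,
                               gap_floor=gap_floor, n_restarts=n_restarts,
                               seed=seed)
        acc = _score_subset(res, true_all[usable])
        rows.append({"grid_type": grid_type, "subset": name,
                     "n_channels": len(usable), "k": res.k, "accuracy_pct": acc})

    for i, strip in enumerate(geometry.ap_strips(width=1)):
        run(strip, "1xN", f"row{i}")
    for i, pair in enumerate(geometry.ap_strips(width=2)):
        run(pair, "2xN", f"rows{i}-{i + 1}")
    run(np.arange(geometry.n_channels), "large", "full")

    per_subset = pd.DataFrame(rows)
    summary = (
        per_subset.groupby("grid_type")["accuracy_pct"]
        .agg(n_subsets="size", mean_acc="mean", sd_acc="std")
        .reindex(["1xN", "2xN", "large"])
        .reset_index()
    )
    return per_subset, summary, skipped
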