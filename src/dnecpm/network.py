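"""Sliding-window connectivity graphs and the dynamic nodal-efficiency matrix.

For each subject the conditioned node-by-time series is cut into overlapping
windows; within each window a Pearson functional-connectivity matrix is
estimated and turned into a (by default weighted) graph whose edge lengths
are reciprocal connection weights.  Nodal global efficiency — the mean
inverse shortest-path distance from a node to all others (Latora–Marchiori)
— is computed per window, giving one efficiency curve per node.  The dnE
matrix is the node-by-node Pearson correlation of those curves: it measures
how synchronously two nodes' communication efficiencies fluctuate over the
scan, and every entry lies in [-1, 1] by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from sklearn.base import BaseEstimator, TransformerMixin

from .conditioning import RoiTimeSeries
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in units of time points (TRs).

    The defaults — 50-point windows advanced one TR (2 s at TR = 2 s) at a
    time — give 191 windows on a 240-point scan.
    """

    length_tp: int = 50
    step_tp: int = 1

    def __post_init__(self) -> None:
        if self.length_tp < 3:
            raise ConfigError("length_tp must be >= 3")
        if self.step_tp < 1:
            raise ConfigError("step_tp must be >= 1")


@dataclass(frozen=True)
class GraphConfig:
    """How a windowed correlation matrix becomes a graph.

    mode : "weighted" keeps correlation weights and assigns edge length
        1/weight; "binary" gives every retained edge length 1.
    negative_policy : "discard" removes negative correlations; "absolute"
        keeps their magnitude.
    sparsity : optional fraction in (0, 1]; when set, only the strongest
        ``sparsity`` fraction of candidate edges (by |weight|, ties broken
        by node-pair lexicographic order) is retained.
    """

    mode: str = "weighted"
    negative_policy: str = "discard"
    sparsity: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "binary"):
            raise ConfigError(f"mode must be 'weighted' or 'binary', got {self.mode!r}")
        if self.negative_policy not in ("discard", "absolute"):
            raise ConfigError(
                f"negative_policy must be 'discard' or 'absolute', "
                f"got {self.negative_policy!r}"
            )
        if self.sparsity is not None and not (0 < self.sparsity <= 1):
            raise ConfigError("sparsity must lie in (0, 1]")


@dataclass
class Graph:
    """Undirected graph as an edge list with travel lengths."""

    n_nodes: int
    edges: np.ndarray        # shape (m, 2), int node indices, i < j
    weights: np.ndarray      # shape (m,)
    lengths: np.ndarray      # shape (m,), positive travel costs

    def length_matrix(self) -> np.ndarray:
        """Dense symmetric matrix of edge lengths, ``inf`` where no edge."""
        mat = np.full((self.n_nodes, self.n_nodes), np.inf)
        np.fill_diagonal(mat, 0.0)
        if len(self.edges):
            i, j = self.edges[:, 0], self.edges[:, 1]
            mat[i, j] = self.lengths
            mat[j, i] = self.lengths
        return mat


@dataclass
class EfficiencyCurves:
    """Node-by-window matrix of nodal efficiencies plus window start indices."""

    data: np.ndarray
    window_starts: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_windows(self) -> int:
        return self.data.shape[1]


@dataclass
class DnEMatrix:
    """Correlation matrix of dynamic nodal-efficiency curves.

    Symmetric with unit diagonal and all entries in [-1, 1].  Nodes whose
    efficiency curve has zero variance are recorded in ``degenerate_nodes``
    and their correlations set to 0 by convention so the matrix stays finite.
    """

    data: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    degenerate_nodes: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.ndim != 2 or self.data.shape[1] != n:
            raise InputError("dnE data must be square")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(n)]
        if len(self.node_ids) != n:
            raise InputError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]


def make_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges ``[k*step, k*step+length)`` covering the scan.

    The count is ``floor((T - length)/step) + 1``; e.g. T=240, length=50,
    step=1 gives 191 windows.
    """
    if n_timepoints < spec.length_tp:
        raise InputError(
            f"series of {n_timepoints} points shorter than window "
            f"length {spec.length_tp}"
        )
    n_win = (n_timepoints - spec.length_tp) // spec.step_tp + 1
    return [
        (k * spec.step_tp, k * spec.step_tp + spec.length_tp)
        for k in range(n_win)
    ]


def window_fc(ts: RoiTimeSeries, window: tuple[int, int]) -> np.ndarray:
    """Pearson correlation matrix of all node pairs within one window."""
    start, stop = window
    if not (0 <= start < stop <= ts.n_timepoints):
        raise InputError(f"window {window} out of bounds for T={ts.n_timepoints}")
    if stop - start < 3:
        raise InputError("window must span at least 3 time points")
    return _corr_with_degenerates(ts.data[:, start:stop], context="window FC")[0]


def _corr_with_degenerates(rows: np.ndarray, context: str = "") -> tuple[np.ndarray, set[int]]:
    """Row-wise Pearson correlations; zero-variance rows give 0 (flagged)."""
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=1)
    degenerate = set(np.flatnonzero(sd == 0).tolist())
    if degenerate:
        logger.warning("%s: zero-variance rows %s set to 0", context or "corr",
                       sorted(degenerate))
    centred = rows - rows.mean(axis=1, keepdims=True)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = centred / safe_sd[:, None]
    c = z @ z.T / rows.shape[1]
    if degenerate:
        idx = list(degenerate)
        c[idx, :] = 0.0
        c[:, idx] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0), degenerate


def fc_to_graph(fc: np.ndarray, config: GraphConfig = GraphConfig()) -> Graph:
    """Turn a symmetric correlation matrix into an undirected graph.

    Negative correlations are discarded or rectified per policy; an optional
    proportional threshold keeps the top ``sparsity`` fraction of edges by
    absolute weight (lexicographic node-pair tie-break).  Weighted mode
    assigns edge length 1/weight so stronger connections are shorter.
    """
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    if fc.ndim != 2 or fc.shape[1] != n:
        raise InputError("correlation matrix must be square")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise InputError("correlation matrix must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    w = fc[iu, ju].copy()
    if config.negative_policy == "absolute":
        w = np.abs(w)
    keep = w > 0
    if config.sparsity is not None:
        m_total = len(w)
        n_keep = int(np.ceil(config.sparsity * m_total))
        # stable sort on (-|w|, i, j): lexicographic tie-break for equal weights
        order = np.lexsort((ju, iu, -np.abs(w)))
        ranked = np.zeros(m_total, dtype=bool)
        ranked[order[:n_keep]] = True
        keep &= ranked
    if not keep.any():
        logger.warning("graph construction: no edges survive thresholding")
    edges = np.column_stack([iu[keep], ju[keep]]).astype(int)
    weights = w[keep]
    if config.mode == "binary":
        lengths = np.ones_like(weights)
    else:
        lengths = 1.0 / weights
    return Graph(n_nodes=n, edges=edges, weights=weights, lengths=lengths)


def nodal_efficiency(graph: Graph | np.ndarray) -> np.ndarray:
    """Nodal global efficiency: mean inverse shortest-path distance.

    ``E_i = (1/(N-1)) * sum_{j != i} 1/d(i, j)`` with d the shortest-path
    length over edge travel costs; unreachable pairs contribute 0.  Accepts
    a :class:`Graph` or a dense length matrix (``inf`` for absent edges).
    """
    if isinstance(graph, Graph):
        lengths = graph.length_matrix()
        if len(graph.lengths) and np.any(graph.lengths < 0):
            raise InputError("edge lengths must be non-negative")
    else:
        lengths = np.asarray(graph, dtype=float)
        if np.any(lengths[np.isfinite(lengths)] < 0):
            raise InputError("edge lengths must be non-negative")
    n = lengths.shape[0]
    if n < 2:
        raise InputError("graph must have at least 2 nodes")
    dist = floyd_warshall(lengths)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def efficiency_curves(
    ts: RoiTimeSeries,
    spec: WindowSpec = WindowSpec(),
    config: GraphConfig = GraphConfig(),
) -> EfficiencyCurves:
    """Windowed nodal-efficiency curves: one row per node, one column per window."""
    windows = make_windows(ts.n_timepoints, spec)
    curves = np.empty((ts.n_nodes, len(windows)))
    for k, win in enumerate(windows):
        fc = window_fc(ts, win)
        graph = fc_to_graph(fc, config)
        curves[:, k] = nodal_efficiency(graph.length_matrix())
    return EfficiencyCurves(
        data=curves, window_starts=np.array([w[0] for w in windows])
    )


def dne_matrix(curves: EfficiencyCurves, node_ids: list[str] | None = None) -> DnEMatrix:
    """Inter-node Pearson correlation of the efficiency curves."""
    if curves.n_windows < 3:
        raise InputError("need at least 3 windows to correlate curves")
    corr, degenerate = _corr_with_degenerates(curves.data, context="dnE")
    return DnEMatrix(data=corr, node_ids=node_ids or [],
                     degenerate_nodes=degenerate)


def subject_dne(
    ts: RoiTimeSeries,
    spec: WindowSpec = WindowSpec(),
    config: GraphConfig = GraphConfig(),
) -> DnEMatrix:
    """Convenience: efficiency curves then dnE for one subject."""
    return dne_matrix(efficiency_curves(ts, spec, config), node_ids=ts.node_ids)


class DynamicEfficiencyTransformer(BaseEstimator, TransformerMixin):
    """Transformer from ROI time series to vectorised dnE features.

    ``transform`` maps a list of :class:`RoiTimeSeries` to a subject-by-pair
    feature matrix (upper triangle of each subject's dnE matrix).  Use
    :meth:`transform_matrices` to obtain the full :class:`DnEMatrix`
    objects instead.
    """

    def __init__(
        self,
        window_length: int = 50,
        window_step: int = 1,
        mode: str = "weighted",
        negative_policy: str = "discard",
        sparsity: float | None = None,
    ):
        self.window_length = window_length
        self.window_step = window_step
        self.mode = mode
        self.negative_policy = negative_policy
        self.sparsity = sparsity

    def _spec(self) -> WindowSpec:
        return WindowSpec(length_tp=self.window_length, step_tp=self.window_step)

    def _config(self) -> GraphConfig:
        return GraphConfig(mode=self.mode, negative_policy=self.negative_policy,
                           sparsity=self.sparsity)

    def fit(self, X, y=None):
        self._spec(), self._config()  # validate parameters
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else 0
        return self

    def transform_matrices(self, X) -> list[DnEMatrix]:
        spec, config = self._spec(), self._config()
        return [subject_dne(ts, spec, config) for ts in X]

    def transform(self, X) -> np.ndarray:
        from .prediction import vectorize_upper

        mats = self.transform_matrices(X)
        rows = []
        for m in mats:
            row, pair_index = vectorize_upper(m)
            rows.append(row)
        self.pair_index_ = pair_index
        return np.vstack(rows)
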