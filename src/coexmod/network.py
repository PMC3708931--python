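"""Hub-seeded mutual-information co-expression network inference.

Pairwise MI between expression profiles is estimated either with a
plug-in estimator on equal-frequency bins or with a Gaussian-kernel
density plug-in on copula-transformed data — the "accurate" mode of
ARACNE-style inference.  The kernel estimator works on normal scores
(rank-uniformised data mapped through the standard normal quantile
function, to which MI is invariant), uses leave-one-out densities to
cancel the self-kernel bias, and removes the leading O(h^2) smoothing
bias by Richardson extrapolation over bandwidths (h, sqrt(2) h).  The MI threshold is
calibrated from a permutation null via an exponential tail fit at a
requested P-value (typically Bonferroni, 0.05/#probes).  Candidate
edges are restricted to pairs with at least one hub endpoint; kept
edges then pass the Data Processing Inequality (DPI) pruning: in every
triangle the strictly weakest edge is removed when its MI falls below
(1 - epsilon) times the smaller of the other two, all triangles being
marked against the pre-pruning network so the result is independent of
visitation order.

All MI values are in nats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import mutual_info_score

from ._rng import substream

logger = logging.getLogger(__name__)

MI_KEY = "mi"


class CalibrationError(RuntimeError):
    """Raised when the permutation null is too small for a tail fit."""


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log-scale intensities.

    No missing values allowed; probe and sample labels are unique.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r} (and {len(bad) - 1} more)"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probe: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe)]


@dataclass
class NetworkConfig:
    """Inference parameters.

    hub_probes        probe labels seeding the network (empty -> all pairs)
    p_value           tail probability defining the MI threshold; 1 -> 0
    kernel_width      Gaussian bandwidth on the normal-scores scale, or
                      "auto" for the Silverman rule 1.06 * n^(-1/5)
    mi_floor          hard lower bound on kept-edge MI (nats)
    dpi_epsilon       DPI tolerance in [0, 1); 0 = strict
    estimator         "kernel" or "binned"
    n_bins            bins for the binned estimator (None -> floor(sqrt(n)))
    null_permutations number of permuted pairs for threshold calibration
    calibration       "tail" (exponential tail fit) or "quantile"
    seed              seed for permutation draws
    """

    hub_probes: frozenset[str] = frozenset()
    p_value: float = 0.05
    kernel_width: float | str = "auto"
    mi_floor: float = 0.0
    dpi_epsilon: float = 0.0
    estimator: str = "kernel"
    n_bins: int | None = None
    null_permutations: int = 1000
    calibration: str = "tail"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hub_probes = frozenset(self.hub_probes)
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")
        if self.kernel_width != "auto" and not float(self.kernel_width) > 0:
            raise ValueError("kernel_width must be positive or 'auto'")
        if self.mi_floor < 0:
            raise ValueError("mi_floor must be >= 0")
        if not 0.0 <= self.dpi_epsilon < 1.0:
            raise ValueError("dpi_epsilon must be in [0, 1)")
        if self.estimator not in ("kernel", "binned"):
            raise ValueError("estimator must be 'kernel' or 'binned'")
        if self.calibration not in ("tail", "quantile"):
            raise ValueError("calibration must be 'tail' or 'quantile'")

    def bandwidth(self, n: int) -> float:
        if self.kernel_width == "auto":
            return 1.06 * n ** (-1.0 / 5.0)
        return float(self.kernel_width)


@dataclass
class TopologySummary:
    """Node/edge totals and the per-component breakdown.

    component_sizes is a list of (n_nodes, n_edges), sorted by node
    count descending; the totals equal the sums over components.
    """

    n_nodes: int
    n_edges: int
    component_sizes: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_component_sizes(cls, sizes: Iterable[tuple[int, int]]) -> "TopologySummary":
        sizes = sorted(((int(n), int(e)) for n, e in sizes), key=lambda t: (-t[0], -t[1]))
        return cls(
            n_nodes=sum(n for n, _ in sizes),
            n_edges=sum(e for _, e in sizes),
            component_sizes=sizes,
        )

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)


# ---------------------------------------------------------------------------
# MI estimation


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels; ties broken by original order."""
    n = len(x)
    order = rankdata(x, method="ordinal") - 1  # 0..n-1
    return (order * n_bins) // n


def _mi_binned(x: np.ndarray, y: np.ndarray, n_bins: int | None) -> float:
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0  # a constant vector carries no information
    b = n_bins if n_bins is not None else max(2, int(math.isqrt(n)))
    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    return float(mutual_info_score(bx, by))


def copula_transform(x: np.ndarray) -> np.ndarray:
    """Rank-uniformise to (0, 1): rank / (n + 1), average ranks for ties."""
    return rankdata(x, method="average") / (len(x) + 1.0)


def normal_scores(x: np.ndarray) -> np.ndarray:
    """Copula transform mapped through the standard normal quantile.

    MI is invariant under strictly monotone marginal transforms, so the
    estimator may work on whichever scale is numerically kindest; the
    normal-scores scale avoids the hard [0, 1] boundaries of the
    rank-uniform scale where kernel density estimates are badly biased.
    """
    return norm.ppf(copula_transform(x))


def _kernel_matrix(z: np.ndarray, h: float) -> np.ndarray:
    """Unnormalised Gaussian kernel matrix on 1-D normal scores.

    Normalisation constants cancel between the joint and the product of
    marginals in the MI plug-in, so they are omitted throughout.
    """
    d = z[:, None] - z[None, :]
    return np.exp(-(d * d) / (2.0 * h * h))


def _mi_plugin_loo(kx: np.ndarray, ky: np.ndarray) -> float:
    """Leave-one-out plug-in MI (nats, unclamped) from kernel matrices."""
    n = kx.shape[0]
    dx, dy = np.diagonal(kx), np.diagonal(ky)
    joint = (kx * ky).sum(axis=1) - dx * dy
    mx = kx.sum(axis=1) - dx
    my = ky.sum(axis=1) - dy
    return float(np.mean(np.log((n - 1) * joint / (mx * my))))


def _mi_kernel(x: np.ndarray, y: np.ndarray, h: float) -> float:
    """Kernel plug-in MI with O(h^2) bias removed by extrapolation.

    The kernel at bandwidth sqrt(2) h is the elementwise square root of
    the kernel at h, so both evaluations share one matrix.
    """
    zx, zy = normal_scores(x), normal_scores(y)
    kx, ky = _kernel_matrix(zx, h), _kernel_matrix(zy, h)
    m1 = _mi_plugin_loo(kx, ky)
    m2 = _mi_plugin_loo(np.sqrt(kx), np.sqrt(ky))
    return max(2.0 * m1 - m2, 0.0)


def estimate_mi(x: Sequence[float], y: Sequence[float], config: NetworkConfig) -> float:
    """Estimated mutual information I(X; Y) in nats (always >= 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if config.estimator == "binned":
        return _mi_binned(x, y, config.n_bins)
    return _mi_kernel(x, y, config.bandwidth(len(x)))


def _kernel_stack(
    values: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Kernel matrices at (h, sqrt(2) h) and leave-one-out marginal sums.

    Returns (k, r, mk, mr): k and r of shape (g, n, n) with r = sqrt(k),
    mk and mr the (g, n) row sums minus the unit self-kernel.
    """
    z = norm.ppf(rankdata(values, method="average", axis=1) / (values.shape[1] + 1.0))
    d = z[:, :, None] - z[:, None, :]
    k = np.exp(-(d * d) / (2.0 * h * h))
    r = np.sqrt(k)
    return k, r, k.sum(axis=2) - 1.0, r.sum(axis=2) - 1.0


def _mi_kernel_rows_vs_one(
    k_all: np.ndarray,
    r_all: np.ndarray,
    mk_all: np.ndarray,
    mr_all: np.ndarray,
    i0: int,
) -> np.ndarray:
    """MI of row ``i0`` against every row of the stack, vectorised.

    Arithmetic is identical to :func:`_mi_kernel` evaluated pairwise
    (the entry at ``i0`` itself is the self-MI and should be ignored).
    """
    g, n, _ = k_all.shape
    k1, r1 = k_all[i0], r_all[i0]
    l1 = np.empty((g, n))
    l2 = np.empty((g, n))
    for i in range(n):
        j1 = k_all[:, i, :] @ k1[i, :] - 1.0
        j2 = r_all[:, i, :] @ r1[i, :] - 1.0
        l1[:, i] = np.log((n - 1) * j1 / (mk_all[:, i] * mk_all[i0, i]))
        l2[:, i] = np.log((n - 1) * j2 / (mr_all[:, i] * mr_all[i0, i]))
    return np.maximum(2.0 * l1.mean(axis=1) - l2.mean(axis=1), 0.0)


def bonferroni_p(familywise: float, n_probes: int) -> float:
    """Per-test P-value = familywise / n_probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0.0 < familywise <= 1.0:
        raise ValueError("familywise must be in (0, 1]")
    return familywise / n_probes


def _null_mi_sample(matrix: ExpressionMatrix, config: NetworkConfig) -> np.ndarray:
    """MI of permuted (independent-by-construction) gene pairs."""
    rng = substream(config.seed, "mi-null")
    n_pairs = config.null_permutations
    g, n = matrix.values.shape
    if g < 2:
        raise CalibrationError("need at least 2 probes to build a null")
    out = np.empty(n_pairs)
    if config.estimator == "binned":
        for t in range(n_pairs):
            i, j = rng.choice(g, size=2, replace=False)
            perm = rng.permutation(n)
            out[t] = _mi_binned(matrix.values[i], matrix.values[j][perm], config.n_bins)
        return out
    h = config.bandwidth(n)
    chunk = 256
    idx_i = rng.integers(0, g, size=n_pairs)
    idx_j = (idx_i + 1 + rng.integers(0, g - 1, size=n_pairs)) % g
    perms = np.array([rng.permutation(n) for _ in range(n_pairs)])
    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        xs = matrix.values[idx_i[lo:hi]]
        ys = np.take_along_axis(matrix.values[idx_j[lo:hi]], perms[lo:hi], axis=1)
        kx, rx, mkx, mrx = _kernel_stack(xs, h)
        ky, ry, mky, mry = _kernel_stack(ys, h)
        j1 = (kx * ky).sum(axis=2) - 1.0
        j2 = (rx * ry).sum(axis=2) - 1.0
        m1 = np.log((n - 1) * j1 / (mkx * mky)).mean(axis=1)
        m2 = np.log((n - 1) * j2 / (mrx * mry)).mean(axis=1)
        out[lo:hi] = np.maximum(2.0 * m1 - m2, 0.0)
    return out


def calibrate_mi_threshold(matrix: ExpressionMatrix, config: NetworkConfig) -> float:
    """MI threshold t* with null tail probability P(I > t*) = p_value.

    Builds a permutation null (sample-shuffled gene pairs), then fits an
    exponential tail ln P(I > t) ~ alpha - beta * t by least squares on
    the upper decile of the empirical survival curve and inverts it at
    ``p_value``.  With ``calibration="quantile"`` the empirical
    (1 - p) quantile is returned instead (small-run fallback).
    """
    if config.p_value >= 1.0:
        return 0.0
    if config.null_permutations < 100:
        raise CalibrationError("null_permutations must be >= 100 for a tail fit")
    null = np.sort(_null_mi_sample(matrix, config))
    if config.calibration == "quantile":
        return float(np.quantile(null, 1.0 - config.p_value))
    n = len(null)
    # survival at the k-th largest value is k/n
    k_top = max(10, n // 10)
    tail_vals = null[-k_top:]
    surv = (np.arange(k_top, 0, -1)) / n
    if np.all(tail_vals == tail_vals[0]):
        raise CalibrationError("degenerate null tail: all values identical")
    coef = np.polyfit(tail_vals, np.log(surv), 1)
    beta, alpha = -coef[0], coef[1]
    if beta <= 0:
        raise CalibrationError("null tail is not decaying; cannot extrapolate")
    t_star = (alpha - math.log(config.p_value)) / beta
    return max(float(t_star), 0.0)


# ---------------------------------------------------------------------------
# network construction


def empty_network() -> nx.Graph:
    return nx.Graph()


def _candidate_pairs(
    probe_ids: Sequence[str], hubs: frozenset[str]
) -> Iterable[tuple[int, int]]:
    idx = {p: i for i, p in enumerate(probe_ids)}
    if not hubs:
        g = len(probe_ids)
        for i in range(g):
            for j in range(i + 1, g):
                yield i, j
        return
    hub_idx = sorted(idx[p] for p in hubs)
    hub_set = set(hub_idx)
    for hi in hub_idx:
        for j in range(len(probe_ids)):
            if j == hi:
                continue
            if j in hub_set and j < hi:
                continue  # hub-hub pair already emitted from the smaller index
            yield hi, j


def build_network(
    matrix: ExpressionMatrix,
    config: NetworkConfig,
    threshold: float | None = None,
    dpi: bool = True,
) -> nx.Graph:
    """Infer the thresholded, DPI-pruned co-expression network.

    Candidate edges are exactly the pairs with at least one hub
    endpoint (all pairs when the hub set is empty).  An edge is kept
    iff its MI >= max(threshold, mi_floor); DPI pruning follows unless
    ``dpi=False`` (useful to inspect the raw thresholded network).
    Hub probes absent from the matrix are logged and dropped; if none
    remain a usage error is raised.
    """
    present = set(matrix.probe_ids)
    hubs = frozenset(h for h in config.hub_probes if h in present)
    dropped = config.hub_probes - hubs
    if dropped:
        logger.warning("%d hub probes absent from matrix; dropped", len(dropped))
    if config.hub_probes and not hubs:
        raise ValueError("all hub probes are absent from the expression matrix")
    if threshold is None:
        threshold = calibrate_mi_threshold(matrix, config)
    cutoff = max(threshold, config.mi_floor)

    net = nx.Graph()
    net.add_nodes_from(sorted(hubs))
    values = matrix.values
    probes = matrix.probe_ids
    n = matrix.n_samples

    if config.estimator == "kernel":
        h = config.bandwidth(n)
        k_all, r_all, mk_all, mr_all = _kernel_stack(values, h)
        idx = {p: i for i, p in enumerate(probes)}
        if hubs:
            hub_idx = sorted(idx[p] for p in hubs)
            hub_set = set(hub_idx)
            for hi in hub_idx:
                mi_row = _mi_kernel_rows_vs_one(k_all, r_all, mk_all, mr_all, hi)
                for j in np.nonzero(mi_row >= cutoff)[0]:
                    j = int(j)
                    if j == hi or (j in hub_set and j < hi):
                        continue
                    net.add_edge(probes[hi], probes[j], **{MI_KEY: float(mi_row[j])})
        else:
            for i in range(len(probes)):
                mi_row = _mi_kernel_rows_vs_one(k_all, r_all, mk_all, mr_all, i)
                for j in np.nonzero(mi_row >= cutoff)[0]:
                    j = int(j)
                    if j <= i:
                        continue
                    net.add_edge(probes[i], probes[j], **{MI_KEY: float(mi_row[j])})
    else:
        for i, j in _candidate_pairs(probes, hubs):
            mi = _mi_binned(values[i], values[j], config.n_bins)
            if mi >= cutoff:
                net.add_edge(probes[i], probes[j], **{MI_KEY: mi})

    if not dpi:
        return net
    return apply_dpi(net, config.dpi_epsilon)


def apply_dpi(net: nx.Graph, dpi_epsilon: float = 0.0) -> nx.Graph:
    """Data Processing Inequality pruning.

    For every triangle, the edge with the strictly smallest MI is
    marked for removal when I_weakest < (1 - epsilon) * min(other two).
    All marks are computed against the input network, then applied at
    once, so the result does not depend on triangle visitation order.
    Ties (no strict minimum) remove nothing.
    """
    if not 0.0 <= dpi_epsilon < 1.0:
        raise ValueError("dpi_epsilon must be in [0, 1)")
    tol = 1.0 - dpi_epsilon
    marked: set[tuple[str, str]] = set()
    adj = {u: set(net.neighbors(u)) for u in net.nodes}

    def key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    for u, v in net.edges:
        a, b = key(u, v)
        common = adj[a] & adj[b]
        for w in common:
            if w <= b:  # visit each triangle once, from its two smallest labels
                continue
            w_uv = net[a][b][MI_KEY]
            w_uw = net[a][w][MI_KEY]
            w_vw = net[b][w][MI_KEY]
            weights = [(w_uv, (a, b)), (w_uw, key(a, w)), (w_vw, key(b, w))]
            weights.sort(key=lambda t: t[0])
            lo, mid, _hi = weights
            if lo[0] < mid[0] and lo[0] < tol * mid[0]:
                marked.add(lo[1])
    out = net.copy()
    out.remove_edges_from(marked)
    return out


def connected_components(net: nx.Graph) -> list[nx.Graph]:
    """Maximal connected components, largest first (ties: smallest node label)."""
    comps = [net.subgraph(c).copy() for c in nx.connected_components(net)]
    comps.sort(key=lambda g: (-g.number_of_nodes(), min(g.nodes)))
    return comps


def filter_components_by_hubs(
    components: Sequence[nx.Graph], hub_probes: Iterable[str]
) -> nx.Graph:
    """Union of the components containing at least one hub probe."""
    hubs = set(hub_probes)
    keep = [c for c in components if hubs & set(c.nodes)]
    out = nx.Graph()
    for c in keep:
        out.add_nodes_from(c.nodes(data=True))
        out.add_edges_from(c.edges(data=True))
    return out


def network_summary(net: nx.Graph) -> TopologySummary:
    comps = connected_components(net)
    return TopologySummary.from_component_sizes(
        (c.number_of_nodes(), c.number_of_edges()) for c in comps
    )


def first_neighborhood(net: nx.Graph, node: str) -> nx.Graph:
    """Induced subgraph on {node} union its neighbors."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    nodes = {node} | set(net.neighbors(node))
    return net.subgraph(nodes).copy()
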