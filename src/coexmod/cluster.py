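"""Overlapping dense-module detection in co-expression networks.

Two complementary detectors are provided:

* a k-core vertex-weighting path ("kcore_complex"): each vertex is
  weighted by the product of its highest k-core level and the density
  of that core within its closed neighborhood; complexes grow outward
  from high-weight seeds, with an optional post-processing phase
  (2-core filter, fluff, haircut).  This path uses the unweighted
  topology only.
* a cohesiveness-growth path ("cohesive"): greedily grow/shrink a seed
  set to a local maximum of f(C) = W_in / (W_in + W_bound + p*|C|) on
  the MI-weighted graph, discard small or sparse results, and merge
  pairs whose overlap score omega(A, B) = |A&B|^2 / (|A|*|B|) exceeds a
  threshold.  Overlapping outputs are permitted.

A final pass removes modules contained (at a configurable fraction) in
a strictly larger module, mirroring the 91 -> 23 reduction that keeps
only maximal clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import MI_KEY


@dataclass(frozen=True)
class Module:
    module_id: str
    members: frozenset[str]
    score: float
    method: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a module needs at least one member")
        if self.score < 0:
            raise ValueError("module score must be >= 0")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    modules: list[Module]

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module ids must be unique")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


@dataclass
class DetectionParams:
    """Knobs for both detection paths.

    vwp                      vertex weight percentage in [0, 1): a neighbor
                             joins a growing complex when its weight is
                             >= (1 - vwp) * seed weight
    min_complex_degree       complexes without a k-core of this order are
                             dropped in post-processing
    fluff / fluff_threshold  optionally absorb outside neighbors whose
                             connectivity-to-complex density exceeds the
                             threshold (the only overlap source here)
    haircut                  optionally trim to the 2-core
    min_module_size          cohesive modules below this size are discarded
    density_floor            cohesive modules sparser than this are discarded
    overlap_merge_threshold  omega(A, B) at or above which two cohesive
                             modules are merged (to a fixpoint)
    containment_threshold    |A&B|/|A| at or above which A is a subcluster
                             of a strictly larger B and is removed
    penalty                  cohesiveness penalty term p (per-member)
    """

    vwp: float = 0.2
    min_complex_degree: int = 2
    fluff: bool = False
    fluff_threshold: float = 0.5
    haircut: bool = False
    min_module_size: int = 3
    density_floor: float = 0.0
    overlap_merge_threshold: float = 0.8
    containment_threshold: float = 1.0
    penalty: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")
        if not 0.0 < self.overlap_merge_threshold <= 1.0:
            raise ValueError("overlap_merge_threshold must be in (0, 1]")
        if not 0.0 < self.containment_threshold <= 1.0:
            raise ValueError("containment_threshold must be in (0, 1]")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


# ---------------------------------------------------------------------------
# k-core vertex weighting path


def vertex_weights(net: nx.Graph) -> dict[str, float]:
    """weight(v) = k * density(K): K the highest k-core of N[v] (closed).

    Isolated vertices weigh 0 (their closed neighborhood has an empty
    1-core, k = 0).
    """
    weights: dict[str, float] = {}
    for v in net.nodes:
        closed = {v} | set(net.neighbors(v))
        sub = net.subgraph(closed)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(sub)
        k = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= k]
        weights[v] = k * _density(net.subgraph(core_nodes))
    return weights


def predict_complexes(
    net: nx.Graph, weights: Mapping[str, float], params: DetectionParams
) -> ModuleSet:
    """Seeded outward growth from high-weight vertices.

    Seeds are taken in descending weight (ties by node label); growth is
    a BFS over not-yet-assigned neighbors u with
    weight(u) >= (1 - vwp) * weight(seed).  Assigned nodes are never
    re-seeded, so this phase yields non-overlapping complexes.
    Complex score = density * size.
    """
    unassigned = set(net.nodes)
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    modules: list[Module] = []
    for seed in order:
        if seed not in unassigned:
            continue
        wmin = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(net.neighbors(v)):
                    if u in unassigned and u not in members and weights[u] >= wmin:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        unassigned -= members
        sub = net.subgraph(members)
        modules.append(
            Module(
                module_id=f"C{len(modules) + 1}",
                members=frozenset(members),
                score=_density(sub) * len(members),
                method="kcore_complex",
            )
        )
    return ModuleSet(modules)


def postprocess_complexes(
    net: nx.Graph, modules: ModuleSet, params: DetectionParams
) -> ModuleSet:
    """2-core filter, then optional fluff, then optional haircut.

    * drop complexes whose induced subgraph has no non-empty
      ``min_complex_degree``-core (default 2-core);
    * fluff: absorb outside neighbors u with
      (#edges u -> complex) / |complex| > fluff_threshold — the only
      source of overlap on this path;
    * haircut: trim the complex to its 2-core.
    """
    out: list[Module] = []
    for m in modules:
        sub = net.subgraph(m.members)
        core = nx.k_core(sub, params.min_complex_degree)
        if core.number_of_nodes() == 0:
            continue
        members = set(m.members)
        if params.fluff:
            candidates = {
                u for v in members for u in net.neighbors(v) if u not in members
            }
            for u in sorted(candidates):
                conn = sum(1 for w in net.neighbors(u) if w in m.members)
                if conn / len(m.members) > params.fluff_threshold:
                    members.add(u)
        if params.haircut:
            members = set(nx.k_core(net.subgraph(members), 2).nodes)
            if not members:
                continue
        sub = net.subgraph(members)
        out.append(
            Module(
                module_id=f"C{len(out) + 1}",
                members=frozenset(members),
                score=_density(sub) * len(members),
                method="kcore_complex",
            )
        )
    return ModuleSet(out)


def detect_kcore_complexes(net: nx.Graph, params: DetectionParams) -> ModuleSet:
    """Full k-core path: weights -> growth -> post-processing."""
    weights = vertex_weights(net)
    return postprocess_complexes(net, predict_complexes(net, weights, params), params)


# ---------------------------------------------------------------------------
# cohesiveness growth path


def _edge_weight(net: nx.Graph, u: str, v: str) -> float:
    return float(net[u][v].get(MI_KEY, 1.0))


def cohesiveness(net: nx.Graph, members: Iterable[str], penalty: float = 0.0) -> float:
    """f(C) = W_in / (W_in + W_bound + penalty * |C|)."""
    members = set(members)
    w_in = 0.0
    w_bound = 0.0
    for v in sorted(members):  # fixed order: bit-reproducible float sums
        for u in sorted(net.neighbors(v)):
            w = _edge_weight(net, u, v)
            if u in members:
                w_in += w / 2.0  # each internal edge visited twice
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow_from(net: nx.Graph, seed: str, penalty: float) -> frozenset[str]:
    """Greedy local search on cohesiveness from a single-node seed."""
    members: set[str] = {seed}
    w_in = 0.0
    w_bound = sum(_edge_weight(net, seed, u) for u in net.neighbors(seed))

    def f(win: float, wb: float, size: int) -> float:
        denom = win + wb + penalty * size
        return win / denom if denom > 0 else 0.0

    current = f(w_in, w_bound, 1)
    while True:
        best: tuple[float, int, str] | None = None  # (f, action, node)
        boundary = {u for v in members for u in net.neighbors(v)} - members
        for u in sorted(boundary):
            w_to = sum(
                _edge_weight(net, u, v) for v in net.neighbors(u) if v in members
            )
            w_out = sum(
                _edge_weight(net, u, v) for v in net.neighbors(u) if v not in members
            )
            cand = f(w_in + w_to, w_bound - w_to + w_out, len(members) + 1)
            if best is None or cand > best[0]:
                best = (cand, 0, u)
        if len(members) > 1:
            for v in sorted(members):
                w_to = sum(
                    _edge_weight(net, v, u) for u in net.neighbors(v) if u in members
                )
                w_out = sum(
                    _edge_weight(net, v, u) for u in net.neighbors(v) if u not in members
                )
                cand = f(w_in - w_to, w_bound + w_to - w_out, len(members) - 1)
                if best is None or cand > best[0]:
                    best = (cand, 1, v)
        if best is None or best[0] <= current + 1e-12:
            return frozenset(members)
        current, action, node = best
        if action == 0:
            members.add(node)
            w_to = sum(_edge_weight(net, node, v) for v in net.neighbors(node) if v in members and v != node)
            w_out = sum(_edge_weight(net, node, v) for v in net.neighbors(node) if v not in members)
            w_in += w_to
            w_bound += w_out - w_to
        else:
            members.remove(node)
            w_to = sum(_edge_weight(net, node, v) for v in net.neighbors(node) if v in members)
            w_out = sum(_edge_weight(net, node, v) for v in net.neighbors(node) if v not in members and v != node)
            w_in -= w_to
            w_bound += w_to - w_out


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A & B|^2 / (|A| * |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def grow_cohesive_modules(
    net: nx.Graph,
    params: DetectionParams,
    seeds: Sequence[str] | None = None,
) -> ModuleSet:
    """Cohesiveness-growth detection with overlap merging.

    Default seeding: every node not yet covered by an emitted module,
    in descending weighted-degree order (ties by label).  Each seed is
    grown to a local maximum of f; results below ``min_module_size`` or
    ``density_floor`` are dropped; then any pair with overlap score
    >= ``overlap_merge_threshold`` is merged, iterating to a fixpoint.
    """
    if seeds is None:
        wdeg = {
            v: sum(_edge_weight(net, v, u) for u in net.neighbors(v)) for v in net.nodes
        }
        order = sorted(net.nodes, key=lambda v: (-wdeg[v], v))
        auto_seed = True
    else:
        order = list(seeds)
        auto_seed = False

    covered: set[str] = set()
    raw: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for seed in order:
        if seed not in net:
            raise KeyError(f"seed {seed!r} not in network")
        if auto_seed and seed in covered:
            continue
        members = _grow_from(net, seed, params.penalty)
        covered |= members
        if members not in seen:
            seen.add(members)
            raw.append(members)

    kept = [
        m
        for m in raw
        if len(m) >= params.min_module_size
        and _density(net.subgraph(m)) >= params.density_floor
    ]

    # merge highly overlapping pairs to a fixpoint
    merged = True
    while merged:
        merged = False
        kept.sort(key=lambda s: (-len(s), tuple(sorted(s))))
        for i, j in itertools.combinations(range(len(kept)), 2):
            if overlap_score(kept[i], kept[j]) >= params.overlap_merge_threshold:
                union = frozenset(kept[i] | kept[j])
                kept = [s for k, s in enumerate(kept) if k not in (i, j)]
                if union not in kept:
                    kept.append(union)
                merged = True
                break

    kept.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    modules = [
        Module(
            module_id=f"M{i + 1}",
            members=m,
            score=cohesiveness(net, m, params.penalty),
            method="cohesive",
        )
        for i, m in enumerate(kept)
    ]
    return ModuleSet(modules)


# ---------------------------------------------------------------------------
# shared post-processing


def remove_subclusters(modules: ModuleSet, containment_threshold: float = 1.0) -> ModuleSet:
    """Drop module A iff some strictly larger B has |A & B| / |A| >= threshold.

    Evaluated against the original set in a single pass (no cascade);
    equal-size pairs never trigger removal.
    """
    if not 0.0 < containment_threshold <= 1.0:
        raise ValueError("containment_threshold must be in (0, 1]")
    originals = list(modules)
    kept = []
    for a in originals:
        contained = any(
            len(b) > len(a)
            and len(a.members & b.members) / len(a) >= containment_threshold
            for b in originals
        )
        if not contained:
            kept.append(a)
    return ModuleSet(kept)


def merge_most_similar(modules: ModuleSet) -> Module:
    """Union of the module pair sharing the most members.

    Ties broken by larger overlap score omega, then by lexicographic
    module-id pair.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules to merge")
    best = None
    for a, b in itertools.combinations(modules, 2):
        ids = tuple(sorted((a.module_id, b.module_id)))
        cand = (
            -len(a.members & b.members),
            -overlap_score(a.members, b.members),
            ids,
        )
        if best is None or cand < best[0]:
            best = (cand, a, b)
    _, a, b = best
    return Module(
        module_id=f"merged({a.module_id}+{b.module_id})",
        members=a.members | b.members,
        score=max(a.score, b.score),
        method=a.method,
    )


def module_stats(
    modules: ModuleSet,
    probe_to_gene: Mapping[str, str] | None = None,
) -> dict:
    """Module count, gene counts with/without multiplicity, per-module table.

    When ``probe_to_gene`` is given, members (probes) are collapsed to
    gene symbols before counting.
    """

    def genes_of(m: Module) -> set[str]:
        if probe_to_gene is None:
            return set(m.members)
        return {probe_to_gene.get(p, p) for p in m.members}

    per_module = pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "size": len(genes_of(m)),
                "score": m.score,
                "method": m.method,
            }
            for m in modules
        ],
        columns=["module_id", "size", "score", "method"],
    )
    all_genes = [g for m in modules for g in sorted(genes_of(m))]
    return {
        "n_modules": len(modules),
        "genes_with_multiplicity": len(all_genes),
        "unique_genes": len(set(all_genes)),
        "per_module": per_module,
    }
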