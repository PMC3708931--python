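"""Multi-omic gene-set integration for hub selection.

Turns per-platform copy-number segment calls plus curated mutation/GWAS
gene lists into the hub gene set that seeds co-expression network
inference.  The chain is:

1. per-platform recurrence: fraction of samples carrying a gain (or
   loss) call overlapping each candidate locus;
2. recurrence filtering at a per-platform threshold (e.g. >=15% of
   SNP-array samples, >=40% of CGH cell lines);
3. cross-platform intersection of the retained (locus, state) sets,
   state-stratified, on bp intervals;
4. mapping retained loci to genes via the annotation;
5. union with the mutation and GWAS lists (provenance kept);
6. eligibility filtering: a hub gene must have at least one expression
   probe and a GO annotation.

All coordinates are 0-based, half-open (BED convention).  Cytoband
labels, when used at all, are annotation-layer only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
STATES = (GAIN, LOSS)


class Locus(NamedTuple):
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersect(self, other: "Locus") -> "Locus | None":
        if not self.overlaps(other):
            return None
        return Locus(self.chrom, max(self.start, other.start), min(self.end, other.end))


class SegmentCall(NamedTuple):
    """One gain/loss call for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str

    @property
    def locus(self) -> Locus:
        return Locus(self.chrom, self.start, self.end)


@dataclass
class SegmentCallSet:
    """All calls from one platform, plus the assayed-sample denominator.

    ``n_samples`` counts every sample the platform assayed, including
    call-free ones; it is the denominator of recurrence frequencies.
    """

    platform: str
    calls: list[SegmentCall]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("SegmentCallSet.n_samples must be >= 1")
        for c in self.calls:
            if c.start >= c.end:
                raise ValueError(f"segment call with start >= end: {c}")
            if c.state not in STATES:
                raise ValueError(f"segment state must be one of {STATES}: {c}")
        n_distinct = len({c.sample_id for c in self.calls})
        if n_distinct > self.n_samples:
            raise ValueError(
                f"{n_distinct} distinct sample ids in calls exceed n_samples={self.n_samples}"
            )


@dataclass
class GeneAnnotation:
    """Gene -> probes / locus / GO-term-presence lookup.

    ``table`` columns: gene, probes (list of probe ids, possibly empty),
    chrom, start, end, has_go_term.  Gene symbols are unique; probe ids
    are unique across genes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "probes", "chrom", "start", "end", "has_go_term"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene symbols in annotation: {dups[:5]}")
        all_probes = [p for probes in self.table["probes"] for p in probes]
        if len(all_probes) != len(set(all_probes)):
            raise ValueError("probe ids must be unique across genes")
        self.table = self.table.reset_index(drop=True)
        self._by_gene = self.table.set_index("gene", drop=False)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene.index

    def probes_of(self, gene: str) -> list[str]:
        return list(self._by_gene.at[gene, "probes"]) if gene in self else []

    def has_go(self, gene: str) -> bool:
        return bool(self._by_gene.at[gene, "has_go_term"]) if gene in self else False

    def locus_of(self, gene: str) -> Locus | None:
        if gene not in self:
            return None
        row = self._by_gene.loc[gene]
        try:
            return Locus(str(row["chrom"]), int(row["start"]), int(row["end"]))
        except (TypeError, ValueError):
            return None

    def probe_to_gene(self) -> dict[str, str]:
        return {p: g for g, probes in zip(self.table["gene"], self.table["probes"]) for p in probes}


@dataclass
class GeneList:
    """A named set of gene symbols with per-symbol provenance."""

    source: str
    symbols: frozenset[str]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = frozenset(self.symbols)
        if not self.provenance:
            self.provenance = {s: frozenset({self.source}) for s in self.symbols}

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class HubGeneSet:
    """Hub-eligible genes (>=1 probe, GO-annotated) and their probes."""

    symbols: frozenset[str]
    probe_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# operations


def compute_locus_frequencies(calls: SegmentCallSet, loci: Sequence[Locus]) -> pd.DataFrame:
    """Per-(locus, state) recurrence table for one platform.

    frequency = (#distinct samples with >=1 overlapping call of that
    state) / n_samples.  A sample with several overlapping calls counts
    once.  Returns a DataFrame with columns
    chrom, start, end, state, support, frequency.
    """
    rows = []
    for locus in loci:
        for state in STATES:
            supporters = {
                c.sample_id
                for c in calls.calls
                if c.state == state and c.locus.overlaps(locus)
            }
            rows.append(
                {
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "state": state,
                    "support": len(supporters),
                    "frequency": len(supporters) / calls.n_samples,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "support", "frequency"])


def filter_by_frequency(table: pd.DataFrame, min_fraction: float) -> set[tuple[Locus, str]]:
    """Keep (locus, state) rows with recurrence >= ``min_fraction`` (inclusive)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    kept = table[table["frequency"] >= min_fraction]
    return {
        (Locus(str(r.chrom), int(r.start), int(r.end)), str(r.state))
        for r in kept.itertuples()
    }


def intersect_loci(sets: Sequence[set[tuple[Locus, str]]]) -> set[tuple[Locus, str]]:
    """Cross-platform intersection of retained (locus, state) sets.

    State-stratified; works on bp intervals.  The result contains the
    intersection *regions* present in every input set — not either
    parent locus — so a narrow SNP-array peak nested inside a broad CGH
    band survives as the peak.
    """
    if len(sets) < 2:
        raise ValueError("intersect_loci needs at least 2 input sets")
    out: set[tuple[Locus, str]] = set()
    for state in STATES:
        current = [loc for loc, s in sets[0] if s == state]
        for other_set in sets[1:]:
            others = [loc for loc, s in other_set if s == state]
            nxt = []
            for a in current:
                for b in others:
                    inter = a.intersect(b)
                    if inter is not None:
                        nxt.append(inter)
            current = nxt
        out.update((loc, state) for loc in current)
    return out


def map_loci_to_genes(
    loci: Iterable[tuple[Locus, str]], annotation: GeneAnnotation
) -> GeneList:
    """Genes whose annotated locus overlaps any retained locus (any-overlap rule)."""
    loci = list(loci)
    hits: set[str] = set()
    for gene in annotation.genes:
        gl = annotation.locus_of(gene)
        if gl is None:
            logger.warning("gene %s has malformed locus annotation; skipped", gene)
            continue
        if any(gl.overlaps(locus) for locus, _state in loci):
            hits.add(gene)
    return GeneList(source="cnv", symbols=frozenset(hits))


def merge_gene_sets(lists: Sequence[GeneList]) -> GeneList:
    """Set union with per-symbol provenance (which sources contained it)."""
    provenance: dict[str, set[str]] = {}
    for gl in lists:
        for sym in gl.symbols:
            provenance.setdefault(sym, set()).update(gl.provenance.get(sym, {gl.source}))
    return GeneList(
        source="merged",
        symbols=frozenset(provenance),
        provenance={s: frozenset(v) for s, v in provenance.items()},
    )


def filter_hub_eligible(genes: GeneList, annotation: GeneAnnotation) -> HubGeneSet:
    """Keep genes with >=1 probe AND a GO term; genes absent from the
    annotation are ineligible."""
    eligible = {
        g for g in genes.symbols if annotation.probes_of(g) and annotation.has_go(g)
    }
    probes = {p for g in eligible for p in annotation.probes_of(g)}
    return HubGeneSet(symbols=frozenset(eligible), probe_ids=frozenset(probes))


# ---------------------------------------------------------------------------
# convenience driver


def integrate(
    call_sets: Mapping[str, SegmentCallSet],
    candidate_loci: Mapping[str, Sequence[Locus]],
    min_fractions: Mapping[str, float],
    annotation: GeneAnnotation,
    extra_lists: Sequence[GeneList] = (),
) -> tuple[HubGeneSet, GeneList, dict[str, pd.DataFrame]]:
    """Full integration chain.

    ``min_fractions`` maps platform label -> recurrence threshold (e.g.
    0.15 for SNP arrays, 0.40 for CGH cell lines).  Returns the hub set,
    the merged gene list, and the per-platform frequency tables.
    """
    tables: dict[str, pd.DataFrame] = {}
    retained: list[set[tuple[Locus, str]]] = []
    for platform, cs in call_sets.items():
        table = compute_locus_frequencies(cs, candidate_loci[platform])
        tables[platform] = table
        retained.append(filter_by_frequency(table, min_fractions[platform]))
    if len(retained) >= 2:
        common = intersect_loci(retained)
    elif retained:
        common = retained[0]
    else:
        common = set()
    cnv_genes = map_loci_to_genes(common, annotation)
    merged = merge_gene_sets([cnv_genes, *extra_lists])
    hubs = filter_hub_eligible(merged, annotation)
    return hubs, merged, tables
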