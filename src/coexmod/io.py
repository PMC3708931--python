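"""Plain-text formats for every pipeline artifact.

Dialects:

* expression: TSV, first column probe id, header row of sample ids;
* segment calls: BED-like TSV (sample, chrom, start, end, state) with a
  ``# platform=... n_samples=...`` header line carrying the denominator;
* annotation: CSV (gene, probes ';'-joined, chrom, start, end, has_go);
* gene lists: one symbol per line;
* networks: TSV edge list (probe_a, probe_b, mi_nats; isolated nodes as
  rows with empty partner/weight) or GraphML.  Weights are serialised
  with shortest round-trip decimal repr, so read(write(net)) preserves
  them exactly;
* modules: CSV (module_id, member, gene, score, method);
* ground truth: CSV (module_id, gene).

All genomic coordinates are 0-based, half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .cluster import Module, ModuleSet
from .integrate import GeneAnnotation, GeneList, Locus, SegmentCall, SegmentCallSet
from .network import MI_KEY, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_segment_calls",
    "write_segment_calls",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_network",
    "write_network",
    "read_modules",
    "write_modules",
    "write_ground_truth",
    "read_ground_truth",
]


# -- expression -------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dups[:5]}")
    if df.isna().any().any():
        mask = df.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise ValueError(f"missing value in {path} at probe {r!r}, sample {c!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any():
                r = coerced.index[coerced.isna()][0]
                raise ValueError(
                    f"malformed numeric cell in {path} at probe {r!r}, sample {c!r}"
                ) from exc
        raise
    return ExpressionMatrix(
        probe_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=None)


# -- segment calls ----------------------------------------------------------


def write_segment_calls(calls: SegmentCallSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# platform={calls.platform}\tn_samples={calls.n_samples}\n")
        fh.write("sample\tchrom\tstart\tend\tstate\n")
        for c in calls.calls:
            fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.state}\n")


def read_segment_calls(path: str | Path) -> SegmentCallSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# platform=... n_samples=...' header")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split("\t") if "=" in kv
        )
        platform = meta.get("platform", "unknown")
        n_samples = int(meta["n_samples"])
        reader = csv.DictReader(fh, delimiter="\t")
        calls = [
            SegmentCall(
                row["sample"], row["chrom"], int(row["start"]), int(row["end"]), row["state"]
            )
            for row in reader
        ]
    return SegmentCallSet(platform=platform, calls=calls, n_samples=n_samples)


# -- annotation -------------------------------------------------------------


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    df = annotation.table.copy()
    df["probes"] = [";".join(p) for p in df["probes"]]
    df["has_go_term"] = df["has_go_term"].astype(int)
    df.to_csv(path, index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, dtype={"gene": str, "chrom": str})
    df["probes"] = [
        [] if pd.isna(p) or p == "" else str(p).split(";") for p in df["probes"]
    ]
    df["has_go_term"] = df["has_go_term"].astype(bool)
    return GeneAnnotation(df)


# -- gene lists -------------------------------------------------------------


def write_gene_list(genes: GeneList | Iterable[str], path: str | Path) -> None:
    symbols = sorted(genes.symbols) if isinstance(genes, GeneList) else sorted(set(genes))
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_gene_list(path: str | Path, source: str = "list") -> GeneList:
    symbols = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneList(source=source, symbols=frozenset(symbols))


# -- networks ---------------------------------------------------------------


def write_network(net: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("probe_a\tprobe_b\tmi_nats\n")
            for u, v in sorted(tuple(sorted(e)) for e in net.edges):
                fh.write(f"{u}\t{v}\t{net[u][v][MI_KEY]!r}\n")
            for v in sorted(net.nodes):
                if net.degree(v) == 0:
                    fh.write(f"{v}\t\t\n")
    elif format == "graphml":
        # canonical node/edge order so identical graphs serialise identically
        canon = nx.Graph()
        canon.add_nodes_from(sorted(net.nodes))
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            canon.add_edge(u, v, **net[u][v])
        nx.write_graphml(canon, path, infer_numeric_types=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str | None = None) -> nx.Graph:
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, **{MI_KEY: float(data[MI_KEY])})
        return out
    if format != "tsv":
        raise ValueError(f"unknown network format {format!r}")
    net = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("probe_a"):
            raise ValueError(f"{path}: not a network TSV (bad header)")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[1] == "":
                net.add_node(parts[0])
            else:
                net.add_edge(parts[0], parts[1], **{MI_KEY: float(parts[2])})
    return net


# -- modules ----------------------------------------------------------------


def write_modules(
    modules: ModuleSet,
    path: str | Path,
    probe_to_gene: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["module_id", "member", "gene", "score", "method"])
        for m in modules:
            for member in sorted(m.members):
                gene = probe_to_gene.get(member, member) if probe_to_gene else member
                writer.writerow([m.module_id, member, gene, repr(m.score), m.method])


def read_modules(path: str | Path) -> ModuleSet:
    df = pd.read_csv(path)
    modules = []
    for mid, grp in df.groupby("module_id", sort=False):
        modules.append(
            Module(
                module_id=str(mid),
                members=frozenset(grp["member"].astype(str)),
                score=float(grp["score"].iloc[0]),
                method=str(grp["method"].iloc[0]),
            )
        )
    return ModuleSet(modules)


# -- ground truth -----------------------------------------------------------


def write_ground_truth(modules, path: str | Path) -> None:
    """CSV of (module_id, gene) for planted modules."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["module_id", "gene"])
        for m in modules:
            for g in m.member_genes:
                writer.writerow([m.module_id, g])


def read_ground_truth(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path)
    return {str(k): list(grp["gene"]) for k, grp in df.groupby("module_id", sort=False)}
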