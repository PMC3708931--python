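"""End-to-end driver: integrate -> network -> modules, with a manifest.

The pipeline either consumes files (expression TSV, segment TSVs,
annotation CSV, gene-list texts) or generates a fully synthetic run
from a :class:`~coexmod.simulate.SimulationConfig`.  Stage order:

    integrate (CNV recurrence + lists -> hubs)
    calibrate MI threshold -> build network (+ DPI)
    component filter by hubs
    cluster -> remove subclusters -> stats

A single global seed is fanned out to stage-labelled substreams; the
manifest records the config snapshot, input checksums, per-stage
counts and the package version.  Re-running an identical config
reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import cluster, integrate, io, network, simulate
from ._version import __version__
from .integrate import GeneList, Locus

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # either a synthetic scenario ...
    simulation: simulate.SimulationConfig | None = None
    annotation_params: dict[str, Any] = field(default_factory=dict)
    gene_list_sizes: tuple[int, int, int] = (141, 41, 1)
    gene_list_universe: list[str] | None = None
    # ... or input files
    expression_path: str | None = None
    segment_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    mutation_path: str | None = None
    gwas_path: str | None = None
    hub_list_path: str | None = None
    # stage parameters
    min_fractions: dict[str, float] = field(default_factory=dict)
    network_params: dict[str, Any] = field(default_factory=dict)
    detection_params: dict[str, Any] = field(default_factory=dict)
    cluster_method: str = "cohesive"
    containment_threshold: float = 1.0
    require_hub_in_module: bool = False
    log_level: str = "INFO"

    def network_config(
        self, hub_probes=frozenset(), n_probes: int | None = None
    ) -> network.NetworkConfig:
        params = dict(self.network_params)
        params.setdefault("seed", self.seed)
        if params.pop("bonferroni", False):
            if n_probes is None:
                raise ValueError("bonferroni correction needs the probe count")
            params["p_value"] = network.bonferroni_p(
                params.get("p_value", 0.05), n_probes
            )
        return network.NetworkConfig(hub_probes=frozenset(hub_probes), **params)

    def detection(self) -> cluster.DetectionParams:
        return cluster.DetectionParams(**self.detection_params)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    def convert(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, dict):
            return {_key(k): convert(v) for k, v in o.items()}
        if isinstance(o, Locus):
            return f"{o.chrom}:{o.start}-{o.end}"
        if isinstance(o, (frozenset, set)):
            return sorted(convert(v) for v in o)
        if isinstance(o, (list, tuple)):
            return [convert(v) for v in o]
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        return str(o)

    def _key(k):
        if isinstance(k, Locus):
            return f"{k.chrom}:{k.start}-{k.end}"
        return str(k)

    return convert(config)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_snapshot(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "inputs": {},
        "complete": False,
    }

    try:
        stage = "inputs"
        if config.simulation is not None:
            sim = config.simulation
            matrix, truth = simulate.generate_expression(sim)
            io.write_expression(matrix, out / "expression.tsv")
            io.write_ground_truth(truth, out / "ground_truth.csv")
            call_sets = {
                p: simulate.generate_segment_calls(sim, p) for p in sim.platforms
            }
            for p, cs in call_sets.items():
                io.write_segment_calls(cs, out / f"segments_{p}.tsv")
            annotation = simulate.generate_annotation(sim, **config.annotation_params)
            io.write_annotation(annotation, out / "annotation.csv")
            n_mut, n_gwas, n_overlap = config.gene_list_sizes
            universe = config.gene_list_universe or sim.gene_labels()
            mutation, gwas = simulate.generate_gene_lists(
                n_mut, n_gwas, n_overlap, universe, seed=sim.seed
            )
            io.write_gene_list(mutation, out / "mutation_genes.txt")
            io.write_gene_list(gwas, out / "gwas_genes.txt")
            candidate_loci = {
                p: sorted(sim.locus_rates.get(p, {})) for p in sim.platforms
            }
        else:
            if config.expression_path is None:
                raise StageError("inputs: need either a simulation block or file paths")
            matrix = io.read_expression(config.expression_path)
            manifest["inputs"]["expression"] = _sha256(Path(config.expression_path))
            call_sets = {}
            for p in config.segment_paths:
                cs = io.read_segment_calls(p)
                call_sets[cs.platform] = cs
                manifest["inputs"][f"segments:{cs.platform}"] = _sha256(Path(p))
            annotation = io.read_annotation(config.annotation_path)
            manifest["inputs"]["annotation"] = _sha256(Path(config.annotation_path))
            mutation = (
                io.read_gene_list(config.mutation_path, "mutation")
                if config.mutation_path
                else GeneList("mutation", frozenset())
            )
            gwas = (
                io.read_gene_list(config.gwas_path, "gwas")
                if config.gwas_path
                else GeneList("gwas", frozenset())
            )
            candidate_loci = {
                p: sorted({c.locus for c in cs.calls}) for p, cs in call_sets.items()
            }
        manifest["stages"]["inputs"] = {
            "n_probes": matrix.n_probes,
            "n_samples": matrix.n_samples,
            "platforms": sorted(call_sets),
        }

        stage = "integrate"
        if config.hub_list_path:
            hub_genes = io.read_gene_list(config.hub_list_path, "hub")
            hubs = integrate.filter_hub_eligible(hub_genes, annotation)
            merged = hub_genes
        elif call_sets:
            min_fractions = {
                p: config.min_fractions.get(p, 0.15) for p in call_sets
            }
            hubs, merged, freq_tables = integrate.integrate(
                call_sets,
                candidate_loci,
                min_fractions,
                annotation,
                extra_lists=[mutation, gwas],
            )
            for p, table in freq_tables.items():
                table.to_csv(out / f"locus_frequencies_{p}.csv", index=False)
        elif mutation.symbols or gwas.symbols:
            merged = integrate.merge_gene_sets([mutation, gwas])
            hubs = integrate.filter_hub_eligible(merged, annotation)
        else:
            logger.warning("no hub inputs; falling back to full-network mode")
            hubs = integrate.HubGeneSet(frozenset(), frozenset())
            merged = GeneList("merged", frozenset())
        io.write_gene_list(sorted(hubs.symbols), out / "hub_genes.txt")
        io.write_gene_list(sorted(hubs.probe_ids), out / "hub_probes.txt")
        manifest["stages"]["integrate"] = {
            "merged_genes": len(merged),
            "hub_genes": len(hubs),
            "hub_probes": len(hubs.probe_ids),
        }

        stage = "network"
        hub_probes = hubs.probe_ids & set(matrix.probe_ids)
        if hubs.probe_ids and not hub_probes:
            logger.warning(
                "no hub probe is present in the expression matrix; "
                "falling back to full-network mode"
            )
        net_config = config.network_config(hub_probes, n_probes=matrix.n_probes)
        threshold = network.calibrate_mi_threshold(matrix, net_config)
        manifest["stages"]["calibrate"] = {"mi_threshold": threshold}
        net = network.build_network(matrix, net_config, threshold=threshold)
        components = network.connected_components(net)
        if hub_probes:
            net = network.filter_components_by_hubs(components, hub_probes)
        summary = network.network_summary(net)
        io.write_network(net, out / "network.tsv", "tsv")
        io.write_network(net, out / "network.graphml", "graphml")
        manifest["stages"]["network"] = {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "n_components": summary.n_components,
        }

        stage = "cluster"
        params = config.detection()
        if config.cluster_method == "cohesive":
            modules = cluster.grow_cohesive_modules(net, params)
        elif config.cluster_method == "kcore":
            modules = cluster.detect_kcore_complexes(net, params)
        else:
            raise StageError(f"cluster: unknown method {config.cluster_method!r}")
        if config.require_hub_in_module and hub_probes:
            modules = cluster.ModuleSet(
                [m for m in modules if m.members & hub_probes]
            )
        final = cluster.remove_subclusters(modules, config.containment_threshold)
        probe_to_gene = annotation.probe_to_gene()
        io.write_modules(modules, out / "modules_raw.csv", probe_to_gene)
        io.write_modules(final, out / "modules.csv", probe_to_gene)
        stats = cluster.module_stats(final, probe_to_gene)
        stats["per_module"].to_csv(out / "module_stats.csv", index=False)
        manifest["stages"]["cluster"] = {
            "modules_before_subcluster_removal": len(modules),
            "modules": stats["n_modules"],
            "genes_with_multiplicity": stats["genes_with_multiplicity"],
            "unique_genes": stats["unique_genes"],
        }

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        if isinstance(exc, StageError):
            raise
        raise StageError(f"{stage}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# the package's standard synthetic study conditions


def synthetic_default(
    out_dir: str,
    seed: int = 0,
    n_genes: int = 2000,
    n_samples: int = 150,
    n_modules: int = 10,
    module_size: int = 20,
    n_hub_modules: int = 5,
) -> PipelineConfig:
    """Reference synthetic scenario for the full pipeline.

    ``n_modules`` planted modules of ``module_size`` genes; the first
    ``n_hub_modules`` of them sit on copy-number loci that recur above
    threshold on all three platforms (gain rate 0.3 on the SNP-array
    cohort of 216, 0.6 on the two 9-cell-line CGH platforms), so their
    members become the hub set (100 hubs under the defaults).  Decoy
    loci recur below threshold or on a single platform only.  The
    mutation/GWAS lists are drawn from the hub-module genes, so hub
    eligibility never depends on the random annotation missingness
    applied to background genes.
    """
    n_modules = min(n_modules, n_genes // module_size)
    if n_modules < 1:
        raise ValueError("n_genes too small for even one planted module")
    n_hub_modules = min(n_hub_modules, n_modules)
    platforms = ["snp_array", "cgh", "array_cgh"]
    cfg = simulate.SimulationConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        noise_sd=0.5,
        seed=seed,
        platforms=platforms,
        platform_n_samples={"snp_array": 216, "cgh": 9, "array_cgh": 9},
    )
    genes = cfg.gene_labels()
    modules = []
    gene_loci: dict[str, Locus] = {}
    hub_genes: list[str] = []
    for m in range(n_modules):
        members = tuple(genes[m * module_size : (m + 1) * module_size])
        modules.append(
            simulate.ModulePlan(
                module_id=f"planted{m + 1}",
                member_genes=members,
                loading=1.0,
                hub_members=members,
            )
        )
        if m < n_hub_modules:
            hub_genes.extend(members)
            chrom = f"chrM{m + 1}"
            for j, g in enumerate(members):
                gene_loci[g] = Locus(chrom, j * 10_000, j * 10_000 + 5_000)
    cfg.modules = modules

    recurrent = [
        Locus(f"chrM{m + 1}", 0, module_size * 10_000) for m in range(n_hub_modules)
    ]
    decoy_low = Locus("chrD1", 0, 100_000)  # recurs below every threshold
    decoy_single = Locus("chrD2", 0, 100_000)  # recurs on the SNP platform only
    cfg.locus_rates = {
        "snp_array": {
            **{loc: (0.30, 0.0) for loc in recurrent},
            decoy_low: (0.05, 0.02),
            decoy_single: (0.50, 0.0),
        },
        "cgh": {
            **{loc: (0.60, 0.0) for loc in recurrent},
            decoy_low: (0.10, 0.10),
            decoy_single: (0.10, 0.0),
        },
        "array_cgh": {
            **{loc: (0.60, 0.0) for loc in recurrent},
            decoy_low: (0.10, 0.10),
            decoy_single: (0.10, 0.0),
        },
    }

    n_hub_genes = len(hub_genes)
    n_mut = min(60, n_hub_genes)
    n_gwas = min(41, max(1, n_hub_genes - n_mut + 1))
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        simulation=cfg,
        annotation_params={
            "frac_no_probe": 0.1,
            "frac_no_go": 0.2,
            "gene_loci": gene_loci,
            "always_eligible": hub_genes,
        },
        gene_list_sizes=(n_mut, n_gwas, 1),
        gene_list_universe=hub_genes,
        min_fractions={"snp_array": 0.15, "cgh": 0.40, "array_cgh": 0.40},
        network_params={"p_value": 0.05, "bonferroni": True, "null_permutations": 1000},
        detection_params={},
        cluster_method="cohesive",
    )
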