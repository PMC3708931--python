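"""Synthetic data with planted, machine-readable ground truth.

Everything the downstream stages consume can be generated here: an
expression matrix with planted overlapping co-expression modules (a
latent-factor model), per-platform gain/loss segment calls with
configured per-locus recurrence rates, mutation/GWAS gene lists of
requested sizes and overlap, and a gene annotation with tunable
fractions of genes lacking probes or GO terms.

Expression model: gene g in module m has profile

    x_g = sum_m a_m * f_m + eps,    f_m ~ N(0, 1) per sample,
                                    eps ~ N(0, sigma^2)

with loadings summed for genes in several modules; background genes
are pure noise.  Two genes sharing one module with loading a and noise
sigma therefore have pairwise correlation a^2 / (a^2 + sigma^2).

All generators are pure functions of (config, seed); independent
random streams are keyed by (seed, stage/platform label) so adding a
platform never perturbs another stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .integrate import (
    GAIN,
    LOSS,
    GeneAnnotation,
    GeneList,
    Locus,
    SegmentCall,
    SegmentCallSet,
)
from .network import ExpressionMatrix


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ModulePlan:
    """One planted co-expression module (ground truth)."""

    module_id: str
    member_genes: tuple[str, ...]
    loading: float = 1.0
    hub_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.member_genes = tuple(self.member_genes)
        self.hub_members = tuple(self.hub_members) or self.member_genes
        if not self.member_genes:
            raise ConfigurationError("module needs at least one member gene")
        if self.loading < 0:
            raise ConfigurationError("loading must be >= 0")
        if not set(self.hub_members) <= set(self.member_genes):
            raise ConfigurationError("hub_members must be a subset of member_genes")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    locus_rates maps platform -> {Locus: (gain_prob, loss_prob)}.
    gain_prob + loss_prob must be <= 1 (a sample-locus never carries
    both states).
    """

    n_genes: int
    n_samples: int
    modules: list[ModulePlan] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    platforms: list[str] = field(default_factory=list)
    locus_rates: dict[str, dict[Locus, tuple[float, float]]] = field(default_factory=dict)
    platform_n_samples: dict[str, int] = field(default_factory=dict)
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ConfigurationError("need n_genes >= 1 and n_samples >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        universe = set(self.gene_labels())
        for m in self.modules:
            if not set(m.member_genes) <= universe:
                raise ConfigurationError(
                    f"module {m.module_id} has members outside the gene universe"
                )
        for platform, rates in self.locus_rates.items():
            if platform not in self.platforms:
                raise ConfigurationError(f"rates given for unknown platform {platform!r}")
            for locus, (pg, pl) in rates.items():
                if not (0 <= pg <= 1 and 0 <= pl <= 1 and pg + pl <= 1):
                    raise ConfigurationError(
                        f"invalid (gain, loss) probabilities {pg, pl} at {locus}"
                    )

    def gene_labels(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"{self.gene_prefix}{i:0{width}d}" for i in range(self.n_genes)]


def probe_of(gene: str) -> str:
    """Default one-probe-per-gene naming used by the generator."""
    return f"{gene}_at"


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[ModulePlan]]:
    """Latent-factor expression matrix plus the planted ground truth.

    Probe ids follow :func:`probe_of`; identical config (and seed)
    yields a bit-identical matrix.
    """
    rng = substream(config.seed, "expression")
    genes = config.gene_labels()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n, s = config.n_genes, config.n_samples
    values = rng.normal(0.0, config.noise_sd, size=(n, s))
    for m in config.modules:
        factor = rng.standard_normal(s)
        for g in m.member_genes:
            values[gene_idx[g]] += m.loading * factor
    matrix = ExpressionMatrix(
        probe_ids=[probe_of(g) for g in genes],
        sample_ids=[f"S{j:03d}" for j in range(s)],
        values=values,
    )
    return matrix, list(config.modules)


def generate_segment_calls(config: SimulationConfig, platform: str) -> SegmentCallSet:
    """Bernoulli gain/loss calls for one platform.

    Per sample and locus one uniform draw decides the state: gain with
    the configured gain probability, loss with the loss probability,
    otherwise no call — a sample-locus never carries both states.
    Each platform has its own random stream.
    """
    if platform not in config.platforms:
        raise KeyError(f"unknown platform {platform!r}")
    rng = substream(config.seed, "segments", platform)
    n_samples = config.platform_n_samples.get(platform, config.n_samples)
    rates = config.locus_rates.get(platform, {})
    calls: list[SegmentCall] = []
    for j in range(n_samples):
        sample = f"{platform}_S{j:03d}"
        for locus, (p_gain, p_loss) in rates.items():
            u = rng.uniform()
            if u < p_gain:
                state = GAIN
            elif u < p_gain + p_loss:
                state = LOSS
            else:
                continue
            calls.append(SegmentCall(sample, locus.chrom, locus.start, locus.end, state))
    return SegmentCallSet(platform=platform, calls=calls, n_samples=n_samples)


def generate_gene_lists(
    n_mutation: int,
    n_gwas: int,
    n_overlap: int,
    universe: Sequence[str],
    seed: int = 0,
) -> tuple[GeneList, GeneList]:
    """Mutation and GWAS lists of exact sizes sharing exactly n_overlap genes."""
    if n_overlap > min(n_mutation, n_gwas):
        raise ConfigurationError("n_overlap cannot exceed either list size")
    needed = n_mutation + n_gwas - n_overlap
    universe = list(dict.fromkeys(universe))
    if needed > len(universe):
        raise ConfigurationError(
            f"universe of {len(universe)} genes too small for {needed} unique symbols"
        )
    rng = substream(seed, "gene-lists")
    chosen = list(rng.choice(universe, size=needed, replace=False))
    shared = chosen[:n_overlap]
    mutation = shared + chosen[n_overlap:n_mutation]
    gwas = shared + chosen[n_mutation:]
    return (
        GeneList(source="mutation", symbols=frozenset(mutation)),
        GeneList(source="gwas", symbols=frozenset(gwas)),
    )


def generate_annotation(
    config: SimulationConfig,
    *,
    frac_no_probe: float = 0.0,
    frac_no_go: float = 0.0,
    gene_loci: Mapping[str, Locus] | None = None,
    always_eligible: Sequence[str] = (),
) -> GeneAnnotation:
    """Gene annotation table with tunable missingness.

    Genes are laid out on four synthetic chromosomes in 10 kb steps
    unless ``gene_loci`` places them explicitly.  Random fractions of
    genes lose their probe or GO term; genes in ``always_eligible``
    keep both regardless (useful for planting hubs).
    """
    if not (0 <= frac_no_probe <= 1 and 0 <= frac_no_go <= 1):
        raise ConfigurationError("missingness fractions must be in [0, 1]")
    rng = substream(config.seed, "annotation")
    genes = config.gene_labels()
    protected = set(always_eligible)
    no_probe = rng.uniform(size=len(genes)) < frac_no_probe
    no_go = rng.uniform(size=len(genes)) < frac_no_go
    rows = []
    for i, g in enumerate(genes):
        if gene_loci and g in gene_loci:
            locus = gene_loci[g]
        else:
            chrom = f"chr{1 + i % 4}"
            start = (i // 4) * 10_000
            locus = Locus(chrom, start, start + 5_000)
        eligible_probe = g in protected or not no_probe[i]
        eligible_go = g in protected or not no_go[i]
        rows.append(
            {
                "gene": g,
                "probes": [probe_of(g)] if eligible_probe else [],
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "has_go_term": bool(eligible_go),
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def planted_module_config(
    n_modules: int = 5,
    module_size: int = 20,
    n_background: int = 50,
    n_samples: int = 200,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    overlap: int = 0,
) -> SimulationConfig:
    """Disjoint (or chain-overlapping) planted modules plus background genes.

    The default sizes are the package's standard planted-recovery
    condition: 5 modules x 20 genes, loading 1, noise 0.5, 200 samples.
    All module members are hubs.
    """
    n_genes = n_modules * (module_size - overlap) + overlap + n_background
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        noise_sd=noise_sd,
        seed=seed,
    )
    genes = cfg.gene_labels()
    modules = []
    step = module_size - overlap
    for m in range(n_modules):
        members = tuple(genes[m * step : m * step + module_size])
        modules.append(
            ModulePlan(
                module_id=f"planted{m + 1}",
                member_genes=members,
                loading=loading,
                hub_members=members,
            )
        )
    cfg.modules = modules
    return cfg
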