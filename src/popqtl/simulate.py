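"""Synthetic population-structured genotype / expression / survival data.

The generator mirrors the data a multistep ancestry-enriched cis-eQTL
analysis consumes:

* **Genotypes** follow the Balding–Nichols model: each SNP has an
  ancestral allele frequency ``p`` and each population draws its own
  frequency from a Beta distribution with mean ``p`` and variance
  ``F * p * (1 - p)``; individuals are then binomial(2) draws, so
  within-population Hardy–Weinberg equilibrium holds by construction.
  A designated minority of SNPs is *ancestry-enriched*: the target
  population drifts at ``fst_differentiated`` (conditioned on a minimum
  divergence from the ancestral frequency, emulating the ascertainment of
  variants preferentially prevalent in one ancestry) while the remaining
  populations drift at ``fst_background``.
* **Expression** is an additive cis model: a gene's log-intensity is the
  sum of ``beta * dosage`` over its planted eQTLs plus Gaussian noise.
* **Survival** times are exponential with a proportional-hazards
  dependence on one gene's expression, with independent exponential
  censoring.

All three generators are pure functions of ``(config, config.seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix, PopulationPanel, SurvivalDataset

__all__ = [
    "GenomeMap",
    "SurvivalConfig",
    "SimulationConfig",
    "default_genome_map",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_survival",
]

_GENO_STREAM, _EXPR_STREAM, _SURV_STREAM = 11, 13, 17


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GenomeMap:
    """SNP and gene placements plus the designated drifted-SNP set."""

    snps: pd.DataFrame  # columns: rsid, chrom, pos
    genes: GeneAnnotation
    differentiated_rsids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        known = set(self.snps["rsid"])
        unknown = [r for r in self.differentiated_rsids if r not in known]
        if unknown:
            raise ConfigError(f"differentiated rsids not in map: {unknown}")


def default_genome_map(
    n_snps: int = 935,
    n_differentiated: int = 4,
    chrom: str = "1",
    snp_spacing: int = 10_000,
    gene_length: int = 20_000,
    planted_gene_offsets: tuple[int, ...] = (30_000, 120_000, 1_200_000, 1_500_000),
    n_decoy_genes: int = 3,
) -> GenomeMap:
    """One-chromosome layout: SNPs every ``snp_spacing`` bp, genes of
    ``gene_length`` bp.

    Each designated drifted SNP gets a companion gene placed
    ``planted_gene_offsets[k]`` bp downstream; the default offsets put
    some planted eQTL pairs inside and some outside a 0.5–1 Mb cis
    window, so window assignment is exercised in both directions.
    Decoy genes carry no effects.
    """
    if n_differentiated > n_snps:
        raise ConfigError("n_differentiated exceeds n_snps")
    positions = snp_spacing * np.arange(1, n_snps + 1)
    snps = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": positions,
        }
    )
    diff_idx = [(k + 1) * n_snps // (n_differentiated + 1) for k in range(n_differentiated)]
    diff_rsids = tuple(snps["rsid"].iloc[diff_idx])
    rows = []
    for k, i in enumerate(diff_idx):
        offset = planted_gene_offsets[k % len(planted_gene_offsets)]
        start = int(positions[i]) + offset
        rows.append((f"GENE_{diff_rsids[k]}", chrom, start, start + gene_length - 1, "+"))
    chrom_span = int(positions[-1]) + 2_000_000
    for j in range(n_decoy_genes):
        start = (j + 1) * chrom_span // (n_decoy_genes + 1) + 5_123
        rows.append((f"DECOY_{j + 1}", chrom, start, start + gene_length - 1, "-"))
    genes = GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    return GenomeMap(snps=snps, genes=genes, differentiated_rsids=diff_rsids)


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 0.02  # events / month
    log_hazard_per_expression_unit: float = 0.5
    censoring_rate: float = 0.015  # events / month

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ConfigError("hazard and censoring rates must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a three-ancestry panel (200 samples each, the scale
    of a HapMap-style reference panel subset) with 935 candidate SNPs of
    which 4 are strongly enriched in the target ancestry — a funnel of
    the shape the pipeline is designed to traverse.
    """

    n_populations: int = 3
    samples_per_population: int = 200
    n_snps: int = 935
    fst_background: float = 0.01
    fst_differentiated: float = 0.25
    n_differentiated: int = 4
    ancestral_freq_range: tuple[float, float] = (0.2, 0.8)
    min_target_divergence: float = 0.2
    population_names: tuple[str, ...] | None = None
    target_population: str | None = None
    genome_map: GenomeMap | None = None
    eqtl_effects: Mapping[tuple[str, str], float] | None = None
    noise_sd: float = 1.0
    low_r2_fraction: float = 0.05
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2 or self.samples_per_population < 2:
            raise ConfigError("need >= 2 populations of >= 2 samples")
        if self.n_snps < 1:
            raise ConfigError("need >= 1 SNP")
        for name, f in (("fst_background", self.fst_background),
                        ("fst_differentiated", self.fst_differentiated)):
            if not (0 <= f < 1):
                raise ConfigError(f"{name} must lie in [0, 1); got {f}")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ConfigError("ancestral_freq_range must be inside (0, 1)")
        if self.n_differentiated > self.n_snps:
            raise ConfigError("n_differentiated exceeds n_snps")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 <= self.low_r2_fraction <= 1):
            raise ConfigError("low_r2_fraction must lie in [0, 1]")
        if self.population_names is None:
            names = (("CEU", "CHB", "JPT") if self.n_populations == 3
                     else tuple(f"POP{i + 1}" for i in range(self.n_populations)))
            object.__setattr__(self, "population_names", names)
        if len(self.population_names) != self.n_populations:
            raise ConfigError("population_names length mismatch")
        if self.target_population is None:
            object.__setattr__(self, "target_population", self.population_names[-1])
        if self.target_population not in self.population_names:
            raise ConfigError(f"target population {self.target_population!r} unknown")
        if self.genome_map is None:
            object.__setattr__(
                self,
                "genome_map",
                default_genome_map(self.n_snps, self.n_differentiated),
            )
        if len(self.genome_map.snps) != self.n_snps:
            raise ConfigError("genome map SNP count != n_snps")
        if len(self.genome_map.differentiated_rsids) != self.n_differentiated:
            raise ConfigError("genome map differentiated count != n_differentiated")
        if self.eqtl_effects is None:
            effects = {
                (rsid, f"GENE_{rsid}"): 1.0
                for rsid in self.genome_map.differentiated_rsids
                if f"GENE_{rsid}" in set(self.genome_map.genes.gene_ids)
            }
            object.__setattr__(self, "eqtl_effects", effects)
        known_snps = set(self.genome_map.snps["rsid"])
        known_genes = set(self.genome_map.genes.gene_ids)
        for (rsid, gene_id), beta in self.eqtl_effects.items():
            if rsid not in known_snps:
                raise ConfigError(f"eqtl effect references unknown SNP {rsid!r}")
            if gene_id not in known_genes:
                raise ConfigError(f"eqtl effect references unknown gene {gene_id!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _beta_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols subpopulation frequency draw (elementwise)."""
    if f == 0:
        return np.array(p, dtype=float, copy=True)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationPanel, set[str]]:
    """Draw the multi-population genotype matrix.

    Returns the genotypes, the sample→population panel, and the ground
    truth: the set of differentiated (target-enriched) rsids.
    """
    rng = _rng(config, _GENO_STREAM)
    gmap = config.genome_map
    n_snps = config.n_snps
    k = config.n_populations
    spp = config.samples_per_population
    lo, hi = config.ancestral_freq_range

    p_anc = rng.uniform(lo, hi, n_snps)
    freqs = np.empty((k, n_snps))
    for i in range(k):
        freqs[i] = _beta_draw(rng, p_anc, config.fst_background)

    target_idx = config.population_names.index(config.target_population)
    rsid_index = {r: j for j, r in enumerate(gmap.snps["rsid"])}
    for rsid in gmap.differentiated_rsids:
        j = rsid_index[rsid]
        freqs[target_idx, j] = _divergent_frequency(
            rng, float(p_anc[j]), config.fst_differentiated, config.min_target_divergence
        )

    calls = np.empty((k * spp, n_snps), dtype=np.int16)
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for i, pop in enumerate(config.population_names):
        calls[i * spp:(i + 1) * spp] = rng.binomial(2, freqs[i], size=(spp, n_snps))
        for s in range(spp):
            sid = f"{pop}_{s:03d}"
            sample_ids.append(sid)
            assignments[sid] = pop

    low = rng.random(n_snps) < config.low_r2_fraction
    r2 = np.where(low, rng.uniform(0.20, 0.25, n_snps), rng.uniform(0.25, 1.0, n_snps))

    variants = pd.DataFrame(
        {
            "rsid": gmap.snps["rsid"].to_numpy(),
            "chrom": gmap.snps["chrom"].to_numpy(),
            "pos": gmap.snps["pos"].to_numpy(),
            "ref": "A",
            "alt": "G",
            "r2": r2,
        }
    )
    gm = GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)
    return gm, PopulationPanel(assignments), set(gmap.differentiated_rsids)


def _divergent_frequency(
    rng: np.random.Generator, p: float, f: float, min_div: float, max_tries: int = 1000
) -> float:
    """Target-population frequency, conditioned on |f_t - p| >= min_div.

    Rejection-samples the Balding–Nichols Beta; if the condition is
    infeasible within ``max_tries`` the frequency is pinned at the
    minimum divergence on a random feasible side (keeps the generator
    total for edge-case configs).
    """
    if f == 0:
        return p
    scale = (1.0 - f) / f
    for _ in range(max_tries):
        draw = float(rng.beta(p * scale, (1.0 - p) * scale))
        if abs(draw - p) >= min_div:
            return draw
    up_ok = p + min_div < 1.0
    down_ok = p - min_div > 0.0
    if up_ok and (not down_ok or rng.random() < 0.5):
        return p + min_div
    if down_ok:
        return p - min_div
    return p


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> ExpressionMatrix:
    """Additive cis-effect expression for every gene in the genome map."""
    rng = _rng(config, _EXPR_STREAM)
    genes = config.genome_map.genes.gene_ids
    n_samples = genotypes.n_samples
    values = rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))
    gene_row = {g: i for i, g in enumerate(genes)}
    known = set(genotypes.rsids)
    for (rsid, gene_id), beta in config.eqtl_effects.items():
        if rsid not in known:
            raise ConfigError(f"effect references SNP {rsid!r} absent from genotypes")
        dosage = genotypes.dosages(rsid).astype(float)
        if (dosage < 0).any():
            raise ConfigError(f"missing dosages for planted eQTL {rsid!r}")
        values[gene_row[gene_id]] += beta * dosage
    frame = pd.DataFrame(values, index=genes, columns=genotypes.sample_ids)
    return ExpressionMatrix(frame)


def simulate_survival(
    expression: ExpressionMatrix, gene_id: str, config: SimulationConfig
) -> SurvivalDataset:
    """Exponential proportional-hazards event times driven by one gene.

    Hazard for sample *i* is ``baseline_hazard * exp(loghr * x_i)``;
    censoring is an independent exponential clock; the recorded time is
    the earlier of the two, with ``event`` marking an observed event.
    """
    rng = _rng(config, _SURV_STREAM)
    x = expression.gene(gene_id).to_numpy(float)
    sc = config.survival
    hazard = sc.baseline_hazard * np.exp(sc.log_hazard_per_expression_unit * x)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / sc.censoring_rate, size=x.shape)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    table = pd.DataFrame(
        {
            "sample_id": expression.sample_ids,
            "time": time,
            "event": event,
            "expression": x,
        }
    )
    return SurvivalDataset(table)
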