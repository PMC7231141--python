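"""Per-variant quality control: imputation accuracy, MAF, Hardy–Weinberg.

A variant is retained when it clears all three screens:

* imputation accuracy ``r^2 >= r2_min`` (variants without an r² are
  assumed directly genotyped and pass),
* minor allele frequency ``maf >= maf_min``,
* Hardy–Weinberg equilibrium ``p >= hwe_p_min``.

All three are strict-inequality *exclusions*, so a variant sitting
exactly on a threshold passes. Frequencies and the HWE test are computed
on the pooled analysis samples by default; per-population HWE testing
(fail if any population deviates) is available and is what the pipeline
uses on structured cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import chdtrc, gammaln

from .core_io import MISSING, GenotypeMatrix, PopulationPanel

logger = logging.getLogger("popqtl")

__all__ = [
    "QCThresholds",
    "VariantQCRecord",
    "allele_frequency",
    "hwe_test",
    "hwe_exact_test",
    "qc_filter",
]


@dataclass(frozen=True)
class QCThresholds:
    r2_min: float = 0.25
    maf_min: float = 0.10
    hwe_p_min: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("r2_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")


@dataclass
class VariantQCRecord:
    rsid: str
    n_called: int
    maf: float
    hwe_chi2: float
    hwe_p: float
    imputation_r2: float | None
    passed: bool
    fail_reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.fail_reasons) == 0)


def allele_frequency(calls: np.ndarray) -> tuple[float, float, int]:
    """Alt-allele frequency, MAF and call count of one dosage vector.

    Missing calls (:data:`~popqtl.core_io.MISSING`) are excluded
    pairwise. Raises on an all-missing vector (frequency undefined).
    """
    calls = np.asarray(calls)
    observed = calls[calls != MISSING]
    n_called = int(observed.size)
    if n_called == 0:
        raise ValueError("allele frequency undefined: all calls missing")
    alt_freq = float(observed.sum()) / (2.0 * n_called)
    return alt_freq, min(alt_freq, 1.0 - alt_freq), n_called


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Pearson chi-square test (1 df) of Hardy–Weinberg proportions.

    Expected genotype counts derive from the estimated allele frequency
    ``p̂``: ``(n p̂², 2n p̂ q̂, n q̂²)``. A monomorphic sample is in perfect
    equilibrium by convention: ``(0.0, 1.0)``.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p_alt = (2 * n_hom_alt + n_het) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 0.0, 1.0
    expected = (n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    return float(chi2), float(chdtrc(1, chi2))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg test p-value (sum of outcomes no more likely
    than the observed heterozygote count, conditional on allele counts).

    Preferred over the chi-square when any expected genotype count is
    small (< 5), where the asymptotic test is anticonservative.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    # log P(n_het | n, n_minor) up to a shared constant, over feasible
    # heterozygote counts of the same parity as n_minor
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het]
    if observed.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= observed[0] * (1 + 1e-12)].sum()))


def _genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    return (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )


def qc_filter(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    panel: PopulationPanel | None = None,
    hwe_per_population: bool = False,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, list[VariantQCRecord]]:
    """Apply the three variant filters; report metrics for every variant.

    Parameters
    ----------
    hwe_per_population
        When True (requires ``panel``), the HWE test runs within each
        population and a variant fails if *any* population deviates at
        the threshold; the reported chi2/p are those of the worst
        population. Pooled testing of a structured cohort exhibits a
        Wahlund heterozygote deficit, so the per-population mode is the
        appropriate one upstream of a between-population differentiation
        scan.
    hwe_method
        ``"chisq"`` (default) or ``"exact"``.

    Returns the genotype matrix restricted to passing variants, plus one
    :class:`VariantQCRecord` per input variant.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if hwe_per_population and panel is None:
        raise ValueError("per-population HWE requires a panel")
    if hwe_method not in ("chisq", "exact"):
        raise ValueError(f"unknown HWE method {hwe_method!r}")

    group_rows: list[np.ndarray]
    if hwe_per_population:
        panel.require(genotypes.sample_ids)
        pops = sorted({panel.population_of(s) for s in genotypes.sample_ids})
        sample_pop = np.array([panel.population_of(s) for s in genotypes.sample_ids])
        group_rows = [np.flatnonzero(sample_pop == p) for p in pops]
    else:
        group_rows = [np.arange(genotypes.n_samples)]

    records: list[VariantQCRecord] = []
    kept: list[int] = []
    warned_small = False
    r2s = genotypes.variants["r2"].to_numpy(float)
    for j in range(genotypes.n_variants):
        col = genotypes.calls[:, j]
        alt_freq, maf, n_called = allele_frequency(col)
        worst_chi2, worst_p = 0.0, 1.0
        for rows in group_rows:
            sub = col[rows]
            sub = sub[sub != MISSING]
            if sub.size == 0:
                continue
            counts = _genotype_counts(sub)
            if hwe_method == "exact":
                p = hwe_exact_test(*counts)
                chi2, _ = hwe_test(*counts)
            else:
                chi2, p = hwe_test(*counts)
                n_sub = sub.size
                q = (2 * counts[2] + counts[1]) / (2 * n_sub)
                min_expected = n_sub * min(q, 1 - q) ** 2
                if min_expected < 5 and not warned_small:
                    warned_small = True
                    logger.warning(
                        "HWE chi-square with expected genotype count < 5 "
                        "(first at %s); consider hwe_method='exact'",
                        genotypes.variants["rsid"].iloc[j],
                    )
            if p < worst_p:
                worst_chi2, worst_p = chi2, p
        reasons = set()
        r2 = r2s[j]
        if not np.isnan(r2) and r2 < thresholds.r2_min:
            reasons.add("low_r2")
        if maf < thresholds.maf_min:
            reasons.add("low_maf")
        if worst_p < thresholds.hwe_p_min:
            reasons.add("hwe_violation")
        records.append(
            VariantQCRecord(
                rsid=str(genotypes.variants["rsid"].iloc[j]),
                n_called=n_called,
                maf=maf,
                hwe_chi2=worst_chi2,
                hwe_p=worst_p,
                imputation_r2=None if np.isnan(r2) else float(r2),
                passed=not reasons,
                fail_reasons=frozenset(reasons),
            )
        )
        if not reasons:
            kept.append(j)
    logger.info("QC: %d / %d variants pass", len(kept), genotypes.n_variants)
    return genotypes.take_variants(kept), records


def qc_report_frame(records: list[VariantQCRecord]):
    """Flatten QC records into a tidy table (one row per variant)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "n_called": [r.n_called for r in records],
            "maf": [r.maf for r in records],
            "hwe_chi2": [r.hwe_chi2 for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "imputation_r2": [r.imputation_r2 for r in records],
            "pass": [r.passed for r in records],
            "fail_reasons": [",".join(sorted(r.fail_reasons)) for r in records],
        }
    )
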