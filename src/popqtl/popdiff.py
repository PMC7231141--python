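"""Cross-population allele-frequency differentiation (pipeline step 2).

For each variant we tabulate ref/alt allele counts per population
(a 2 x K contingency table), test homogeneity of allele frequencies with
a Pearson chi-square on K - 1 degrees of freedom, and select the
variants that are both significantly heterogeneous and *enriched* in a
target ancestry — operationalized as the target population's alt-allele
frequency being the strict extremum (maximum or minimum) across
populations.

Also provides a variance-based FST estimator used to validate the
Balding–Nichols generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core_io import MISSING, GenotypeMatrix, PopulationPanel

logger = logging.getLogger("popqtl")

__all__ = [
    "PopDiffRecord",
    "population_allele_counts",
    "chisq_differentiation",
    "compute_popdiff",
    "select_differential_snps",
    "fst_estimate",
]


class DegenerateTableError(ValueError):
    """The allele-count table admits no chi-square test."""


@dataclass
class PopDiffRecord:
    """Per-variant differentiation summary.

    ``allele_counts`` is a 2 x K integer table, rows (ref, alt), columns
    in ``populations`` order. ``degenerate_reason`` is set (and the test
    fields are NaN) when the variant could not be tested.
    """

    rsid: str
    populations: tuple[str, ...]
    allele_counts: np.ndarray
    alt_freqs: np.ndarray
    chi2: float = float("nan")
    df: int = 0
    p: float = float("nan")
    target_enriched: bool = False
    selected: bool = False
    degenerate_reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.degenerate_reason is None


def population_allele_counts(
    genotypes: GenotypeMatrix,
    panel: PopulationPanel,
    populations: list[str] | tuple[str, ...],
) -> list[PopDiffRecord]:
    """Build per-variant 2 x K allele-count tables.

    Alt count per population is the dosage sum over its non-missing
    calls; ref count is ``2 * n_called - alt``. A population with zero
    called samples for a variant marks that variant degenerate (it is
    skipped from testing, with the reason recorded).
    """
    panel.require(genotypes.sample_ids)
    present = {panel.population_of(s) for s in genotypes.sample_ids}
    absent = [p for p in populations if p not in present]
    if absent:
        raise ValueError(f"populations with no samples: {absent}")
    sample_pop = np.array([panel.population_of(s) for s in genotypes.sample_ids])
    masks = [sample_pop == p for p in populations]

    calls = genotypes.calls
    observed = calls != MISSING
    dose = np.where(observed, calls, 0)
    records: list[PopDiffRecord] = []
    alt_by_pop = np.stack([dose[m].sum(axis=0) for m in masks])  # K x V
    n_called_by_pop = np.stack([observed[m].sum(axis=0) for m in masks])
    rsids = genotypes.variants["rsid"].to_numpy()
    pops = tuple(populations)
    for j, rsid in enumerate(rsids):
        alt = alt_by_pop[:, j].astype(np.int64)
        n_called = n_called_by_pop[:, j].astype(np.int64)
        ref = 2 * n_called - alt
        table = np.vstack([ref, alt])  # 2 x K
        with np.errstate(invalid="ignore"):
            freqs = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
        reason = None
        if (n_called == 0).any():
            missing_pops = [pops[i] for i in np.flatnonzero(n_called == 0)]
            reason = f"no called samples in {','.join(missing_pops)}"
        records.append(
            PopDiffRecord(
                rsid=str(rsid),
                populations=pops,
                allele_counts=table,
                alt_freqs=freqs,
                degenerate_reason=reason,
            )
        )
    return records


def chisq_differentiation(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a 2 x K allele-count table.

    Returns ``(chi2, df, p)`` with ``df = K - 1``. An all-zero row or
    column makes the test undefined and raises
    :class:`DegenerateTableError`.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x K table, got shape {table.shape}")
    if table.sum() <= 0:
        raise DegenerateTableError("empty table")
    if (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("monomorphic across all populations")
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError("population without observed alleles")
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def compute_popdiff(
    genotypes: GenotypeMatrix,
    panel: PopulationPanel,
    populations: list[str] | tuple[str, ...] | None = None,
) -> list[PopDiffRecord]:
    """Allele counts + chi-square differentiation for every variant."""
    if populations is None:
        populations = panel.populations
    records = population_allele_counts(genotypes, panel, populations)
    n_skipped = 0
    for rec in records:
        if not rec.testable:
            n_skipped += 1
            continue
        try:
            rec.chi2, rec.df, rec.p = chisq_differentiation(rec.allele_counts)
        except DegenerateTableError as exc:
            rec.degenerate_reason = str(exc)
            n_skipped += 1
    if n_skipped:
        logger.info("popdiff: %d variants untestable (degenerate tables)", n_skipped)
    return records


def select_differential_snps(
    records: list[PopDiffRecord],
    target_population: str,
    p_threshold: float = 0.001,
) -> list[str]:
    """Pick ancestry-enriched variants.

    A variant is selected iff its differentiation test gives
    ``p < p_threshold`` (strict) *and* the target population's
    alt-allele frequency is strictly the maximum or strictly the minimum
    across populations (enrichment of either allele). Both clauses are
    recorded on the records (``target_enriched``, ``selected``).
    """
    selected: list[str] = []
    for rec in records:
        if target_population not in rec.populations:
            raise ValueError(
                f"target population {target_population!r} not among {rec.populations}"
            )
        if not rec.testable or np.isnan(rec.p):
            continue
        t = rec.populations.index(target_population)
        others = np.delete(rec.alt_freqs, t)
        ft = rec.alt_freqs[t]
        rec.target_enriched = bool(
            np.isfinite(ft)
            and ((ft > np.nanmax(others)) or (ft < np.nanmin(others)))
        )
        rec.selected = bool(rec.p < p_threshold and rec.target_enriched)
        if rec.selected:
            selected.append(rec.rsid)
    return selected


def popdiff_frame(records: list[PopDiffRecord]) -> pd.DataFrame:
    """Tidy per-variant table of frequencies and test results."""
    rows = []
    for rec in records:
        row = {"rsid": rec.rsid}
        for i, pop in enumerate(rec.populations):
            row[f"alt_freq_{pop}"] = rec.alt_freqs[i]
        row.update(
            chi2=rec.chi2,
            df=rec.df,
            p=rec.p,
            target_enriched=rec.target_enriched,
            selected=rec.selected,
            degenerate_reason=rec.degenerate_reason or "",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fst_estimate(
    genotypes: GenotypeMatrix, panel: PopulationPanel
) -> pd.Series:
    """Variance-based per-variant FST (simulator validation helper).

    ``FST = s² / (p̄ (1 - p̄))`` where ``s²`` is the sample variance
    (K - 1 denominator) of the subpopulation alt frequencies about the
    pooled frequency ``p̄``, clipped to [0, 1]. Variants monomorphic in
    the pooled sample are undefined (NaN).
    """
    populations = panel.populations
    if len(populations) < 2:
        raise ValueError("FST needs >= 2 populations")
    records = population_allele_counts(genotypes, panel, populations)
    out = {}
    k = len(populations)
    for rec in records:
        if not rec.testable:
            out[rec.rsid] = np.nan
            continue
        alt = rec.allele_counts[1].astype(float)
        tot = rec.allele_counts.sum(axis=0).astype(float)
        p_bar = alt.sum() / tot.sum()
        if p_bar in (0.0, 1.0):
            out[rec.rsid] = np.nan
            continue
        s2 = float(((rec.alt_freqs - p_bar) ** 2).sum() / (k - 1))
        out[rec.rsid] = float(np.clip(s2 / (p_bar * (1.0 - p_bar)), 0.0, 1.0))
    return pd.Series(out, name="fst")
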