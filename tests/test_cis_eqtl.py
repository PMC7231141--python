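"""Window assignment, per-pair OLS, BH adjustment and the funnel."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popqtl import ovcca_example as example
from popqtl.cis_eqtl import (
    FunnelConfig,
    UndefinedAssociationError,
    assign_cis_pairs,
    bh_adjust,
    cis_distance,
    regress_pair,
    run_funnel,
)
from popqtl.core_io import MISSING, GeneAnnotation
from popqtl.simulate import (
    SimulationConfig,
    default_genome_map,
    simulate_expression,
    simulate_genotypes,
)
from popqtl.variant_qc import QCThresholds


# ---------------------------------------------------------------------------
# cis-window assignment
# ---------------------------------------------------------------------------


def test_published_loci_window_assignment():
    snps = example.reference_snps()
    genes = example.reference_genes()
    pairs = {(p.rsid, p.gene_id): p for p in assign_cis_pairs(snps, genes, 500_000)}
    assert pairs[("rs4873815", "ZNF707")].distance == 28_310
    # 8p21.3 distal associations exceed half a megabase ...
    assert ("rs11136002", "TNFRSF10B") not in pairs
    pairs_1mb = {
        (p.rsid, p.gene_id): p for p in assign_cis_pairs(snps, genes, 1_000_000)
    }
    # ... but qualify at 1 Mb
    assert pairs_1mb[("rs11136002", "TNFRSF10B")].distance == 660_571
    assert pairs_1mb[("rs13259097", "RHOBTB2")].distance == 723_370


def test_distance_convention():
    assert cis_distance(50, 100, 200) == 50
    assert cis_distance(150, 100, 200) == 0  # inside the gene body
    assert cis_distance(250, 100, 200) == 50
    genes = GeneAnnotation(
        pd.DataFrame([("G", "1", 1000, 2000, ".")],
                     columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    snp = pd.DataFrame([("rs", "1", 3000)], columns=["rsid", "chrom", "pos"])
    # inclusive boundary: distance == window is paired
    assert len(assign_cis_pairs(snp, genes, 1000)) == 1
    assert len(assign_cis_pairs(snp, genes, 999)) == 0


def test_chromosome_naming_mismatch_is_an_error():
    genes = GeneAnnotation(
        pd.DataFrame([("G", "chr8", 1000, 2000, ".")],
                     columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    snp = pd.DataFrame([("rs", "8", 1500)], columns=["rsid", "chrom", "pos"])
    with pytest.raises(ValueError, match="naming mismatch"):
        assign_cis_pairs(snp, genes, 10_000)


# ---------------------------------------------------------------------------
# per-pair regression
# ---------------------------------------------------------------------------


def test_regress_pair_closed_form():
    dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)
    expr = np.array([0.1, 1.1, 2.1, -0.1, 0.9, 1.9])
    r = regress_pair(dosage, expr)
    assert r.beta == pytest.approx(1.0)
    assert r.df == 4


def test_regress_pair_perfect_fit():
    dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)
    r = regress_pair(dosage, 2 * dosage)
    assert r.beta == pytest.approx(2.0)
    assert r.p < 1e-12


def test_regress_pair_pairwise_complete():
    dosage = np.array([0, 1, 2, MISSING, 1], dtype=float)
    expr = np.array([0.0, 1.0, 2.0, 5.0, np.nan])
    r = regress_pair(dosage, expr)
    assert r.n == 3
    assert r.beta == pytest.approx(1.0)


def test_regress_pair_undefined_inputs():
    with pytest.raises(UndefinedAssociationError, match="constant dosage"):
        regress_pair(np.ones(10), np.random.default_rng(0).normal(size=10))
    with pytest.raises(UndefinedAssociationError, match="observations"):
        regress_pair(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    with pytest.raises(UndefinedAssociationError, match="constant expression"):
        regress_pair(np.array([0, 1, 2.0]), np.zeros(3))


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def brute_force_bh(p: np.ndarray, alpha: float) -> np.ndarray:
    """Literal step-up definition: largest k with p_(k) <= k*alpha/m."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def test_bh_examples():
    q, rej = bh_adjust(np.array([0.03]))
    assert q[0] == pytest.approx(0.03) and rej[0]
    q, rej = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert rej.all()  # largest k with p_(k) <= 0.05 k/4 is k=4
    q, rej = bh_adjust(np.array([0.001, 0.8]))
    assert np.allclose(q, [0.002, 0.8])
    assert rej.tolist() == [True, False]


@given(seed=st.integers(0, 5000), m=st.integers(1, 40))
def test_bh_matches_brute_force_step_up(seed, m):
    rng = np.random.default_rng(seed)
    p = rng.random(m) ** 2
    q, reject = bh_adjust(p, alpha=0.05)
    assert np.array_equal(reject, brute_force_bh(p, 0.05))
    assert (q >= p - 1e-12).all() and (q <= 1).all()
    # q preserves the p ordering
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_domain_error():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))


# ---------------------------------------------------------------------------
# power monotonicity and the funnel
# ---------------------------------------------------------------------------


def _power(beta: float, n: int, reps: int, rng, ols_batch) -> float:
    x = rng.binomial(2, 0.3, size=(reps, n)).astype(float)
    y = beta * x + rng.normal(0, 1, size=(reps, n))
    _, p = ols_batch(x, y)
    return float((p < 0.05).mean())


def test_power_monotone_in_effect_and_sample_size(ols_batch):
    rng = np.random.default_rng(12)
    by_beta = [_power(b, 100, 400, rng, ols_batch) for b in (0.1, 0.3, 0.8)]
    assert by_beta[0] < by_beta[1] < by_beta[2]
    by_n = [_power(0.25, n, 400, rng, ols_batch) for n in (30, 100, 300)]
    assert by_n[0] < by_n[1] < by_n[2]


def test_funnel_recovers_planted_signal(small_config, small_cohort):
    gm, panel, truth, em = small_cohort
    result = run_funnel(
        gm, panel, em, small_config.genome_map.genes,
        FunnelConfig(target_population="JPT"),
    )
    report = result.report
    assert report.snps_passing_qc <= report.snps_tested == 60
    assert report.differential_snps <= report.snps_passing_qc
    assert truth <= set(result.selected_rsids)
    sig = {(a.pair.rsid, a.pair.gene_id) for a in result.associations if a.significant}
    # the planted pair within the window is found; the one planted
    # 250 kb away is inside the 1 Mb window too
    assert set(small_config.eqtl_effects) <= sig
    assert report.distinct_cis_genes >= 2


def test_funnel_empty_stage_completes(small_config, small_cohort):
    gm, panel, _, em = small_cohort
    cfg = FunnelConfig(
        target_population="JPT",
        diff_p_threshold=1e-300,  # nothing can clear this
    )
    result = run_funnel(gm, panel, em, small_config.genome_map.genes, cfg)
    assert result.report.differential_snps == 0
    assert result.report.cis_pairs == 0
    assert result.report.distinct_cis_genes == 0
    assert result.associations == []


def test_funnel_rejects_unknown_candidates(small_config, small_cohort):
    gm, panel, _, em = small_cohort
    with pytest.raises(ValueError, match="candidate genes"):
        run_funnel(
            gm, panel, em, small_config.genome_map.genes,
            FunnelConfig(target_population="JPT"),
            candidate_gene_ids=["NOT_A_GENE"],
        )


def test_all_null_funnel_reports_no_cis_genes():
    """No drift and no effects: the funnel finds nothing almost always."""
    gmap = default_genome_map(80, 0)
    zero_hits = 0
    reps = 20
    for seed in range(reps):
        cfg = SimulationConfig(
            n_snps=80, n_differentiated=0, samples_per_population=60,
            fst_background=1e-6, genome_map=gmap, eqtl_effects={}, seed=seed,
        )
        gm, panel, _ = simulate_genotypes(cfg)
        em = simulate_expression(gm, cfg)
        res = run_funnel(gm, panel, em, gmap.genes,
                         FunnelConfig(target_population="JPT"))
        zero_hits += res.report.distinct_cis_genes == 0
    assert zero_hits >= int(0.95 * reps)
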