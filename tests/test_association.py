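"""Genotype→|1−SI| regression, Storey/BH q-values, hit filtering, group
t-tests, and EM-based pairwise LD."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from exonskip.association import (
    associate,
    filter_hits,
    genotype_group_ttest,
    pairwise_ld,
    qvalues,
    AssociationResult,
)
from exonskip.io import GenotypeMatrix, SnpRecord
from exonskip.simulate import simulate_ld_pair
from exonskip.splicing import SIMatrix


def make_inputs(dosage, si_row, snp="rs1", exon="g1:10-20"):
    samples = [f"s{i}" for i in range(len(dosage))]
    gt = GenotypeMatrix(
        pd.DataFrame([dosage], index=[snp], columns=samples, dtype=float), {snp: "G"}
    )
    si = SIMatrix(pd.DataFrame([si_row], index=[exon], columns=samples, dtype=float),
                  {exon: "g1"})
    return gt, si


def test_perfect_linear_fit():
    dosage = [0, 0, 1, 1, 2, 2]
    si_row = [1.0, 1.0, 0.9, 0.9, 0.8, 0.8]  # |1-SI| = 0.1 * dosage
    gt, si = make_inputs(dosage, si_row)
    (res,) = associate(gt, si, [("rs1", "g1:10-20")])
    assert res.beta == pytest.approx(0.1)
    assert res.r_squared == pytest.approx(1.0)
    assert res.p_value < 1e-10
    assert res.skipping_allele == "G"


def test_orientation_recode_flips_beta_and_allele():
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=60)
    y = 0.05 * dosage + rng.normal(0, 0.02, size=60)
    gt, si = make_inputs(list(dosage), list(1 - y))
    rec = {"rs1": SnpRecord("rs1", "1", 5, "A", "G")}
    (fwd,) = associate(gt, si, [("rs1", "g1:10-20")], snp_records=rec)
    gt2, _ = make_inputs(list(2 - dosage), list(1 - y))
    gt2.counted_allele["rs1"] = "A"
    (rev,) = associate(gt2, si, [("rs1", "g1:10-20")], snp_records=rec)
    assert rev.beta == pytest.approx(-fwd.beta)
    assert rev.p_value == pytest.approx(fwd.p_value)
    assert rev.r_squared == pytest.approx(fwd.r_squared)
    assert fwd.skipping_allele == "G" and rev.skipping_allele == "G"


def test_monomorphic_snp_flagged_untestable():
    gt, si = make_inputs([1, 1, 1, 1], [1.0, 0.9, 0.8, 1.1])
    (res,) = associate(gt, si, [("rs1", "g1:10-20")])
    assert not res.testable and np.isnan(res.q_value)


def test_missing_genotypes_dropped_pairwise():
    gt, si = make_inputs([0, 1, 2, np.nan, 0, 2], [1.0, 0.9, 0.8, 0.5, 1.0, 0.8])
    (res,) = associate(gt, si, [("rs1", "g1:10-20")])
    assert res.n_used == 5


# --- q-values --------------------------------------------------------------


def test_qvalues_all_ones():
    assert np.allclose(qvalues([1.0, 1.0, 1.0]), 1.0)


def test_qvalues_with_pi0_one_equal_bh(rng):
    p = rng.uniform(0, 1, size=200)
    q = qvalues(p, pi0=1.0)
    bh = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, bh)


def test_qvalues_monotone_in_p_rank_and_order_invariant(rng):
    p = np.concatenate([rng.uniform(0, 0.01, 30), rng.uniform(0, 1, 300)])
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    perm = rng.permutation(p.size)
    assert np.allclose(qvalues(p[perm])[np.argsort(perm)], q)


def test_qvalues_reject_out_of_range():
    with pytest.raises(ValueError):
        qvalues([0.5, 1.5])


def test_pi0_smoother_shrinks_q_under_signal(rng):
    """With abundant signal π0 < 1, so Storey q ≤ BH q."""
    p = np.concatenate([rng.uniform(0, 1e-4, 300), rng.uniform(0, 1, 200)])
    q = qvalues(p)
    bh = multipletests(p, method="fdr_bh")[1]
    assert np.all(q <= bh + 1e-12)
    assert q.min() < bh.min()


# --- filter ----------------------------------------------------------------


def make_result(p, q, r2):
    return AssociationResult("s", "e", beta=0.1, p_value=p, q_value=q, r_squared=r2, n_used=100)


@pytest.mark.parametrize(
    "p,q,r2,kept",
    [
        (0.05, 0.05, 0.5, False),   # p boundary strict
        (0.01, 0.08, 0.05, True),
        (0.01, 0.08, 0.03, False),  # R2 boundary strict
        (0.01, 0.10, 0.05, False),  # FDR boundary strict
    ],
)
def test_filter_hit_boundaries(p, q, r2, kept):
    assert bool(filter_hits([make_result(p, q, r2)])) is kept


# --- t-test ----------------------------------------------------------------


def test_identical_groups_t_zero_p_one():
    res = genotype_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)


def test_degenerate_group_untestable():
    assert not genotype_group_ttest([1.0], [1.0, 2.0]).testable
    assert not genotype_group_ttest([1.0, 1.0], [2.0, 2.0]).testable


def test_ttest_type_i_error_calibrated(rng):
    hits = 0
    reps = 2000
    for _ in range(reps):
        a = rng.normal(0, 1, size=15)
        b = rng.normal(0, 1, size=15)
        if genotype_group_ttest(a, b).p_value < 0.05:
            hits += 1
    assert hits / reps == pytest.approx(0.05, abs=0.015)


def test_ttest_power_under_two_sd_shift(rng):
    strong = sum(
        genotype_group_ttest(rng.normal(0, 1, 30), rng.normal(2, 1, 30)).p_value < 1e-3
        for _ in range(200)
    )
    assert strong / 200 > 0.95


# --- LD --------------------------------------------------------------------


def ld_matrix(a, b):
    samples = [f"s{i}" for i in range(len(a))]
    df = pd.DataFrame([a, b], index=["x", "y"], columns=samples, dtype=float)
    return GenotypeMatrix(df, {"x": "A", "y": "A"})


def test_identical_dosages_give_full_ld():
    a = [0, 1, 2, 0, 1, 2, 1, 0, 2, 1, 1, 0]
    res = pairwise_ld(ld_matrix(a, a), "x", "y")
    assert res.r2 == pytest.approx(1.0, abs=1e-6)
    assert res.d_prime == pytest.approx(1.0, abs=1e-6)


def test_independent_snps_have_near_zero_r2(rng):
    a, b = simulate_ld_pair(rng, 4000, 0.3, 0.4, r=0.0)
    res = pairwise_ld(ld_matrix(list(a), list(b)), "x", "y")
    assert res.r2 < 0.01


def test_dprime_one_with_unequal_frequencies_gives_r2_below_one(rng):
    # D at its positive bound with pA != pB: complete but not perfect LD
    a, b = simulate_ld_pair(rng, 4000, 0.1, 0.4, r=1.0)
    res = pairwise_ld(ld_matrix(list(a), list(b)), "x", "y")
    assert res.d_prime > 0.95
    assert res.r2 < 0.5


def test_em_recovers_simulated_r2(rng):
    target = 0.6
    a, b = simulate_ld_pair(rng, 6000, 0.3, 0.3, r=np.sqrt(target))
    res = pairwise_ld(ld_matrix(list(a), list(b)), "x", "y")
    assert res.r2 == pytest.approx(target, abs=0.06)


def test_monomorphic_ld_flagged():
    res = pairwise_ld(ld_matrix([0] * 12, [0, 1] * 6), "x", "y")
    assert not res.defined


def test_too_few_shared_samples_error():
    with pytest.raises(ValueError, match="shared"):
        pairwise_ld(ld_matrix([0, 1, 2], [0, 1, 2]), "x", "y")
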