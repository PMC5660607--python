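"""eQTL statistics: transform, OLS/Wald scan, cis window, permutation null, PRS."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cicnet import (
    PrsModel,
    fit_eqtl,
    generate_dag,
    inverse_normal,
    permutation_null,
    prs_score,
    simulate_expression,
    simulate_genotypes_and_cis,
)
from cicnet.synthetic import expression_with_genetics


# --- inverse normal transform -----------------------------------------------

def test_inverse_normal_symmetry():
    out = inverse_normal([1.0, 2.0, 3.0])
    assert out[1] == pytest.approx(0.0, abs=1e-12)
    assert out[0] == pytest.approx(-out[2], abs=1e-12)


def test_inverse_normal_rank_invariance():
    x = np.array([0.3, 5.0, 2.2, 9.1, 1.1])
    np.testing.assert_allclose(inverse_normal(x), inverse_normal(np.exp(x)),
                               atol=1e-12)


def test_inverse_normal_output_is_standard_normal():
    rng = np.random.default_rng(1)
    out = inverse_normal(rng.gamma(2.0, size=1000))  # skewed input
    assert abs(out.mean()) < 1e-6
    assert kstest(out, "norm").pvalue > 0.05


def test_inverse_normal_rejects_constant_input():
    with pytest.raises(ValueError):
        inverse_normal([1.0, 1.0, 1.0])


# --- the scan ----------------------------------------------------------------

def _toy_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    x = rng.binomial(2, 0.4, size=n).astype(float)
    geno = pd.DataFrame([x], index=["V1"], columns=samples)
    return geno, samples, x


def test_perfect_linear_fit_recovers_slope_and_intercept():
    geno, samples, x = _toy_data()
    y = 2.0 * x + 1.0
    expr = pd.DataFrame([y], index=["G1"], columns=samples)
    res = fit_eqtl(expr, geno, transform=False)
    assert res.loc[0, "beta_hat"] == pytest.approx(2.0, abs=1e-10)
    assert res.loc[0, "intercept"] == pytest.approx(1.0, abs=1e-10)
    assert res.loc[0, "wald_p"] < 1e-12


def test_scan_matches_statsmodels_ols():
    """Cross-check beta, SE and Wald p against an independent OLS fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    geno, samples, x = _toy_data(seed=3)
    y = 0.5 * x + rng.normal(size=len(x))
    expr = pd.DataFrame([y], index=["G1"], columns=samples)
    res = fit_eqtl(expr, geno, transform=False)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert res.loc[0, "beta_hat"] == pytest.approx(fit.params[1], rel=1e-8)
    assert res.loc[0, "se"] == pytest.approx(fit.bse[1], rel=1e-8)
    assert res.loc[0, "wald_p"] == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_cis_window_boundary_is_one_megabase():
    gene_coords = pd.DataFrame({"chrom": ["chr1"], "start": [2_000_000],
                                "end": [2_010_000]}, index=["G1"])
    variant_coords = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2"],
         "pos": [1_000_001, 999_999, 2_000_000]},
        index=["V_in", "V_out", "V_other"])
    rng = np.random.default_rng(4)
    samples = [f"S{i}" for i in range(30)]
    expr = pd.DataFrame(rng.normal(size=(1, 30)), index=["G1"], columns=samples)
    geno = pd.DataFrame(rng.binomial(2, 0.3, size=(3, 30)).astype(float),
                        index=["V_in", "V_out", "V_other"], columns=samples)
    res = fit_eqtl(expr, geno, gene_coords, variant_coords).set_index("variant")
    assert bool(res.loc["V_in", "cis"])        # 999,999 bases upstream of span
    assert not bool(res.loc["V_out", "cis"])   # 1,000,001 bases upstream
    assert not bool(res.loc["V_other", "cis"])  # different chromosome


def test_monomorphic_variants_skipped():
    geno, samples, x = _toy_data()
    geno.loc["V_mono"] = 1.0
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.normal(size=(2, len(samples))),
                        index=["G1", "G2"], columns=samples)
    res = fit_eqtl(expr, geno)
    assert set(res["variant"]) == {"V1"}


def test_planted_cis_effect_detected_with_correct_sign():
    sem = generate_dag(40, 2, rng_seed=6)
    hits = 0
    for seed in range(10):
        geno, gc, vc, truth = simulate_genotypes_and_cis(
            sem, 20, maf_range=(0.3, 0.3), beta_range=(0.8, 0.8),
            n_samples=200, rng_seed=seed)
        expr = expression_with_genetics(sem, geno, truth.cis_effects,
                                        rng_seed=seed + 100)
        res = fit_eqtl(expr, geno, gc, vc).set_index(["gene", "variant"])
        variant, (gene, beta) = next(iter(sorted(truth.cis_effects.items())))
        row = res.loc[(gene, variant)]
        if row["beta_hat"] > 0 and row["wald_p"] < 1e-3:
            hits += 1
    assert hits >= 9


def test_permutation_null_deterministic_and_fdr_behaviour():
    sem = generate_dag(20, 2, rng_seed=7)
    geno, gc, vc, _ = simulate_genotypes_and_cis(
        sem, 20, beta_range=(0.0, 0.0), n_samples=60, rng_seed=8)
    expr = simulate_expression(sem, 60, rng_seed=9)
    expr.columns = geno.columns
    n1 = permutation_null(expr, geno, n_rounds=2, rng_seed=10)
    n2 = permutation_null(expr, geno, n_rounds=2, rng_seed=10)
    np.testing.assert_array_equal(n1.null_p, n2.null_p)
    # global null: empirical FDR near 1 at a moderate threshold
    assert n1.fdr(0.2) > 0.5


def test_permutation_null_fdr_small_for_planted_signal():
    sem = generate_dag(30, 2, rng_seed=11)
    geno, gc, vc, truth = simulate_genotypes_and_cis(
        sem, 30, maf_range=(0.3, 0.5), beta_range=(1.5, 2.0),
        n_samples=150, rng_seed=12)
    expr = expression_with_genetics(sem, geno, truth.cis_effects, rng_seed=13)
    null = permutation_null(expr, geno, n_rounds=3, rng_seed=14)
    assert null.fdr(1e-8) < 0.1


# --- PRS ----------------------------------------------------------------------

def test_prs_weighted_sum():
    model = PrsModel([("V1", "A", 0.5), ("V2", "C", -0.2)])
    geno = pd.DataFrame([[2.0, 0.0], [1.0, 0.0]], index=["V1", "V2"],
                        columns=["s1", "s2"])
    scores, used = prs_score(model, geno)
    assert used == 2
    assert scores["s1"] == pytest.approx(0.5 * 2 - 0.2 * 1)  # 0.8
    assert scores["s2"] == 0.0


def test_prs_trims_to_genotyped_panel():
    model = PrsModel([("V1", "A", 0.5), ("V_missing", "T", 3.0)])
    geno = pd.DataFrame([[1.0]], index=["V1"], columns=["s1"])
    scores, used = prs_score(model, geno)
    assert used == 1 and scores["s1"] == pytest.approx(0.5)


def test_prs_linearity_and_zero_coefficient_irrelevance():
    model = PrsModel([("V1", "A", 0.4), ("V2", "G", 0.0)])
    g1 = pd.DataFrame([[1.0], [2.0]], index=["V1", "V2"], columns=["s"])
    g2 = pd.DataFrame([[1.0], [0.0]], index=["V1", "V2"], columns=["s"])
    s1, _ = prs_score(model, g1)
    s2, _ = prs_score(model, g2)
    s_sum, _ = prs_score(model, g1 + g2)
    assert s_sum["s"] == pytest.approx(s1["s"] + s2["s"])
    trimmed, _ = prs_score(PrsModel([("V1", "A", 0.4)]), g1)
    assert trimmed["s"] == pytest.approx(s1["s"])


def test_prs_errors_without_overlap():
    model = PrsModel([("VX", "A", 1.0)])
    geno = pd.DataFrame([[1.0]], index=["V1"], columns=["s1"])
    with pytest.raises(ValueError):
        prs_score(model, geno)


def test_prs_model_rejects_duplicates():
    with pytest.raises(ValueError):
        PrsModel([("V1", "A", 0.5), ("V1", "C", 0.2)])
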