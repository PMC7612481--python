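"""Generator correctness: frequency model, LD genotypes, summary statistics,
case-control and cohort phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transprs import synthetic as syn
from transprs import weighting as wt
from transprs.errors import DataError


def _model(m=50, fst=0.1, rho=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return syn.AncestryModel("pop", fst, [(m, rho)], rng.uniform(0.1, 0.9, m))


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def test_fst_zero_returns_ancestral():
    model = _model(fst=0.0)
    np.testing.assert_array_equal(
        syn.simulate_allele_freqs(model, seed=1), model.ancestral_freqs)


def test_freqs_inside_unit_interval():
    model = _model(fst=0.3)
    f = syn.simulate_allele_freqs(model, seed=1)
    assert ((f >= 0.01) & (f <= 0.99)).all()


def test_balding_nichols_moments():
    """Across many replicate draws the variance matches F p (1-p)."""
    p0, fst, reps = 0.4, 0.05, 100_000
    model = syn.AncestryModel("pop", fst, [(reps, 0.0)], np.full(reps, p0))
    draws = syn.simulate_allele_freqs(model, seed=2)
    assert draws.mean() == pytest.approx(p0, abs=0.005)
    assert draws.var() == pytest.approx(fst * p0 * (1 - p0), rel=0.05)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_dosages_are_hard_calls():
    gm = syn.simulate_genotypes(np.full(10, 0.5), [(10, 0.4)], 200, seed=3)
    assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}


def test_hardy_weinberg_proportions():
    p = 0.3
    gm = syn.simulate_genotypes(np.array([p]), [(1, 0.0)], 100_000, seed=4)
    counts = np.bincount(gm.dosages[:, 0].astype(int), minlength=3) / 100_000
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    np.testing.assert_allclose(counts, expected, atol=0.006)


def test_variant_means_track_freqs():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.2, 0.8, 20)
    gm = syn.simulate_genotypes(p, [(20, 0.5)], 20_000, seed=5)
    np.testing.assert_allclose(gm.dosages.mean(axis=0), 2 * p, atol=0.03)


def test_rho_zero_uncorrelated():
    gm = syn.simulate_genotypes(np.full(8, 0.5), [(8, 0.0)], 30_000, seed=6)
    corr = np.corrcoef(gm.dosages, rowvar=False)
    off = corr[np.triu_indices(8, 1)]
    assert np.abs(off).max() < 0.03


def test_ld_decay_with_lag():
    rho = 0.6
    gm = syn.simulate_genotypes(np.full(6, 0.5), [(6, rho)], 50_000, seed=7)
    corr = np.corrcoef(gm.dosages, rowvar=False)
    r_lag1 = np.mean([corr[i, i + 1] for i in range(5)])
    r_lag2 = np.mean([corr[i, i + 2] for i in range(4)])
    assert r_lag1 > r_lag2 > 0.05  # monotone decay


def test_fractional_dosage_option():
    gm = syn.simulate_genotypes(np.full(5, 0.5), [(5, 0.0)], 500, seed=8,
                                mean_info=0.8)
    assert ((gm.dosages >= 0) & (gm.dosages <= 2)).all()
    assert not set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}


def test_determinism_under_seed():
    a = syn.simulate_genotypes(np.full(5, 0.4), [(5, 0.3)], 50, seed=99)
    b = syn.simulate_genotypes(np.full(5, 0.4), [(5, 0.3)], 50, seed=99)
    np.testing.assert_array_equal(a.dosages, b.dosages)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def test_identity_ld_noise_free_recovers_gamma():
    rng = np.random.default_rng(9)
    m = 12
    gamma = rng.normal(0, 0.05, m)
    p = rng.uniform(0.1, 0.9, m)
    ss = syn.make_summary_stats(gamma, p, np.eye(m), 10_000, noise=False)
    scale = np.sqrt(2 * p * (1 - p))
    np.testing.assert_allclose(ss.df["beta"] * scale, gamma, atol=1e-12)


def test_joint_weights_round_trip_noise_free():
    rng = np.random.default_rng(10)
    m = 20
    gamma = rng.normal(0, 0.05, m)
    p = rng.uniform(0.1, 0.9, m)
    R = syn.ld_matrix([(5, 0.5)] * 4)
    ss = syn.make_summary_stats(gamma, p, R, 10_000, noise=False)
    std = wt.StandardizedEffects.from_summary_stats(ss)
    ws = wt.joint_weights(std, R, ridge_eps=0.0)
    rec = ws.df["weight"].to_numpy() * np.sqrt(2 * p * (1 - p))
    np.testing.assert_allclose(rec, gamma, atol=1e-8)


def test_noise_sd_matches_se():
    """Over replicate draws the empirical SD of beta-hat matches the SE."""
    m, n = 2000, 5000
    gamma = np.zeros(m)
    p = np.full(m, 0.5)
    ss = syn.make_summary_stats(gamma, p, np.eye(m), n, noise=True, seed=11)
    z = ss.df["beta"] / ss.df["se"]
    assert z.std() == pytest.approx(1.0, abs=0.05)


def test_non_psd_ld_fatal():
    R = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(DataError, match="positive semi-definite"):
        syn.make_summary_stats([0.1, 0.1], [0.5, 0.5], R, 1000)


# ---------------------------------------------------------------------------
# case-control
# ---------------------------------------------------------------------------

def test_null_or_ci_covers_one():
    from transprs import evaluation as ev
    from transprs import scoring as sc

    cohort, prs = syn.simulate_case_control(
        or_per_sd=1.0, n_case=2000, n_control=2000, seed=12)
    est = ev.fit_or_per_sd(sc.PRSVector(prs), cohort, n_pcs=0, adjust_stratum=False)
    assert est.ci_low <= 1.0 <= est.ci_high


def test_case_control_mean_shift():
    """Binormal limit: case mean exceeds control mean by ln(OR) score SDs."""
    or_per_sd = 1.5
    cohort, prs = syn.simulate_case_control(
        or_per_sd=or_per_sd, n_case=50_000, n_control=50_000, seed=13)
    case = prs[cohort.df["case"].to_numpy() == 1]
    ctrl = prs[cohort.df["case"].to_numpy() == 0]
    assert case.mean() - ctrl.mean() == pytest.approx(np.log(or_per_sd), abs=0.02)


def test_or_recovery_from_pool():
    """Resampling a real score pool recovers the target OR."""
    from transprs import evaluation as ev
    from transprs import scoring as sc

    rng = np.random.default_rng(14)
    pool = rng.standard_normal(400_000)
    cohort, prs = syn.simulate_case_control(
        scores=pool, or_per_sd=1.5, n_case=20_000, n_control=20_000, seed=14)
    est = ev.fit_or_per_sd(sc.PRSVector(prs), cohort, n_pcs=0, adjust_stratum=False)
    assert 1.45 <= est.estimate <= 1.55


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def test_cohort_null_hr():
    from transprs import evaluation as ev
    from transprs import scoring as sc

    cohort, prs = syn.simulate_cohort(hr_per_sd=1.0, n=20_000, seed=15,
                                      baseline_hazard=0.005)
    est = ev.fit_hr_per_sd(sc.PRSVector(prs), cohort, n_pcs=0)
    assert est.ci_low <= 1.0 <= est.ci_high


def test_event_count_closed_form():
    """Without censoring and at HR=1, events ~ n (1 - exp(-lambda T))."""
    lam, T, n = 0.002, 15.0, 100_000
    cohort, _ = syn.simulate_cohort(
        hr_per_sd=1.0, baseline_hazard=lam, censor_rate=0.0, followup=T,
        n=n, seed=16)
    expected = n * (1 - np.exp(-lam * T))
    observed = cohort.df["event"].sum()
    assert observed == pytest.approx(expected, rel=0.06)


def test_time_doubling_leaves_hr_unchanged():
    from transprs import evaluation as ev
    from transprs import scoring as sc

    cohort, prs = syn.simulate_cohort(hr_per_sd=1.6, n=5000, seed=17,
                                      baseline_hazard=0.01)
    est1 = ev.fit_hr_per_sd(sc.PRSVector(prs), cohort, n_pcs=0)
    df2 = cohort.df.copy()
    df2["time"] = 2 * df2["time"]
    est2 = ev.fit_hr_per_sd(sc.PRSVector(prs), syn.CohortTable(df2), n_pcs=0)
    assert est1.estimate == pytest.approx(est2.estimate, rel=1e-6)


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

def test_two_ancestries_separate_on_pc1(scenario):
    from sklearn.metrics import silhouette_score

    from transprs import evaluation as ev
    from transprs.io_formats import GenotypeMatrix

    eas, eur = scenario.genotypes["EAS"], scenario.genotypes["EUR"]
    merged = GenotypeMatrix(
        [f"A{i}" for i in range(eas.n_samples)] + [f"B{i}" for i in range(eur.n_samples)],
        eas.variant_ids,
        np.vstack([eas.dosages, eur.dosages]),
    )
    pcs = ev.compute_pcs(merged, 2)
    labels = [0] * eas.n_samples + [1] * eur.n_samples
    assert silhouette_score(pcs[["pc1"]].to_numpy(), labels) > 0.5
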