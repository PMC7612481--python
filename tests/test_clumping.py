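"""Greedy clumping against an exhaustive oracle; threshold grid selection."""

import numpy as np
import pandas as pd
import pytest

from transprs import clumping as cl
from transprs import synthetic as syn
from transprs.errors import DataError
from transprs.io_formats import CohortTable, SummaryStats

from conftest import make_sumstats


def oracle_greedy(df, r2_lookup, window, r2_max):
    """Independent re-statement of the greedy rule: visit in ascending
    (P, chrom, pos); keep iff every kept variant in the window has
    r2 <= r2_max.  Written directly from the selection rule, no shared code."""
    rows = sorted(df.to_dict("records"), key=lambda r: (r["pval"], r["chrom"], r["pos"]))
    kept = []
    for r in rows:
        ok = True
        for k in kept:
            if k["chrom"] == r["chrom"] and abs(k["pos"] - r["pos"]) <= window:
                key = frozenset((k["variant_id"], r["variant_id"]))
                if r2_lookup.get(key, 0.0) > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(r)
    return [r["variant_id"] for r in kept]


def random_instance(m, seed, window_scale=50_000):
    rng = np.random.default_rng(seed)
    df = syn.variant_table(m, spacing=1)
    df["pos"] = np.sort(rng.integers(0, window_scale * m // 4, m))
    df["eaf"] = rng.uniform(0.1, 0.9, m)
    df["beta"] = rng.normal(0, 0.1, m)
    df["se"] = rng.uniform(0.01, 0.05, m)
    df["pval"] = rng.uniform(1e-12, 1e-2, m)
    df["info"], df["n"] = 1.0, 10000
    # random symmetric r2 in [0,1]
    ids = df["variant_id"].tolist()
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = rng.uniform(0, 1) * np.sqrt(rng.uniform(0, 1))
    lookup = {
        frozenset((ids[i], ids[j])): R[i, j] ** 2
        for i in range(m) for j in range(i + 1, m)
    }
    return SummaryStats(df), cl.MatrixLD(ids, R), lookup


def test_identity_ld_keeps_everything():
    ss = make_sumstats(m=10)
    ld = cl.MatrixLD(ss.df["variant_id"].tolist(), np.eye(10))
    out = cl.dedup_high_ld(ss, ld)
    assert set(out.df["variant_id"]) == set(ss.df["variant_id"])


def test_dedup_lowest_p_survives():
    ss = make_sumstats(m=2, pvals=[1e-9, 1e-6], positions=[1000, 2000])
    R = np.array([[1.0, np.sqrt(0.95)], [np.sqrt(0.95), 1.0]])
    ld = cl.MatrixLD(["rs1", "rs2"], R)
    out = cl.dedup_high_ld(ss, ld)
    assert out.df["variant_id"].tolist() == ["rs1"]


def test_dedup_matches_oracle_random_instances():
    cfg = cl.ClumpConfig()
    for seed in range(25):
        ss, ld, lookup = random_instance(15, seed)
        out = cl.dedup_high_ld(ss, ld, cfg)
        expected = oracle_greedy(ss.df, lookup, cfg.dedup_window, cfg.dedup_r2)
        assert set(out.df["variant_id"]) == set(expected)


def test_greedy_clump_hand_trace():
    """Three variants at 0/100kb/400kb: #2 is in LD with retained #1 inside
    the window and is dropped; #3 is outside the window and kept."""
    ss = make_sumstats(m=3, pvals=[1e-10, 1e-9, 1e-8],
                       positions=[1_000_000, 1_100_000, 1_400_000])
    R = np.eye(3)
    R[0, 1] = R[1, 0] = 0.5   # r2 = 0.25 > 0.1
    ld = cl.MatrixLD(["rs1", "rs2", "rs3"], R)
    kept = cl.greedy_clump(ss, ld, cl.ClumpConfig())
    assert kept == ["rs1", "rs3"]


def test_zero_window_keeps_all():
    ss = make_sumstats(m=6)
    ld = cl.MatrixLD(ss.df["variant_id"].tolist(), np.full((6, 6), 0.99))
    cfg = cl.ClumpConfig(clump_window=0)
    # positions are distinct, so a zero-length window never captures a pair
    assert len(cl.greedy_clump(ss, ld, cfg)) == 6


def test_greedy_matches_oracle_many_seeds():
    cfg = cl.ClumpConfig(clump_window=100_000, clump_r2=0.1)
    for seed in range(30):
        ss, ld, lookup = random_instance(20, seed + 1000)
        kept = cl.greedy_clump(ss, ld, cfg)
        expected = oracle_greedy(ss.df, lookup, cfg.clump_window, cfg.clump_r2)
        assert kept == expected


def test_row_order_invariance(rng):
    cfg = cl.ClumpConfig(clump_window=100_000, clump_r2=0.2)
    ss, ld, _ = random_instance(20, 42)
    shuffled = SummaryStats(ss.df.sample(frac=1, random_state=1).reset_index(drop=True))
    assert cl.greedy_clump(ss, ld, cfg) == cl.greedy_clump(shuffled, ld, cfg)


def test_variant_absent_from_ld_treated_uncorrelated(caplog):
    ss = make_sumstats(m=3, pvals=[1e-9, 1e-8, 1e-7], positions=[100, 200, 300])
    ld = cl.MatrixLD(["rs1"], np.eye(1))  # rs2, rs3 unknown
    kept = cl.greedy_clump(ss, ld, cl.ClumpConfig())
    assert kept == ["rs1", "rs2", "rs3"]


# ---------------------------------------------------------------------------
# threshold grid
# ---------------------------------------------------------------------------

def _validation_setup(seed=0, m=40, n=800, n_causal=6, or_per_sd=2.0):
    """Genotypes + case/control labels driven by a known causal subset."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, m)
    gm = syn.simulate_genotypes(p, [(m, 0.0)], n, seed=rng,
                                variants=syn.variant_table(m))
    gamma = np.zeros(m)
    causal = rng.choice(m, n_causal, replace=False)
    gamma[causal] = rng.normal(0, 0.4, n_causal)
    Xs = (gm.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = Xs @ gamma
    z = (z - z.mean()) / z.std()
    y = rng.random(n) < 1 / (1 + np.exp(-np.log(or_per_sd) * z))
    cohort = CohortTable(pd.DataFrame({"sample_id": gm.sample_ids,
                                       "case": y.astype(int)}))
    # marginal stats from the same genotypes (simple per-variant regression)
    beta = np.array([np.polyfit(gm.dosages[:, j], y.astype(float), 1)[0]
                     for j in range(m)])
    resid_sd = y.std()
    se = resid_sd / (gm.dosages.std(axis=0) * np.sqrt(n))
    from scipy import stats as st
    pval = 2 * st.norm.sf(np.abs(beta / se))
    df = syn.variant_table(m)
    df["eaf"], df["beta"], df["se"] = p, beta, se
    df["pval"] = np.clip(pval, 1e-300, 1.0)
    df["info"], df["n"] = 1.0, n
    return SummaryStats(df), gm, cohort, causal


def test_single_variant_below_pmax():
    ss, gm, cohort, _ = _validation_setup(seed=3)
    df = ss.df.copy()
    df["pval"] = 0.5
    df.loc[0, "pval"] = 1e-5
    t, ws, curve = cl.threshold_grid_select(SummaryStats(df), gm, cohort)
    assert ws.m == 1 and ws.variant_ids == ["rs1"]


def test_no_variant_in_grid_is_error():
    ss, gm, cohort, _ = _validation_setup(seed=4)
    df = ss.df.copy()
    df["pval"] = 0.5
    with pytest.raises(DataError, match="empty PRS"):
        cl.threshold_grid_select(SummaryStats(df), gm, cohort)


def test_grid_endpoint_respected():
    """No variant with P above p_max is ever included."""
    ss, gm, cohort, _ = _validation_setup(seed=5)
    _, ws, curve = cl.threshold_grid_select(ss, gm, cohort)
    sel = ss.df.set_index("variant_id").loc[ws.variant_ids, "pval"]
    assert (sel <= 1e-3).all()
    assert (curve["threshold"] <= 1e-3).all()


def test_causal_scenario_beats_gws_only():
    """With mid-significance causal signal, the tuned threshold does at
    least as well as the genome-wide-significant-only PRS."""
    ss, gm, cohort, causal = _validation_setup(seed=6, n=1500)
    cfg = cl.ClumpConfig(p_min=1e-30, p_max=1e-3)
    t, ws, curve = cl.threshold_grid_select(ss, gm, cohort, cfg)
    best_auc = curve["auc"].max()
    strict = curve[curve["threshold"] <= 5e-8]
    if len(strict):
        assert best_auc >= strict["auc"].max() - 1e-12
    # tuned set contains most of the detectable causal signal
    causal_ids = {f"rs{i + 1}" for i in causal}
    detectable = causal_ids & set(ss.df[ss.df["pval"] < 1e-3]["variant_id"])
    if detectable:
        assert len(detectable & set(ws.variant_ids)) >= len(detectable) / 2


def test_nesting_monotone_in_threshold():
    ss, gm, cohort, _ = _validation_setup(seed=7)
    _, _, curve = cl.threshold_grid_select(ss, gm, cohort,
                                           cl.ClumpConfig(p_min=1e-30, p_max=1e-2))
    assert curve["threshold"].is_monotonic_increasing
    assert curve["n_variants"].is_monotonic_increasing


def test_dense_grid_equivalence():
    """Evaluating at observed P values equals a dense uniform threshold grid
    (piecewise constancy of the selected set in the threshold)."""
    from transprs.evaluation import auc_rank

    ss, gm, cohort, _ = _validation_setup(seed=8, m=25, n=600)
    cfg = cl.ClumpConfig(p_min=1e-30, p_max=1e-2)
    t_best, ws, curve = cl.threshold_grid_select(ss, gm, cohort, cfg)

    df = ss.df.sort_values("pval").reset_index(drop=True)
    X = gm.dosages[:, [gm.variant_ids.index(v) for v in df["variant_id"]]]
    y = cohort.df.set_index("sample_id").loc[gm.sample_ids, "case"].to_numpy()
    best = (-1.0, None)
    for t in np.geomspace(1e-30, 1e-2, 4000):
        mask = df["pval"].to_numpy() <= t
        if not mask.any():
            continue
        score = X[:, mask] @ df.loc[mask, "beta"].to_numpy()
        auc = auc_rank(score[y == 1], score[y == 0])
        if auc > best[0] + 1e-15:
            best = (auc, int(mask.sum()))
    assert best[0] == pytest.approx(curve["auc"].max(), abs=1e-12)
    assert best[1] == ws.m
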