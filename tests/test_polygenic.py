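"""LD, clumping, scoring conventions and the cross-validation engine."""

import numpy as np
import pandas as pd
import pytest

from linegwas import (
    ClumpParams,
    PolygenicScoreCV,
    SimulationConfig,
    clump,
    cross_validated_r2,
    ld_r2,
    permuted_null_profile,
    polygenic_score,
    simulate_panel,
    summarize_profiles,
)

from conftest import make_panel, make_phenotypes


def test_ld_r2_examples():
    panel = make_panel(np.array([
        [0, 0, 0, 2, 2],
        [2, 2, 2, 0, 2],
        [0, 0, 2, 0, 2],
        [2, 2, 0, 2, 2],
    ], dtype=float))
    assert ld_r2(panel, "v0", "v1") == pytest.approx(1.0)          # identical
    assert ld_r2(panel, "v0", "v2") == pytest.approx(0.0, abs=1e-12)  # orthogonal
    assert ld_r2(panel, "v2", "v3") == pytest.approx(1.0)          # sign-free
    assert ld_r2(panel, "v0", "v4") == 0.0                          # constant -> 0


def test_clump_manual_trace():
    # v0 best p; v1 within window and r2=1 -> removed; v2 on another chromosome
    panel = make_panel(
        np.array([
            [0, 0, 0],
            [2, 2, 2],
            [0, 0, 2],
            [2, 2, 0],
        ], dtype=float),
        chrom=["2L", "2L", "3R"],
        pos=[1000, 2000, 1500],
    )
    res = pd.DataFrame({"variant_id": ["v0", "v1", "v2"], "p": [1e-6, 1e-3, 1e-2]})
    kept = clump(res, panel, ClumpParams(r2_max=0.25, window=250_000))
    assert kept == ["v0", "v2"]


def test_clump_keeps_uncorrelated_and_r2max_boundary():
    rng = np.random.default_rng(0)
    dos = 2.0 * (rng.random((40, 6)) < 0.5)
    panel = make_panel(dos, pos=[100, 200, 300, 400, 500, 600])
    res = pd.DataFrame({"variant_id": [f"v{i}" for i in range(6)],
                        "p": np.linspace(1e-5, 0.5, 6)})
    kept_all = clump(res, panel, ClumpParams(r2_max=1.0, window=10**6))
    assert len(kept_all) == 6  # nothing exceeds r2 = 1
    # mutually orthogonal dosages: everything retained at any threshold
    ortho = make_panel(np.array([
        [0, 0, 0],
        [2, 0, 0],
        [0, 2, 0],
        [2, 2, 2],
        [0, 0, 2],
        [2, 2, 0],
        [0, 2, 2],
        [2, 0, 2],
    ], dtype=float), pos=[10, 20, 30])
    res3 = pd.DataFrame({"variant_id": ["v0", "v1", "v2"], "p": [0.1, 0.2, 0.3]})
    assert len(clump(res3, ortho, ClumpParams(r2_max=0.25, window=1000))) == 3


def test_score_conventions():
    panel = make_panel(np.array([[0.0, 0.0], [2.0, np.nan]]))
    w = pd.Series([2.0, 1.0], index=["v0", "v1"])
    s = polygenic_score(panel, w)
    # line 0: (0*2 + 0*1)/2 = 0 ; line 1: (2*2)/1 = 4 (missing SNP averaged out)
    assert s.tolist() == [0.0, 4.0]
    none = make_panel(np.array([[np.nan, np.nan], [0.0, 2.0]]))
    s2 = polygenic_score(none, w)
    assert np.isnan(s2.iloc[0])


def test_perfect_linear_recovery():
    # phenotype exactly a weighted dosage sum, no missing: R^2 = 1 at t=1
    rng = np.random.default_rng(1)
    dos = 2.0 * (rng.random((30, 10)) < 0.5)
    panel = make_panel(dos)
    beta = rng.standard_normal(10)
    y = dos @ beta + 50.0
    score = polygenic_score(panel, pd.Series(beta, index=[f"v{i}" for i in range(10)]))
    # score is the mean rather than sum of beta*dosage: still perfectly
    # correlated with y
    r = np.corrcoef(score, y)[0, 1]
    assert r * r == pytest.approx(1.0, abs=1e-12)


def test_threshold_nesting_within_repeat(sim_small_qc):
    panel, phenos, _, covars = sim_small_qc
    prof = cross_validated_r2(panel, phenos, covars,
                              thresholds=(1.0, 0.5, 0.1, 0.01), n_repeats=3, seed=5)
    for _, grp in prof.groupby("repeat"):
        ordered = grp.sort_values("threshold", ascending=False)["n_snps"].to_numpy()
        assert (np.diff(ordered) <= 0).all()


def test_r2_equals_single_regressor_ols():
    rng = np.random.default_rng(2)
    s = rng.standard_normal(50)
    y = 0.3 * s + rng.standard_normal(50)
    from linegwas.polygenic import _r2_score_vs_phenotype
    r2 = _r2_score_vs_phenotype(s, y)
    X = np.column_stack([np.ones(50), s])
    bh = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ bh
    r2_ols = 1 - resid.var() / y.var()
    assert r2 == pytest.approx(r2_ols, abs=1e-12)


def test_permutation_leaves_genotypes_untouched(sim_small_qc):
    panel, phenos, _, covars = sim_small_qc
    before = panel.dosages.copy()
    permuted_null_profile(panel, phenos, covars,
                          thresholds=(1.0, 0.1), n_perm=2, seed=6)
    np.testing.assert_array_equal(panel.dosages, before)


def test_null_floor_positive_and_profiles_deterministic(sim_small_qc):
    panel, phenos, _, covars = sim_small_qc
    null1 = permuted_null_profile(panel, phenos, covars,
                                  thresholds=(1.0, 0.1), n_perm=5, seed=7)
    null2 = permuted_null_profile(panel, phenos, covars,
                                  thresholds=(1.0, 0.1), n_perm=5, seed=7)
    pd.testing.assert_frame_equal(null1, null2)
    assert null1["r2"].dropna().mean() > 0.0


def test_gap_increases_with_heritability():
    # observed-vs-null mean R^2 gap grows with planted H^2 in {0, 0.2, 0.4}
    gaps = []
    for h2 in (0.0, 0.2, 0.4):
        cfg = SimulationConfig(
            n_snps=1200, n_causal=80 if h2 > 0 else 0, target_H2=h2,
            effect_scaling="fill" if h2 > 0 else "fixed", seed=23,
        )
        panel, phenos, _ = simulate_panel(cfg)
        obs = cross_validated_r2(panel, phenos, None,
                                 thresholds=(1.0, 0.1), n_repeats=12, seed=24)
        null = permuted_null_profile(panel, phenos, None,
                                     thresholds=(1.0, 0.1), n_perm=12, seed=25)
        gaps.append(obs["r2"].mean() - null["r2"].mean())
    assert gaps[0] < gaps[1] < gaps[2]
    assert abs(gaps[0]) < 0.05


def test_estimator_wrapper(sim_small_qc):
    panel, phenos, _, covars = sim_small_qc
    est = PolygenicScoreCV(thresholds=(1.0, 0.1), n_repeats=3, seed=8)
    est.fit(panel, phenos, covars)
    assert {"mean_r2", "null_mean_r2", "welch_p"} <= set(est.summary_.columns)
    assert est.get_params()["r2_max"] == 0.25


def test_summarize_without_null(sim_small_qc):
    panel, phenos, _, covars = sim_small_qc
    obs = cross_validated_r2(panel, phenos, covars,
                             thresholds=(1.0,), n_repeats=2, seed=9)
    s = summarize_profiles(obs)
    assert "welch_p" not in s.columns
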