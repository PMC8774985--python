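"""The moderation model: moments, likelihood, drop series, curves."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from acemod.ace import ACEParams, expected_cov_ace, fit_model
from acemod.moderation import (
    DROP_SPECS,
    ModerationParams,
    aic,
    aic_classic,
    chi2_pvalue,
    fit_moderation,
    moderated_cov,
    moderated_mean,
    moderation_series,
    neg2_loglik_moderated,
    variance_curves,
)
from acemod.simulate import SimulationConfig, generate_dataset, paper_like_config

from conftest import oracle_moderated_deviance


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def test_moderated_mean_linear_form():
    p = ModerationParams(m=0.0, beta_m=0.3)
    assert moderated_mean(p, 2.0) == pytest.approx(0.6)
    p0 = ModerationParams(m=1.2, beta_m=0.0)
    assert moderated_mean(p0, 5.0) == 1.2


def test_moderated_cov_hand_arithmetic():
    p = ModerationParams(a=0.6, beta_a=0.2, c=0.0, e=0.8, beta_e=-0.1)
    S = moderated_cov(p, 0.0, 1.0, "DZ")
    assert S[0, 0] == pytest.approx(1.00)
    assert S[1, 1] == pytest.approx(1.13)
    assert S[0, 1] == pytest.approx(0.24)  # 0.5 * 0.6 * 0.8


def test_moderated_cov_reduces_bitwise_to_unmoderated():
    p = ModerationParams(a=0.61, c=0.23, e=0.74, m=0.1)
    base = ACEParams(a=0.61, c=0.23, e=0.74, mu=0.1)
    for zyg in ("MZ", "DZ"):
        for M1, M2 in ((0.0, 0.0), (1.3, -0.7)):
            np.testing.assert_array_equal(
                moderated_cov(p, M1, M2, zyg), expected_cov_ace(base, zyg))


def test_moderated_cov_degenerate_mz_correlation_one():
    # e-path zero at M: co-twin correlation exactly 1 for MZ at matched M
    p = ModerationParams(a=0.8, e=0.5, beta_e=-0.5)
    S = moderated_cov(p, 1.0, 1.0, "MZ")
    r = S[0, 1] / math.sqrt(S[0, 0] * S[1, 1])
    assert r == pytest.approx(1.0, abs=1e-12)


@given(st.tuples(*[st.floats(-1.0, 1.0) for _ in range(8)]),
       st.floats(-3, 3), st.floats(-3, 3), st.booleans())
def test_moderated_cov_positive_semidefinite(vals, M1, M2, mz):
    p = ModerationParams(*vals)
    S = moderated_cov(p, M1, M2, "MZ" if mz else "DZ")
    ev = np.linalg.eigvalsh(S)
    assert ev.min() >= -1e-10


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_moderated_deviance_matches_oracle(paper_arrays):
    y1, y2, m1, m2, is_mz = paper_arrays
    sl = slice(0, 40)
    rng = np.random.default_rng(8)
    for _ in range(10):
        p = ModerationParams(
            a=rng.uniform(0.3, 0.9), c=rng.uniform(0, 0.4),
            e=rng.uniform(0.4, 1.0), beta_a=rng.normal(0, 0.15),
            beta_c=rng.normal(0, 0.1), beta_e=rng.normal(0, 0.1),
            m=rng.normal(0, 0.3), beta_m=rng.normal(0, 0.3))
        got = neg2_loglik_moderated(p, y1[sl], y2[sl], m1[sl], m2[sl], is_mz[sl])
        expect = oracle_moderated_deviance(p, y1[sl], y2[sl], m1[sl], m2[sl],
                                           is_mz[sl])
        assert got == pytest.approx(expect, abs=1e-8)


# ---------------------------------------------------------------------------
# Fitting and the drop series
# ---------------------------------------------------------------------------

def test_ep_bookkeeping():
    assert len(DROP_SPECS["AE"]["full"]) == 6
    assert len(DROP_SPECS["AE"]["drop_mean"]) == 5
    assert len(DROP_SPECS["AE"]["drop_variance"]) == 4
    assert len(DROP_SPECS["AE"]["drop_all"]) == 3
    assert len(DROP_SPECS["ACE"]["full"]) == 8


def test_drop_all_equals_unmoderated_ae(paper_arrays):
    y1, y2, m1, m2, is_mz = paper_arrays
    mod = fit_moderation(y1, y2, m1, m2, is_mz, "drop_all", "AE")
    ae = fit_model(y1, y2, is_mz, "AE")
    assert mod.neg2lnL == pytest.approx(ae.neg2lnL, abs=1e-4)
    assert mod.ep == 3 and mod.df == 2 * 1518 - 3


def test_full_fit_on_unmoderated_data_matches_ae():
    p = ModerationParams(a=math.sqrt(0.4), e=math.sqrt(0.6))
    cfg = SimulationConfig(n_mz_pairs=400, n_dz_pairs=400, params=p,
                           hyperactivity_params=p, seed=19)
    ds, _ = generate_dataset(cfg)
    y1, y2, is_mz = ds.pair_arrays("y_inattention")
    m1, m2, _ = ds.pair_arrays("m_unhealthy")
    full = fit_moderation(y1, y2, m1, m2, is_mz, "full", "AE")
    ae = fit_model(y1, y2, is_mz, "AE")
    # full model can only improve on the nested no-moderation fit
    assert full.neg2lnL <= ae.neg2lnL + 1e-6
    assert full.neg2lnL >= ae.neg2lnL - 20.0  # chance improvement only


def test_moderation_series_structure_and_ordering(paper_arrays):
    y1, y2, m1, m2, is_mz = paper_arrays
    comp, fits = moderation_series(y1, y2, m1, m2, is_mz, n_starts=1)
    assert [r.model for r in comp.rows] == [
        "Full model", "Drop moderation of the mean components",
        "Drop moderation of the variance components", "Drop all moderation"]
    full_dev = fits["full"].neg2lnL
    for d in ("drop_mean", "drop_variance", "drop_all"):
        assert fits[d].neg2lnL >= full_dev - 1e-6
    for r in comp.rows:
        if r.chi2 is not None:
            assert r.chi2 >= -1e-6 and 0 <= r.p_value <= 1
        assert r.aic == pytest.approx(r.neg2lnL - 2 * r.df)
        assert r.aic_classic == pytest.approx(r.neg2lnL + 2 * r.ep)
    # generating model has real mean and variance moderation
    assert comp.row("Drop moderation of the mean components").p_value < 0.001
    assert "significant" in comp.verdict


def test_moderation_power_at_published_sample_size():
    """Strong variance moderation: drop-variance LRT significant in >= 80%
    of 100 replicates at 1518 pairs."""
    hits = 0
    reps = 100
    for s in range(reps):
        ds, _ = generate_dataset(paper_like_config(seed=20000 + s))
        y1, y2, is_mz = ds.pair_arrays("y_inattention")
        m1, m2, _ = ds.pair_arrays("m_unhealthy")
        full = fit_moderation(y1, y2, m1, m2, is_mz, "full", "AE", n_starts=1)
        dv = fit_moderation(y1, y2, m1, m2, is_mz, "drop_variance", "AE",
                            n_starts=1)
        stat = max(dv.neg2lnL - full.neg2lnL, 0.0)
        hits += chi2_pvalue(stat, 2) < 0.05
    assert hits / reps >= 0.80


def test_moderation_null_mean_moderation_only():
    """With no variance moderation generated, the drop-all test (against a
    model that still carries mean moderation) is non-significant in >= 90%
    of replicates."""
    p = ModerationParams(a=math.sqrt(0.4), e=math.sqrt(0.6), beta_m=0.25)
    hits = 0
    reps = 100
    for s in range(reps):
        cfg = SimulationConfig(n_mz_pairs=400, n_dz_pairs=400, params=p,
                               hyperactivity_params=p, seed=30000 + s)
        ds, _ = generate_dataset(cfg)
        y1, y2, is_mz = ds.pair_arrays("y_inattention")
        m1, m2, _ = ds.pair_arrays("m_unhealthy")
        full = fit_moderation(y1, y2, m1, m2, is_mz, "full", "AE", n_starts=1)
        dv = fit_moderation(y1, y2, m1, m2, is_mz, "drop_variance", "AE",
                            n_starts=1)
        stat = max(dv.neg2lnL - full.neg2lnL, 0.0)
        hits += chi2_pvalue(stat, 2) >= 0.05
    assert hits / reps >= 0.90


# ---------------------------------------------------------------------------
# Information criteria and tails
# ---------------------------------------------------------------------------

def test_aic_conventions():
    assert aic(14204.83, 2999) == pytest.approx(8206.83)
    assert aic(12857.35, 3003) == pytest.approx(6851.35)
    assert aic(0.0, 0) == 0.0
    assert aic_classic(100.0, 6) == pytest.approx(112.0)
    with pytest.raises(ValueError):
        aic(10.0, -1)


def test_chi2_tail_probabilities():
    assert round(chi2_pvalue(0.29, 1), 2) == 0.59
    assert round(chi2_pvalue(16.80, 3), 3) == 0.001
    assert chi2_pvalue(0.0, 4) == 1.0
    with pytest.raises(ValueError):
        chi2_pvalue(1.0, 0)
    with pytest.raises(ValueError):
        chi2_pvalue(-0.1, 1)


# ---------------------------------------------------------------------------
# Variance curves
# ---------------------------------------------------------------------------

def test_variance_curves_flat_without_moderation():
    p = ModerationParams(a=0.6, e=0.8)
    c = variance_curves(p, np.linspace(-2, 2, 9))
    assert np.ptp(c.A) == 0 and np.ptp(c.E) == 0
    np.testing.assert_allclose(c.A_share + c.C_share + c.E_share, 1.0,
                               atol=1e-10)


def test_variance_curves_monotone_heritability():
    p = ModerationParams(a=0.6, e=0.8, beta_a=0.15, beta_e=-0.05)
    grid = np.linspace(-1.5, 1.5, 21)  # a + beta_a*M > 0 throughout
    c = variance_curves(p, grid)
    assert np.all(np.diff(c.A_share) > 0)
    np.testing.assert_allclose(c.total, c.A + c.C + c.E, rtol=1e-12)


def test_variance_curve_recovery_at_extremes():
    """Fitted heritability at the 10th/90th moderator percentiles recovers
    the generating 0.30 / 0.51 within 0.05 at large n."""
    cfg = paper_like_config(seed=77)
    from acemod.simulate import ModeratorModel
    # rg = 0 so the mean-moderation estimate is not confounded by
    # gene-environment correlation (E[A|M] != 0 when rg > 0)
    big = SimulationConfig(n_mz_pairs=50000, n_dz_pairs=50000,
                           params=cfg.params,
                           hyperactivity_params=cfg.hyperactivity_params,
                           moderator=ModeratorModel(rg=0.0),
                           seed=77)
    ds, _ = generate_dataset(big)
    y1, y2, is_mz = ds.pair_arrays("y_inattention")
    m1, m2, _ = ds.pair_arrays("m_unhealthy")
    fit = fit_moderation(y1, y2, m1, m2, is_mz, "full", "AE", n_starts=1)
    z90 = 1.2815515655446004
    c = variance_curves(fit, np.array([-z90, z90]))
    assert c.A_share[0] == pytest.approx(0.30, abs=0.05)
    assert c.A_share[1] == pytest.approx(0.51, abs=0.05)
    assert fit.params.beta_m == pytest.approx(0.25, abs=0.02)
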