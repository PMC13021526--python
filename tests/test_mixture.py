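"""Mixture fitting, information criteria and the model comparison."""

import math

import numpy as np
import pytest

from salsup import (
    CAPTURE_BOUNDS,
    ExGaussParams,
    compare_models,
    exgauss_logpdf,
    exgauss_median,
    exgauss_rvs,
    fit_baseline,
    fit_exgauss,
    fit_mixture,
    information_criteria,
)

BASE = ExGaussParams(1.2, 640, 72)
CAP = ExGaussParams(1.0, 850, 90)


def mixture_sample(n, p_capture, rng, baseline=BASE, capture=CAP):
    captured = rng.random(n) < p_capture
    return np.where(
        captured, exgauss_rvs(capture, n, rng), exgauss_rvs(baseline, n, rng)
    )


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def test_aic_difference_for_equal_loglik():
    lnl = -1234.5
    aic5, _ = information_criteria(lnl, 5, 100)
    aic7, _ = information_criteria(lnl, 7, 100)
    assert aic7 - aic5 == pytest.approx(4.0)


def test_bic_penalty_exceeds_aic_penalty_above_e_squared():
    for n in (8, 20, 10_000):
        aic, bic = information_criteria(0.0, 5, n)
        assert (bic > aic) == (n > math.e**2)
    with pytest.raises(ValueError):
        information_criteria(0.0, 5, 1)


# ---------------------------------------------------------------------------
# single-curve fitting and the family comparison
# ---------------------------------------------------------------------------

def test_exgauss_mle_recovers_parameters(rng):
    rts = exgauss_rvs(BASE, 10_000, rng)
    fitted, _ = fit_exgauss(rts, seed=0)
    assert fitted.K == pytest.approx(BASE.K, rel=0.05)
    assert fitted.loc == pytest.approx(BASE.loc, rel=0.05)
    assert fitted.scale == pytest.approx(BASE.scale, rel=0.05)


def test_family_comparison_recovers_generating_family():
    wins_exg = 0
    for seed in range(3):
        rng = np.random.default_rng(seed)
        res = fit_baseline(exgauss_rvs(BASE, 2000, rng), seed=0)
        wins_exg += res.winner == "ex_gaussian"
    assert wins_exg == 3

    from scipy import stats

    winners = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        rts = stats.lognorm.rvs(0.35, loc=250, scale=450, size=2000, random_state=rng)
        winners.append(fit_baseline(rts, seed=0).winner)
    # the generating family wins the majority; close sibling shapes
    # (inverse-gamma, chi-squared) may occasionally edge it out, but the
    # ex-Gaussian must never falsely win on log-normal data
    assert winners.count("lognormal") >= 3
    assert "ex_gaussian" not in winners


def test_baseline_requires_enough_trials(rng):
    with pytest.raises(ValueError):
        fit_baseline(exgauss_rvs(BASE, 30, rng))


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------

def test_identical_conditions_give_symmetric_capture_probs(rng):
    hp = mixture_sample(3000, 0.5, rng)
    lp = mixture_sample(3000, 0.5, rng)
    fit = fit_mixture(hp, lp, BASE, "capture", seed=0)
    assert fit.p_capture_hp == pytest.approx(fit.p_capture_lp, abs=0.06)


def test_mixture_density_is_stated_convex_combination(rng):
    hp = mixture_sample(500, 0.4, rng)
    lp = mixture_sample(500, 0.7, rng)
    fit = fit_mixture(hp, lp, BASE, "capture", n_starts=4, seed=0)
    grid = np.linspace(350, 1900, 25)
    for cond, p, curve in (
        ("hp", fit.p_capture_hp, fit.capture_curve_hp),
        ("lp", fit.p_capture_lp, fit.capture_curve_lp),
    ):
        expected = (1 - p) * np.exp(exgauss_logpdf(grid, BASE)) + p * np.exp(
            exgauss_logpdf(grid, curve)
        )
        np.testing.assert_allclose(
            np.exp(fit.condition_logpdf(grid, cond)), expected, rtol=1e-10
        )


def test_capture_probabilities_respect_bounds_and_pin_flag(rng):
    # generating probability far above the 0.8 ceiling
    hp = mixture_sample(3000, 0.95, rng)
    lp = mixture_sample(3000, 0.95, rng)
    fit = fit_mixture(hp, lp, BASE, "capture", seed=0)
    lo, hi = CAPTURE_BOUNDS
    for p in (fit.p_capture_hp, fit.p_capture_lp):
        assert lo <= p <= hi
    assert fit.p_capture_hp == pytest.approx(hi, abs=0.01)
    assert fit.boundary_pinned


def test_model_kinds_have_stated_parameter_counts(rng):
    hp = mixture_sample(400, 0.4, rng)
    lp = mixture_sample(400, 0.7, rng)
    for kind, k in (("capture", 5), ("disengagement", 7), ("combined", 8)):
        fit = fit_mixture(hp, lp, BASE, kind, n_starts=3, seed=0)
        assert fit.n_params == k
        if kind == "disengagement":
            assert fit.p_capture_hp == fit.p_capture_lp


def test_likelihood_nesting_in_comparison(rng):
    hp = mixture_sample(1500, 0.44, rng)
    lp = mixture_sample(1500, 0.70, rng)
    comp = compare_models(hp, lp, BASE, n_starts=6, seed=0)
    assert comp.fits["combined"].loglik >= comp.fits["capture"].loglik - 1e-6
    assert comp.fits["combined"].loglik >= comp.fits["disengagement"].loglik - 1e-6
    assert comp.winner_bic == min(comp.fits, key=lambda m: comp.fits[m].bic)
    deltas = comp.pairwise_deltas("bic")
    assert len(deltas) == 3


def test_unbounded_exploratory_mode_keeps_winner(rng):
    hp = mixture_sample(2000, 0.44, rng)
    lp = mixture_sample(2000, 0.70, rng)
    base = fit_baseline(exgauss_rvs(BASE, 2000, rng), seed=0).params
    bounded = compare_models(hp, lp, base, n_starts=6, seed=0)
    free = compare_models(
        hp, lp, base, n_starts=6, seed=0, capture_bounds=(0.001, 0.999)
    )
    assert bounded.winner_bic == free.winner_bic == "capture"


def test_binned_objective_gives_negative_criteria(rng):
    """Least squares on normalized histograms yields small residual variance,
    hence the Gaussian-error log-likelihood convention produces negative AIC."""
    hp = mixture_sample(4000, 0.44, rng)
    lp = mixture_sample(4000, 0.70, rng)
    fit = fit_mixture(hp, lp, BASE, "capture", objective="binned", n_starts=6, seed=0)
    assert fit.n_obs == 100  # 50 bins per condition
    assert fit.aic < 0
    assert fit.p_capture_lp > fit.p_capture_hp


def test_capture_cost_is_median_difference(rng):
    hp = mixture_sample(2500, 0.44, rng)
    lp = mixture_sample(2500, 0.70, rng)
    comp = compare_models(hp, lp, BASE, n_starts=6, seed=0)
    med_base = exgauss_median(BASE)
    med_cap = exgauss_median(comp.fits["capture"].capture_curve_hp)
    assert comp.capture_cost == pytest.approx(med_cap - med_base, abs=1e-9)
    assert comp.capture_cost == pytest.approx(215.0, abs=40.0)


def test_too_few_trials_error():
    with pytest.raises(ValueError):
        fit_mixture([500.0] * 3, [600.0] * 3, BASE, "capture")


def test_per_participant_comparison_structure_and_degenerate_cohort(rng):
    from salsup import per_participant_comparison

    nd = exgauss_rvs(BASE, 400, rng)
    hp = mixture_sample(400, 0.44, rng)
    lp = mixture_sample(400, 0.70, rng)
    # identical data for every participant: zero between-participant variance
    # in the criteria differences
    data = {pid: (nd, hp, lp) for pid in ("a", "b", "c")}
    table, group = per_participant_comparison(data, n_starts=4, seed=0)
    assert set(table["model"]) == {"capture", "disengagement", "combined"}
    assert len(table) == 9
    wide = table.pivot(index="participant", columns="model", values="bic")
    diffs = wide["capture"] - wide["disengagement"]
    assert diffs.std() == pytest.approx(0.0, abs=1e-9)
    assert group["excluded"] == []
    for crit in ("aic", "bic"):
        assert set(group[crit]["pairwise"]) == {
            "capture_vs_disengagement", "capture_vs_combined",
            "combined_vs_disengagement",
        }


def test_per_participant_failed_fit_excluded_and_logged():
    from salsup import per_participant_comparison

    rng = np.random.default_rng(0)
    good = (exgauss_rvs(BASE, 400, rng), mixture_sample(400, 0.4, rng),
            mixture_sample(400, 0.7, rng))
    bad = (exgauss_rvs(BASE, 10, rng), good[1], good[2])  # baseline underpowered
    table, group = per_participant_comparison(
        {"ok1": good, "ok2": good, "ok3": good, "broken": bad}, n_starts=3, seed=0
    )
    assert group["excluded"] == ["broken"]
    assert set(table["participant"]) == {"ok1", "ok2", "ok3"}
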