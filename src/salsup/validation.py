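"""Simulation studies validating the estimators against their generating truth.

Each function runs a self-contained study — density accuracy against a
quadrature oracle, capture-mixture parameter recovery, model-selection
recovery, staircase convergence, PSE recovery and group-test power — and
returns a dict of summary numbers.  All randomness is controlled by the
``seed`` argument.
"""

from __future__ import annotations

import json
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import integrate, stats

from .mixture import (
    ExGaussParams,
    compare_models,
    exgauss_median,
    exgauss_pdf,
    exgauss_rvs,
    fit_baseline,
    fit_mixture,
)
from .psychometrics import fit_participant_pses, pse_group_test, staircase_difference
from .staircase import StaircaseConfig, StaircasePair, ending_points
from .synthetic import ObserverConfig, make_schedule, simulate_session

__all__ = [
    "density_check",
    "capture_recovery_study",
    "model_selection_study",
    "staircase_convergence_study",
    "staircase_shift_study",
    "pse_recovery_study",
    "pse_power_study",
    "preprocess_ledger_check",
]

#: Study-condition truth: the default observer's curves and capture odds.
_TRUTH = ObserverConfig()


def _convolution_pdf(x: float, p: ExGaussParams) -> float:
    """Gaussian (x) exponential convolution by adaptive quadrature."""
    tau = p.tau

    def integrand(t):
        return (1.0 / tau) * math.exp(-t / tau) * stats.norm.pdf(x - t, p.loc, p.scale)

    bump = max(0.0, x - p.loc)
    val, _ = integrate.quad(
        integrand, 0.0, bump + 12.0 * p.scale, points=[bump],
        epsabs=1e-13, epsrel=1e-13, limit=400,
    )
    return val


def density_check(n_points: int = 1000, seed: int = 0) -> dict:
    """Max density error vs the convolution oracle plus the worst unit-integral error."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_points):
        p = ExGaussParams(
            K=float(rng.uniform(0.1, 3.0)),
            loc=float(rng.uniform(300, 900)),
            scale=float(rng.uniform(20, 150)),
        )
        x = float(rng.uniform(p.loc - 3 * p.scale, p.loc + 6 * p.scale * (1 + p.K)))
        max_err = max(max_err, abs(float(exgauss_pdf(x, p)) - _convolution_pdf(x, p)))
    integral_err = 0.0
    for p in (ExGaussParams(1.2, 640, 72), ExGaussParams(0.3, 500, 40),
              ExGaussParams(2.5, 800, 120)):
        total, _ = integrate.quad(
            lambda x: float(exgauss_pdf(x, p)),
            p.loc - 12 * p.scale, p.loc + 60 * p.scale * (1 + p.K), limit=400,
        )
        integral_err = max(integral_err, abs(total - 1.0))
    return {"max_abs_error": max_err, "integral_abs_error": integral_err,
            "n_points": n_points}


def _mixture_sample(n: int, p_capture: float, baseline: ExGaussParams,
                    capture: ExGaussParams, rng: np.random.Generator) -> np.ndarray:
    captured = rng.random(n) < p_capture
    return np.where(captured, exgauss_rvs(capture, n, rng),
                    exgauss_rvs(baseline, n, rng))


def capture_recovery_study(
    n_replicates: int = 20, n_per_condition: int = 8000, seed: int = 0
) -> dict:
    """Refit the capture model on data generated at the study conditions.

    Each replicate draws fresh no-distractor, HP and LP trials from the
    default observer's generating mixture (capture odds 0.44 / 0.70, baseline
    and capture medians near 714 / 929 ms), refits the baseline and the
    capture model, and records the recovered odds and curve medians.
    """
    base_true, cap_true = _TRUTH.baseline_params, _TRUTH.capture_params
    p_hp_true, p_lp_true = _TRUTH.p_capture_hp, _TRUTH.p_capture_lp
    rows = {"p_hp": [], "p_lp": [], "base_median": [], "cap_median": []}
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        nd = exgauss_rvs(base_true, n_per_condition, rng)
        hp = _mixture_sample(n_per_condition, p_hp_true, base_true, cap_true, rng)
        lp = _mixture_sample(n_per_condition, p_lp_true, base_true, cap_true, rng)
        base = fit_baseline(nd, seed=seed)
        fit = fit_mixture(hp, lp, base.params, "capture", seed=seed)
        rows["p_hp"].append(fit.p_capture_hp)
        rows["p_lp"].append(fit.p_capture_lp)
        rows["base_median"].append(exgauss_median(base.params))
        rows["cap_median"].append(exgauss_median(fit.capture_curve_hp))
    means = {k: float(np.mean(v)) for k, v in rows.items()}
    return {
        **means,
        "capture_cost": means["cap_median"] - means["base_median"],
        "true_p_hp": p_hp_true,
        "true_p_lp": p_lp_true,
        "true_base_median": exgauss_median(base_true),
        "true_cap_median": exgauss_median(cap_true),
        "n_replicates": n_replicates,
        "n_per_condition": n_per_condition,
    }


def model_selection_study(
    n_datasets: int = 20, n_per_condition: int = 2000, seed: int = 0
) -> dict:
    """BIC model-recovery rates on capture- and disengagement-generated data."""
    base_true, cap_true = _TRUTH.baseline_params, _TRUTH.capture_params
    dis_hp = ExGaussParams(1.0, 800, 85)
    dis_lp = ExGaussParams(1.0, 900, 95)
    capture_wins = 0
    disengagement_wins = 0
    for rep in range(n_datasets):
        rng = np.random.default_rng([seed, 1000 + rep])
        nd = exgauss_rvs(base_true, n_per_condition, rng)
        base = fit_baseline(nd, seed=seed).params
        hp = _mixture_sample(n_per_condition, _TRUTH.p_capture_hp, base_true,
                             cap_true, rng)
        lp = _mixture_sample(n_per_condition, _TRUTH.p_capture_lp, base_true,
                             cap_true, rng)
        capture_wins += compare_models(hp, lp, base, seed=seed).winner_bic == "capture"
        hp2 = _mixture_sample(n_per_condition, 0.5, base_true, dis_hp, rng)
        lp2 = _mixture_sample(n_per_condition, 0.5, base_true, dis_lp, rng)
        disengagement_wins += (
            compare_models(hp2, lp2, base, seed=seed).winner_bic == "disengagement"
        )
    return {
        "capture_recovery_rate": capture_wins / n_datasets,
        "disengagement_recovery_rate": disengagement_wins / n_datasets,
        "n_datasets": n_datasets,
        "n_per_condition": n_per_condition,
    }


def staircase_convergence_study(
    thresholds: np.ndarray | None = None, n_probes: int = 58, seed: int = 0
) -> dict:
    """Terminal error against a noiseless threshold observer, sweeping thresholds.

    The observer picks the staircased side exactly when its value exceeds the
    threshold.  Convergence demands a terminal error no larger than the
    terminal step for every threshold.  Only one track is driven here, so the
    default probe budget is a full block's worth of probe trials (0.4 x 144,
    all landing on the tested track).
    """
    if thresholds is None:
        thresholds = np.arange(40.0, 471.0, 5.0)
    worst_ratio = 0.0
    max_abs_error = 0.0
    for i, th in enumerate(thresholds):
        pair = StaircasePair(StaircaseConfig(), np.random.default_rng([seed, i]))
        for _ in range(n_probes):
            choice = "HP" if pair.value("HP") > th else "LP"
            pair.update("HP", choice)
        err = abs(pair.value("HP") - th)
        step = pair.states["HP"].step
        worst_ratio = max(worst_ratio, err / step)
        max_abs_error = max(max_abs_error, err)
    return {
        "max_error_step_ratio": worst_ratio,
        "max_abs_error": max_abs_error,
        "n_thresholds": int(len(thresholds)),
        "n_probes": n_probes,
    }


def _simulate_subjects(n_subjects: int, shift: float, seed: int):
    """Independent sessions at the study conditions with the given PSE shift."""
    observer = replace(_TRUTH, true_pse_shift=shift, seed=seed)
    for i in range(n_subjects):
        schedule = make_schedule(seed=int(np.random.default_rng([seed, i]).integers(2**31)))
        yield simulate_session(observer, schedule, participant=f"p{i:04d}")


def staircase_shift_study(
    n_subjects: int = 100, shift: float = -9.0, seed: int = 0
) -> dict:
    """Mean LP-minus-HP block-end staircase difference over simulated subjects."""
    diffs = []
    for _, _, logs in _simulate_subjects(n_subjects, shift, seed):
        diffs.append(
            float(staircase_difference(ending_points(logs, 5))["difference"].iloc[0])
        )
    return {
        "mean_lp_minus_hp": float(np.mean(diffs)),
        "expected": 2.0 * shift,
        "n_subjects": n_subjects,
    }


def pse_recovery_study(
    n_subjects: int = 50, shift: float = -9.0, seed: int = 0
) -> dict:
    """Mean per-subject fitted PSE over simulated subjects (paper-scale probe counts)."""
    pses, n_probes = [], []
    for _, probes, _ in _simulate_subjects(n_subjects, shift, seed):
        fits = fit_participant_pses(probes)
        if fits["converged"].iloc[0]:
            pses.append(float(fits["pse"].iloc[0]))
        n_probes.append(len(probes))
    return {
        "mean_pse": float(np.mean(pses)),
        "true_shift": shift,
        "n_converged": len(pses),
        "mean_probes_per_subject": float(np.mean(n_probes)),
        "n_subjects": n_subjects,
    }


def pse_power_study(
    n_cohorts: int = 30, n_per_cohort: int = 90, shift: float = -9.0,
    seed: int = 0, alpha: float = 0.05,
) -> dict:
    """Rejection rate of the group PSE test across simulated cohorts."""
    rejections = 0
    for c in range(n_cohorts):
        pses = []
        for _, probes, _ in _simulate_subjects(n_per_cohort, shift, seed * 7919 + c + 1):
            fits = fit_participant_pses(probes)
            if fits["converged"].iloc[0]:
                pses.append(float(fits["pse"].iloc[0]))
        res = pse_group_test(pses)
        rejections += res.p_value < alpha
    return {
        "power": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_per_cohort": n_per_cohort,
        "alpha": alpha,
    }


def preprocess_ledger_check(fixture_csv: str | Path, ledger_json: str | Path) -> dict:
    """Compare the filter chain's surviving counts against the packaged hand ledger."""
    from .preprocess import (
        FilterReport, exclude_repetitions, filter_correct, filter_rt_window,
        filter_sd, restrict_horizontal,
    )
    from .synthetic import read_table

    ledger = json.loads(Path(ledger_json).read_text())
    df = read_table(fixture_csv)
    report = FilterReport()
    out = filter_rt_window(df, report=report)
    out = filter_sd(out, report=report)
    out = filter_correct(out, report=report)
    out = exclude_repetitions(out, "distractor", report=report)
    out = restrict_horizontal(out, "distractor", report=report)
    got = {s["filter"]: s["n_after"] for s in report.steps}
    expected = {k: v for k, v in ledger.items() if k != "n_input"}
    mismatches = sum(got.get(k) != v for k, v in expected.items())
    return {"mismatches": mismatches, "counts": got, "expected": expected,
            "n_input": len(df)}
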