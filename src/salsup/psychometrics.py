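"""Combined-salience scoring, equal-count binning, logistic PSE fits, and
the staircase block-end difference analysis.

Sign conventions
----------------
The *combined salience* of a probe trial is ``hp_value - lp_value`` (degrees):
positive = physically brighter probe at the high-probability (HP) side.  A
two-parameter logistic ``p(x) = 1 / (1 + exp(-slope * (x - midpoint)))`` is
least-squares fitted to the binned probability of choosing the HP side; its
``midpoint`` is the combined-salience value at which either side is chosen
equally often.

The *reported* point of subjective equality follows the suppression
convention: negative PSE = probes at the HP side must be physically brighter
to appear equal.  If the 50% point sits at midpoint m > 0 the HP side needs m
extra degrees, so the reported PSE is ``-midpoint``.  Darker-task data trace
the mirrored curve (negative slope) around the same midpoint, so the same
rule applies to both polarities and group tests can pool them directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

logger = logging.getLogger("salsup.psychometrics")

__all__ = [
    "PsychometricFit",
    "GroupTestResult",
    "combined_salience",
    "bin_equal_count",
    "fit_psychometric",
    "suppression_pse",
    "fit_participant_pses",
    "aggregate_psychometric",
    "pse_group_test",
    "staircase_difference",
]


def combined_salience(hp_value, lp_value):
    """HP-side minus LP-side probe brightness in spectrum degrees (vectorized)."""
    return np.asarray(hp_value, dtype=float) - np.asarray(lp_value, dtype=float)


def bin_equal_count(
    scores: Sequence[float], responses: Sequence[bool], n_bins: int = 8
) -> pd.DataFrame:
    """Partition trials into ``n_bins`` contiguous equal-count score bins.

    Trials are stably sorted by (score, input position) and split into
    contiguous groups whose sizes differ by at most one; when the count does
    not divide evenly the extra trials go to the lowest-score bins.  Each bin
    is labelled by its mean score and carries the proportion of HP choices.
    """
    scores = np.asarray(scores, dtype=float)
    responses = np.asarray(responses, dtype=bool)
    if scores.shape != responses.shape:
        raise ValueError("scores and responses must have equal length")
    n = scores.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} trials to form {n_bins} bins, got {n}")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    rows, start = [], 0
    for size in sizes:
        idx = order[start : start + size]
        rows.append(
            {
                "label": float(scores[idx].mean()),
                "p_hp": float(responses[idx].mean()),
                "n": size,
            }
        )
        start += size
    return pd.DataFrame(rows)


@dataclass
class PsychometricFit:
    """A fitted two-parameter logistic psychometric curve."""

    midpoint: float
    slope: float
    bins: pd.DataFrame
    converged: bool

    @property
    def pse(self) -> float:
        """Reported PSE (suppression convention: negative = HP needs more brightness)."""
        return suppression_pse(self.midpoint)

    def predict(self, x):
        return expit(self.slope * (np.asarray(x, dtype=float) - self.midpoint))


def suppression_pse(midpoint: float) -> float:
    """Map a fitted curve midpoint to the reported PSE.

    A midpoint of +m degrees means the HP probe needs m extra degrees of
    physical brightness to be chosen equally often, which the suppression
    convention reports as -m.
    """
    return -float(midpoint)


def _logistic(x, midpoint, slope):
    return expit(slope * (x - midpoint))


def fit_psychometric(
    bins: pd.DataFrame, polarity: Literal["brighter", "darker"] = "brighter"
) -> PsychometricFit:
    """Least-squares logistic fit to binned (label, p_hp) points.

    Initialized at midpoint 0 with slope +0.01 for brighter-task data and
    -0.01 for darker-task data.  Fits where the optimizer fails or the slope
    degenerates to ~0 (flat choice data, PSE unidentifiable) are returned with
    ``converged=False`` so callers can exclude them from group tests.
    """
    usable = bins[bins["n"] > 0]
    if len(usable) < 4:
        raise ValueError(f"need at least 4 non-empty bins, got {len(usable)}")
    x = usable["label"].to_numpy(dtype=float)
    y = usable["p_hp"].to_numpy(dtype=float)
    slope0 = 0.01 if polarity == "brighter" else -0.01
    try:
        with warnings.catch_warnings():
            # flat choice data legitimately yields an unidentifiable fit;
            # that case is reported through the converged flag, not a warning
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _logistic, x, y, p0=[0.0, slope0], maxfev=20000
            )
        midpoint, slope = float(popt[0]), float(popt[1])
        span = float(x.max() - x.min()) or 1.0
        converged = (
            np.isfinite(popt).all()
            and np.isfinite(pcov).all()
            and abs(slope) > 1e-6
            and abs(midpoint) < 50.0 * span
        )
    except RuntimeError:
        logger.info("psychometric fit did not converge")
        midpoint, slope, converged = float("nan"), 0.0, False
    return PsychometricFit(midpoint=midpoint, slope=slope, bins=bins, converged=converged)


def fit_participant_pses(
    probes: pd.DataFrame, n_bins: int = 8
) -> pd.DataFrame:
    """Bin and fit each participant's probe data; one row per participant.

    Returns columns ``participant, midpoint, slope, pse, converged, n_trials``
    where ``pse`` is on the suppression sign convention.  Participants whose
    fits do not converge keep a row (flagged) but should be excluded from
    group tests.
    """
    rows = []
    for pid, grp in probes.groupby("participant", sort=True):
        polarity = str(grp["polarity"].iloc[0])
        scores = combined_salience(grp["hp_value"], grp["lp_value"])
        try:
            bins = bin_equal_count(scores, grp["chose_hp"].to_numpy(dtype=bool), n_bins)
            fit = fit_psychometric(bins, polarity)
        except ValueError as err:
            logger.warning("participant %s psychometric fit skipped: %s", pid, err)
            rows.append(
                {"participant": pid, "midpoint": np.nan, "slope": np.nan,
                 "pse": np.nan, "converged": False, "n_trials": len(grp)}
            )
            continue
        rows.append(
            {
                "participant": pid,
                "midpoint": fit.midpoint,
                "slope": fit.slope,
                "pse": fit.pse,
                "converged": fit.converged,
                "n_trials": len(grp),
            }
        )
    return pd.DataFrame(rows)


def aggregate_psychometric(
    probes: pd.DataFrame, n_bins: int = 8
) -> PsychometricFit:
    """One psychometric fit to all probe trials pooled across participants."""
    polarity = str(probes["polarity"].iloc[0])
    scores = combined_salience(probes["hp_value"], probes["lp_value"])
    bins = bin_equal_count(scores, probes["chose_hp"].to_numpy(dtype=bool), n_bins)
    return fit_psychometric(bins, polarity)


@dataclass
class GroupTestResult:
    """One-sample location test of a per-participant score against zero."""

    test: Literal["t", "wilcoxon"]
    statistic: float
    p_value: float
    effect_size: float      # Cohen's d for the t-test, rank-biserial for Wilcoxon
    cohens_d: float
    n: int
    mean: float
    sd: float
    alternative: str
    normality_p: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "test", "statistic", "p_value", "effect_size", "cohens_d", "n",
            "mean", "sd", "alternative", "normality_p",
        )}


def _rank_biserial(x: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation of x against zero."""
    nz = x[x != 0]
    if nz.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    return (w_pos - w_neg) / (w_pos + w_neg)


def pse_group_test(
    values: Sequence[float],
    alternative: Literal["two-sided", "less"] = "two-sided",
    mu: float = 0.0,
) -> GroupTestResult:
    """One-sample location test of per-participant scores against ``mu``.

    Uses a t-test with Cohen's d when a Shapiro-Wilk check does not reject
    normality (alpha = .05), otherwise a Wilcoxon signed-rank test with the
    matched-pairs rank-biserial correlation — mirroring the parametric test /
    rank-based fallback policy of the analysis.  ``alternative='less'``
    matches the one-tailed variant (scores below zero).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values for a group test")
    d = x - mu
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return GroupTestResult(
                test="t", statistic=0.0, p_value=1.0, effect_size=0.0, cohens_d=0.0,
                n=int(x.size), mean=float(np.mean(x)), sd=0.0,
                alternative=alternative, normality_p=1.0,
            )
        raise ValueError("degenerate variance: all values identical and nonzero")
    normality_p = float(stats.shapiro(d).pvalue) if 3 <= d.size <= 5000 else 1.0
    cohens_d = mean / sd
    if normality_p >= 0.05:
        res = stats.ttest_1samp(x, popmean=mu, alternative=alternative)
        return GroupTestResult(
            test="t", statistic=float(res.statistic), p_value=float(res.pvalue),
            effect_size=cohens_d, cohens_d=cohens_d, n=int(x.size),
            mean=float(np.mean(x)), sd=sd, alternative=alternative,
            normality_p=normality_p,
        )
    res = stats.wilcoxon(d, alternative=alternative)
    return GroupTestResult(
        test="wilcoxon", statistic=float(res.statistic), p_value=float(res.pvalue),
        effect_size=_rank_biserial(d), cohens_d=cohens_d, n=int(x.size),
        mean=float(np.mean(x)), sd=sd, alternative=alternative,
        normality_p=normality_p,
    )


def staircase_difference(ending: pd.DataFrame) -> pd.DataFrame:
    """Per-participant LP-minus-HP staircase block-end difference.

    ``ending`` is the tidy output of :func:`salsup.staircase.ending_points`.
    For each participant the per-block difference ``LP_end - HP_end`` is
    averaged over blocks with both sides present; participants with no
    complete block are flagged (``n_blocks = 0``, NaN difference).
    """
    numeric = ending[ending["block"] != "mean"]
    rows = []
    for pid, grp in numeric.groupby("participant", sort=True):
        wide = grp.pivot(index="block", columns="side", values="ending_value")
        complete = wide.dropna(subset=["HP", "LP"]) if {"HP", "LP"} <= set(wide.columns) else wide.iloc[0:0]
        if complete.empty:
            logger.warning("participant %s has no complete staircase block", pid)
            rows.append({"participant": pid, "difference": np.nan, "n_blocks": 0})
            continue
        diffs = complete["LP"] - complete["HP"]
        rows.append(
            {"participant": pid, "difference": float(diffs.mean()), "n_blocks": int(len(diffs))}
        )
    return pd.DataFrame(rows)
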