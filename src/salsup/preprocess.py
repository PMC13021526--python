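"""Trial- and participant-level filters and condition labelling.

The filter chain for RT analyses runs, in order: RT window (300-2000 ms,
boundaries kept), per-participant 2.5-SD trim (single pass, statistics taken
on the post-window data), removal of incorrect responses (skipped for
accuracy analyses), removal of location repetitions (distractor or target
role), and the horizontal-midline restriction (ring positions 0 and 4).  Each
filter is a pure row selection, hence idempotent, and every application is
recorded in a :class:`FilterReport` whose counts reconcile exactly.

Participant-level exclusions mirror the cohort rules: group-accuracy 2.5 SD,
the 30-degree screen-test bound, and the probe-error rule (rate of
objectively wrong probe choices, or probe accuracy for the colored-search
profile).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .synthetic import HORIZONTAL_LOCATIONS

logger = logging.getLogger("salsup.preprocess")

__all__ = [
    "FilterReport",
    "filter_rt_window",
    "filter_sd",
    "filter_correct",
    "exclude_repetitions",
    "restrict_horizontal",
    "label_conditions",
    "preprocess_search",
    "ExclusionRules",
    "participant_exclusions",
    "probe_wrong_rate",
    "summarize_sessions",
    "load_mapped_csv",
    "DEFAULT_OSF_MAPPING",
]

Role = Literal["distractor", "target"]


@dataclass
class FilterReport:
    """Ordered record of every filter application plus participant exclusions."""

    steps: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)

    def record(self, name: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise ValueError("a filter cannot add trials")
        self.steps.append(
            {
                "filter": name,
                "n_before": int(n_before),
                "n_after": int(n_after),
                "fraction_removed": (n_before - n_after) / n_before if n_before else 0.0,
            }
        )
        logger.info("filter %-22s %6d -> %6d trials", name, n_before, n_after)

    def exclude(self, participant: str, reason: str) -> None:
        self.exclusions.append({"participant": str(participant), "reason": reason})
        logger.info("participant %s excluded: %s", participant, reason)

    @property
    def total_removed(self) -> int:
        return sum(s["n_before"] - s["n_after"] for s in self.steps)

    def to_dict(self) -> dict:
        return {"steps": self.steps, "exclusions": self.exclusions}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _apply(df: pd.DataFrame, mask: pd.Series, name: str,
           report: FilterReport | None) -> pd.DataFrame:
    out = df[mask.to_numpy(dtype=bool)]
    if report is not None:
        report.record(name, len(df), len(out))
    return out


def filter_rt_window(
    trials: pd.DataFrame, low: float = 300.0, high: float = 2000.0,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Drop trials with RT below ``low`` or above ``high`` ms (bounds kept)."""
    mask = (trials["rt"] >= low) & (trials["rt"] <= high)
    return _apply(trials, mask, "rt_window", report)


def filter_sd(
    trials: pd.DataFrame, k: float = 2.5, report: FilterReport | None = None,
) -> pd.DataFrame:
    """Per-participant +/- k SD trim around the participant mean RT.

    Mean and SD are computed once on the data as given (single pass, no
    re-estimation after removal); a participant with zero SD loses no trials.
    """
    stats_ = trials.groupby("participant")["rt"].agg(["mean", "std"])
    stats_["std"] = stats_["std"].fillna(0.0)
    merged = trials.merge(stats_, left_on="participant", right_index=True, how="left")
    dev = (merged["rt"] - merged["mean"]).abs()
    mask = (dev <= k * merged["std"]) | (merged["std"] == 0.0)
    mask.index = trials.index
    return _apply(trials, mask, "sd_trim", report)


def filter_correct(
    trials: pd.DataFrame, report: FilterReport | None = None,
) -> pd.DataFrame:
    """Keep correct responses only (RT analyses; accuracy analyses skip this)."""
    return _apply(trials, trials["correct"].astype(bool), "correct_only", report)


def exclude_repetitions(
    trials: pd.DataFrame, role: Role = "distractor",
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Drop trials whose ``role`` location repeats the immediately preceding trial.

    Adjacency is judged on the original presentation order (``trial_index``):
    a trial counts as a repetition only when the previous presentation index
    is present in the table and carries the same location.  Two absent
    distractors in a row are not a repetition.
    """
    col = f"{role}_location"
    ordered = trials.sort_values(["participant", "trial_index"])
    grp = ordered.groupby("participant")
    prev_loc = grp[col].shift(1)
    prev_idx = grp["trial_index"].shift(1)
    adjacent = prev_idx == ordered["trial_index"] - 1
    same = (ordered[col] == prev_loc) & ordered[col].notna() & prev_loc.notna()
    repetition = (adjacent & same).reindex(trials.index)
    return _apply(trials, ~repetition, f"{role}_repetition", report)


def restrict_horizontal(
    trials: pd.DataFrame, role: Role = "distractor", keep_absent: bool = True,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Keep trials whose ``role`` is on the horizontal midline (locations 0, 4).

    For the distractor role, absent trials are kept by default so the same
    subset can supply the no-distractor baseline.
    """
    col = f"{role}_location"
    mask = trials[col].isin(HORIZONTAL_LOCATIONS)
    if role == "distractor" and keep_absent:
        mask = mask | trials[col].isna()
    return _apply(trials, mask.fillna(False), f"{role}_horizontal", report)


def label_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach ``condition`` (absent/HP/LP) and circular ``gradient_distance`` (0-4)."""
    out = trials.copy()
    d = out["distractor_location"]
    hp = out["hp_location"]
    out["condition"] = np.select(
        [d.isna().to_numpy(), (d == hp).fillna(False).to_numpy(dtype=bool)],
        ["absent", "HP"],
        default="LP",
    )
    raw = (d - hp).abs()
    dist = np.minimum(raw, 8 - raw)
    out["gradient_distance"] = dist.astype("Int64")
    return out


def preprocess_search(
    trials: pd.DataFrame,
    role: Role = "distractor",
    rt_low: float = 300.0,
    rt_high: float = 2000.0,
    sd_k: float = 2.5,
    drop_incorrect: bool = True,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Run the full filter chain for one analysis role and label conditions.

    ``role='distractor'`` yields the set for distractor analyses and mixture
    fitting (absent trials retained as the baseline); ``role='target'``
    restricts to distractor-absent trials with horizontal targets, applying
    target-repetition exclusion instead.
    """
    report = report if report is not None else FilterReport()
    df = filter_rt_window(trials, rt_low, rt_high, report=report)
    df = filter_sd(df, sd_k, report=report)
    if drop_incorrect:
        df = filter_correct(df, report=report)
    if role == "target":
        df = _apply(df, df["distractor_location"].isna(), "distractor_absent", report)
    df = exclude_repetitions(df, role, report=report)
    df = restrict_horizontal(df, role, report=report)
    return label_conditions(df)


# ---------------------------------------------------------------------------
# Participant-level exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRules:
    """Cohort exclusion thresholds.

    ``probe_style='wrong_rate'`` drops participants whose rate of objectively
    wrong probe choices exceeds ``probe_wrong_max`` (monochrome profiles);
    ``probe_style='accuracy'`` drops those whose probe accuracy falls below
    ``probe_correct_min`` (colored-search profile).  ``missing_screen``
    controls participants without a screen-test record (the cohort procedure
    replaced them, i.e. dropped).
    """

    accuracy_sd: float = 2.5
    screen_test_max: float = 30.0
    probe_style: Literal["wrong_rate", "accuracy"] = "wrong_rate"
    probe_wrong_max: float = 0.45
    probe_correct_min: float = 0.55
    missing_screen: Literal["drop", "keep"] = "drop"


def probe_wrong_rate(
    probes: pd.DataFrame, min_difference: float = 64.0
) -> pd.Series:
    """Per-participant rate of objectively wrong probe choices.

    Near subjective equality there is no objective answer, so a choice counts
    as wrong only on trials where the physical brightness difference exceeds
    ``min_difference`` degrees and the observer picked the side the task
    polarity rules out (the dimmer side in the brighter task, the brighter
    side in the darker task).  Participants with no such decisive trial get a
    rate of 0.
    """
    df = probes.copy()
    diff = df["hp_value"] - df["lp_value"]
    decisive = diff.abs() > min_difference
    hp_correct = np.where(df["polarity"] == "brighter", diff > 0, diff < 0)
    wrong = df["chose_hp"].astype(bool) != hp_correct
    out = {}
    for pid, grp_idx in df.groupby("participant").groups.items():
        dec = decisive.loc[grp_idx]
        out[pid] = float(wrong.loc[grp_idx][dec].mean()) if dec.any() else 0.0
    return pd.Series(out, name="probe_wrong_rate")


def summarize_sessions(
    search: pd.DataFrame,
    probes: pd.DataFrame,
    screen_test: pd.Series | dict | None = None,
    min_difference: float = 64.0,
) -> pd.DataFrame:
    """Per-participant summaries used by :func:`participant_exclusions`.

    ``screen_test`` maps participant to the absolute screen-test mismatch in
    degrees; missing entries become NaN.
    """
    acc = search.groupby("participant")["correct"].mean().rename("accuracy")
    wrong = probe_wrong_rate(probes, min_difference)
    dec_diff = (probes["hp_value"] - probes["lp_value"]).abs() > min_difference
    correct_rate = {}
    for pid, grp in probes.groupby("participant"):
        diff = grp["hp_value"] - grp["lp_value"]
        decisive = diff.abs() > min_difference
        if decisive.any():
            hp_correct = np.where(grp["polarity"] == "brighter", diff > 0, diff < 0)
            correct_rate[pid] = float(
                (grp["chose_hp"].astype(bool) == hp_correct)[decisive].mean()
            )
        else:
            correct_rate[pid] = 1.0
    summary = pd.concat(
        [acc, wrong, pd.Series(correct_rate, name="probe_accuracy")], axis=1
    )
    screen = pd.Series(screen_test if screen_test is not None else {}, dtype=float)
    summary["screen_test_error"] = screen.reindex(summary.index)
    return summary.reset_index(names="participant")


def participant_exclusions(
    summaries: pd.DataFrame,
    rules: ExclusionRules = ExclusionRules(),
    report: FilterReport | None = None,
) -> tuple[list[str], FilterReport]:
    """Apply the cohort exclusion rules in order; returns (kept ids, report).

    Order: group-accuracy 2.5 SD rule, screen-test 30-degree rule ("more than
    30" is strict, 30 itself is kept), probe-error rule.  The accuracy
    mean/SD come from the full submitted cohort.  Every decision is logged
    with its reason.
    """
    report = report if report is not None else FilterReport()
    df = summaries.set_index("participant")
    mean_acc = df["accuracy"].mean()
    sd_acc = df["accuracy"].std(ddof=1)
    kept: list[str] = []
    for pid, row in df.iterrows():
        if sd_acc > 0 and abs(row["accuracy"] - mean_acc) > rules.accuracy_sd * sd_acc:
            report.exclude(pid, f"accuracy {row['accuracy']:.3f} beyond "
                                f"{rules.accuracy_sd} SD of group mean {mean_acc:.3f}")
            continue
        screen = row.get("screen_test_error", np.nan)
        if np.isnan(screen):
            if rules.missing_screen == "drop":
                report.exclude(pid, "missing screen-test record")
                continue
        elif screen > rules.screen_test_max:
            report.exclude(pid, f"screen-test mismatch {screen:.1f} deg "
                                f"> {rules.screen_test_max}")
            continue
        if rules.probe_style == "wrong_rate":
            if row["probe_wrong_rate"] > rules.probe_wrong_max:
                report.exclude(pid, f"probe wrong rate {row['probe_wrong_rate']:.2f} "
                                    f"> {rules.probe_wrong_max}")
                continue
        else:
            if row["probe_accuracy"] < rules.probe_correct_min:
                report.exclude(pid, f"probe accuracy {row['probe_accuracy']:.2f} "
                                    f"< {rules.probe_correct_min}")
                continue
        kept.append(str(pid))
    return kept, report


# ---------------------------------------------------------------------------
# External-dialect adapter
# ---------------------------------------------------------------------------

#: Column mapping for the deposited-data dialect; keys are canonical names,
#: values the external column names.  Users can override any entry through a
#: YAML mapping file.
DEFAULT_OSF_MAPPING: dict[str, str] = {
    "participant": "subject_nr",
    "block": "block",
    "trial_index": "trial_nr",
    "target_location": "target_pos",
    "distractor_location": "dist_pos",
    "hp_location": "high_prob_pos",
    "rt": "response_time",
    "correct": "correct",
}


def load_mapped_csv(
    path: str | Path, mapping: dict[str, str] | str | Path | None = None
) -> pd.DataFrame:
    """Read an externally formatted search-trial CSV onto the canonical schema.

    ``mapping`` maps canonical column names to the file's column names; a
    YAML file path or a dict may be given, and omitted entries fall back to
    :data:`DEFAULT_OSF_MAPPING`.  Absent distractors may be encoded as empty
    cells or a negative sentinel.
    """
    if mapping is None:
        mapping = {}
    elif not isinstance(mapping, dict):
        mapping = yaml.safe_load(Path(mapping).read_text()) or {}
    full = {**DEFAULT_OSF_MAPPING, **mapping}
    raw = pd.read_csv(path)
    missing = [ext for ext in full.values() if ext not in raw.columns]
    if missing:
        raise ValueError(f"input file lacks expected columns: {missing}")
    df = raw[[full[c] for c in full]].rename(columns={v: k for k, v in full.items()})
    df["distractor_location"] = pd.to_numeric(df["distractor_location"], errors="coerce")
    df.loc[df["distractor_location"] < 0, "distractor_location"] = np.nan
    df["distractor_location"] = df["distractor_location"].astype("Int64")
    df["correct"] = df["correct"].astype(bool)
    df["rt"] = df["rt"].astype(float)
    return df
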