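"""Trial filters, condition labels, the filter report and cohort exclusions."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salsup import (
    ExclusionRules,
    FilterReport,
    exclude_repetitions,
    filter_correct,
    filter_rt_window,
    filter_sd,
    label_conditions,
    participant_exclusions,
    preprocess_search,
    probe_wrong_rate,
    read_table,
    restrict_horizontal,
    summarize_sessions,
)
from salsup.preprocess import load_mapped_csv


def trials(rows, **defaults):
    base = dict(participant="p1", block=1, target_location=1,
                distractor_location=None, hp_location=0, rt=600.0, correct=True)
    base.update(defaults)
    out = []
    for i, r in enumerate(rows, start=1):
        row = dict(base, trial_index=i)
        row.update(r)
        out.append(row)
    df = pd.DataFrame(out)
    df["distractor_location"] = df["distractor_location"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# RT window
# ---------------------------------------------------------------------------

def test_rt_window_boundaries_inclusive():
    df = trials([{"rt": v} for v in
                 (250.0, 299.9, 300.0, 500.0, 1999.0, 2000.0, 2000.1, 2500.0,
                  150.0, 700.0)])
    out = filter_rt_window(df)
    assert len(out) == 5
    assert set(out["rt"]) == {300.0, 500.0, 1999.0, 2000.0, 700.0}


def test_rt_window_hand_fixture_of_ten():
    rts = [250.0, 300.0, 450.0, 800.0, 2000.0, 2100.0, 120.0, 600.0, 1500.0, 1900.0]
    out = filter_rt_window(trials([{"rt": v} for v in rts]))
    assert len(out) == 7  # 250, 2100 and 120 fall outside the window


# ---------------------------------------------------------------------------
# SD trim
# ---------------------------------------------------------------------------

def test_sd_zero_variance_removes_nothing():
    df = trials([{"rt": 500.0}] * 20)
    assert len(filter_sd(df)) == 20


def test_sd_removes_extreme_outlier():
    df = trials([{"rt": 500.0 + i * 0.01} for i in range(99)] + [{"rt": 5000.0}])
    out = filter_sd(df)
    assert len(out) == 99
    assert 5000.0 not in set(out["rt"])


def test_sd_removal_fraction_matches_normal_tail(rng):
    df = trials([{"rt": float(v)} for v in rng.normal(700, 100, 10_000)])
    out = filter_sd(df, k=2.5)
    removed = 1 - len(out) / len(df)
    expect = 2 * stats.norm.sf(2.5)  # ~1.24%
    assert removed == pytest.approx(expect, abs=0.004)


def test_sd_is_per_participant():
    fast = trials([{"rt": float(400 + i)} for i in range(50)], participant="fast")
    slow = trials([{"rt": float(1400 + i)} for i in range(50)], participant="slow")
    out = filter_sd(pd.concat([fast, slow], ignore_index=True))
    assert len(out) == 100  # neither group is an outlier within its own stream


# ---------------------------------------------------------------------------
# repetition exclusion
# ---------------------------------------------------------------------------

def test_adjacent_distractor_repetition_removed():
    df = trials([{"distractor_location": 4}, {"distractor_location": 4}])
    out = exclude_repetitions(df, "distractor")
    assert list(out["trial_index"]) == [1]


def test_non_adjacent_same_location_kept():
    df = trials([{"distractor_location": 4}, {"distractor_location": None},
                 {"distractor_location": 4}])
    assert len(exclude_repetitions(df, "distractor")) == 3


def test_absent_after_absent_not_a_repetition():
    df = trials([{"distractor_location": None}] * 5)
    assert len(exclude_repetitions(df, "distractor")) == 5


def test_twelve_trial_hand_sequence():
    locs = [2, 2, 5, None, 5, 5, 5, 1, 3, 3, None, None]
    # hand count: repetitions at positions 2 (2->2), 6 (5->5), 7 (5->5), 10 (3->3)
    df = trials([{"distractor_location": l} for l in locs])
    out = exclude_repetitions(df, "distractor")
    assert len(out) == 8
    assert set(df["trial_index"]) - set(out["trial_index"]) == {2, 6, 7, 10}


def test_gap_from_earlier_filter_breaks_adjacency():
    df = trials([{"distractor_location": 4}, {"distractor_location": 4},
                 {"distractor_location": 4}])
    thinned = df[df["trial_index"] != 2]  # middle trial removed upstream
    out = exclude_repetitions(thinned, "distractor")
    assert list(out["trial_index"]) == [1, 3]


def test_target_repetition_role():
    df = trials([{"target_location": 3}, {"target_location": 3},
                 {"target_location": 5}])
    assert len(exclude_repetitions(df, "target")) == 2


# ---------------------------------------------------------------------------
# horizontal restriction and condition labels
# ---------------------------------------------------------------------------

def test_horizontal_restriction_keeps_midline_and_absent():
    df = trials([{"distractor_location": d} for d in (0, 2, 4, 6, None)])
    out = restrict_horizontal(df, "distractor")
    kept = list(out["distractor_location"].array)
    assert kept == [0, 4, pd.NA]
    no_absent = restrict_horizontal(df, "distractor", keep_absent=False)
    assert list(no_absent["distractor_location"]) == [0, 4]


def test_condition_labels_and_gradient_distance():
    df = trials(
        [{"distractor_location": d} for d in (0, 4, 7, 2, None)], hp_location=0
    )
    out = label_conditions(df)
    assert list(out["condition"]) == ["HP", "LP", "LP", "LP", "absent"]
    assert list(out["gradient_distance"].array) == [0, 4, 1, 2, pd.NA]


# ---------------------------------------------------------------------------
# chain, report, idempotency
# ---------------------------------------------------------------------------

def test_packaged_fixture_matches_hand_ledger(fixture_csv, fixture_ledger):
    """Every filter's surviving count equals the independently hand-computed ledger."""
    ledger = json.loads(fixture_ledger.read_text())
    df = read_table(fixture_csv)
    assert len(df) == ledger["n_input"] == 200
    report = FilterReport()
    out = filter_rt_window(df, report=report)
    out = filter_sd(out, report=report)
    out = filter_correct(out, report=report)
    out = exclude_repetitions(out, "distractor", report=report)
    out = restrict_horizontal(out, "distractor", report=report)
    got = {s["filter"]: s["n_after"] for s in report.steps}
    assert got == {k: v for k, v in ledger.items() if k != "n_input"}


def test_selection_filters_are_idempotent(fixture_csv):
    df = read_table(fixture_csv)
    for fn in (
        lambda d: filter_rt_window(d),
        lambda d: filter_correct(d),
        lambda d: exclude_repetitions(d, "distractor"),
        lambda d: restrict_horizontal(d, "distractor"),
    ):
        once = fn(df)
        twice = fn(once)
        pd.testing.assert_frame_equal(once, twice)
        df = once


def test_sd_trim_is_single_pass(fixture_csv):
    """The SD trim re-estimates its statistics from whatever it is given, so
    the chain applies it exactly once; a second application on its own output
    may legitimately remove further trials."""
    df = filter_rt_window(read_table(fixture_csv))
    once = filter_sd(df)
    assert len(once) <= len(df)
    again = filter_sd(once)
    assert len(again) <= len(once)


def test_report_counts_reconcile(fixture_csv):
    df = read_table(fixture_csv)
    report = FilterReport()
    out = preprocess_search(df, role="distractor", report=report)
    for step in report.steps:
        assert step["n_after"] <= step["n_before"]
    for prev, cur in zip(report.steps, report.steps[1:]):
        assert cur["n_before"] == prev["n_after"]
    assert report.total_removed == len(df) - len(out)


def test_target_chain_restricts_to_absent_horizontal(fixture_csv):
    out = preprocess_search(read_table(fixture_csv), role="target")
    assert out["distractor_location"].isna().all()
    assert out["target_location"].isin([0, 4]).all()


# ---------------------------------------------------------------------------
# participant exclusions
# ---------------------------------------------------------------------------

def _summaries(rows):
    return pd.DataFrame(
        rows,
        columns=["participant", "accuracy", "probe_wrong_rate", "probe_accuracy",
                 "screen_test_error"],
    )


def test_accuracy_at_group_mean_is_kept():
    accs = [0.89, 0.90, 0.91, 0.90, 0.89, 0.91, 0.90, 0.90, 0.91, 0.89, 0.50]
    rows = [[f"p{i}", a, 0.1, 0.9, 5.0] for i, a in enumerate(accs)]
    kept, report = participant_exclusions(_summaries(rows))
    assert "p10" not in kept  # the 50%-accuracy outlier
    assert set(kept) == {f"p{i}" for i in range(10)}
    # a participant exactly at the group mean always survives the rule
    assert "p1" in kept


def test_screen_test_strict_threshold():
    rows = [["a", 0.9, 0.1, 0.9, 30.0], ["b", 0.9, 0.1, 0.9, 31.0],
            ["c", 0.9, 0.1, 0.9, 2.0]]
    kept, report = participant_exclusions(_summaries(rows))
    assert "a" in kept and "c" in kept and "b" not in kept
    reasons = {e["participant"]: e["reason"] for e in report.exclusions}
    assert "screen-test" in reasons["b"]


def test_probe_wrong_rate_rule_and_accuracy_style():
    rows = [["a", 0.9, 0.50, 0.50, 1.0], ["b", 0.9, 0.10, 0.90, 1.0]]
    kept1, _ = participant_exclusions(_summaries(rows), ExclusionRules())
    assert kept1 == ["b"]
    kept2, _ = participant_exclusions(
        _summaries(rows), ExclusionRules(probe_style="accuracy")
    )
    assert kept2 == ["b"]


def test_missing_screen_record_policy():
    rows = [["a", 0.9, 0.1, 0.9, np.nan], ["b", 0.9, 0.1, 0.9, 1.0],
            ["c", 0.9, 0.1, 0.9, 1.0]]
    kept_default, _ = participant_exclusions(_summaries(rows))
    assert "a" not in kept_default
    kept, _ = participant_exclusions(
        _summaries(rows), ExclusionRules(missing_screen="keep")
    )
    assert "a" in kept


def test_injected_guesser_is_the_one_dropped(rng):
    """A cohort with one random-guessing participant on probe trials."""
    rows = []
    for pid in ("g", "h", "i", "j"):
        guessing = pid == "g"
        for i in range(60):
            diff = float(rng.choice([-150.0, 150.0]))
            chose_hp = bool(rng.random() < 0.5) if guessing else diff > 0
            rows.append(dict(participant=pid, block=1, trial_index=i,
                             hp_value=187.0 + diff / 2, lp_value=187.0 - diff / 2,
                             standard_side="LP", chose_hp=chose_hp,
                             polarity="brighter", color_set="red"))
    probes = pd.DataFrame(rows)
    wrong = probe_wrong_rate(probes)
    search = trials([{"rt": 600.0}] * 10)
    search = pd.concat(
        [search.assign(participant=p) for p in ("g", "h", "i", "j")],
        ignore_index=True,
    )
    summaries = summarize_sessions(search, probes)
    kept, report = participant_exclusions(
        summaries, ExclusionRules(missing_screen="keep")
    )
    assert set(kept) == {"h", "i", "j"}
    assert wrong["g"] > 0.45 and all(wrong[p] == 0.0 for p in "hij")


# ---------------------------------------------------------------------------
# external dialect adapter
# ---------------------------------------------------------------------------

def test_load_mapped_csv_renames_and_coerces(tmp_path):
    raw = pd.DataFrame(
        {
            "subject_nr": ["s1", "s1"],
            "block": [1, 1],
            "trial_nr": [1, 2],
            "target_pos": [3, 5],
            "dist_pos": [4, -1],  # negative sentinel = absent
            "high_prob_pos": [0, 0],
            "response_time": [612.5, 700.1],
            "correct": [1, 0],
        }
    )
    path = tmp_path / "osf_style.csv"
    raw.to_csv(path, index=False)
    df = load_mapped_csv(path)
    assert list(df.columns) == ["participant", "block", "trial_index",
                                "target_location", "distractor_location",
                                "hp_location", "rt", "correct"]
    assert df["distractor_location"].isna().iloc[1]
    assert df["correct"].tolist() == [True, False]

    # user-supplied mapping override via YAML
    raw2 = raw.rename(columns={"response_time": "RT_ms"})
    path2 = tmp_path / "alt.csv"
    raw2.to_csv(path2, index=False)
    mapping = tmp_path / "map.yaml"
    mapping.write_text("rt: RT_ms\n")
    df2 = load_mapped_csv(path2, mapping)
    assert df2["rt"].iloc[0] == 612.5

    with pytest.raises(ValueError):
        load_mapped_csv(path2)  # default mapping no longer matches
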