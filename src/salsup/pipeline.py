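"""End-to-end orchestration: simulate -> preprocess -> contrasts ->
psychometrics -> mixture comparison -> report.

Every stage writes a plain-text artifact (CSV or JSON) under the configured
output directory and the final :class:`RunReport` gathers the headline
numbers; a fixed (config, seed) pair reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mixture import compare_models, fit_baseline, per_participant_comparison
from .preprocess import (
    ExclusionRules, FilterReport, participant_exclusions, preprocess_search,
    load_mapped_csv, summarize_sessions,
)
from .psychometrics import (
    aggregate_psychometric, fit_participant_pses, pse_group_test,
    staircase_difference,
)
from .staircase import StaircaseConfig, ending_points
from .synthetic import ObserverConfig, read_table, simulate_cohort, write_table

logger = logging.getLogger("salsup.pipeline")

__all__ = ["AnalysisConfig", "RunReport", "behavioral_contrasts", "run_pipeline", "PROFILES"]

#: Experiment profiles: probe polarity, probe color set and standard value.
PROFILES: dict[str, dict] = {
    "exp1a": {"polarity": "brighter", "color_set": "red", "standard_value": 187.0},
    "exp1b": {"polarity": "darker", "color_set": "green", "standard_value": 187.0},
    "exp2": {"polarity": "brighter", "color_set": "gray", "standard_value": 100.0},
}


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    mode: Literal["synthetic", "osf_csv"] = "synthetic"
    profile: Literal["exp1a", "exp1b", "exp2"] = "exp1a"
    n_participants: int = 20
    seed: int = 0
    outdir: str = "salsup_run"
    # filter parameters
    rt_low: float = 300.0
    rt_high: float = 2000.0
    sd_k: float = 2.5
    # mixture fitting
    objective: Literal["mle", "binned"] = "mle"
    n_starts: int = 16
    fit_per_participant: bool = False
    # external-data mode
    search_csv: str | None = None
    probe_csv: str | None = None
    staircase_csv: str | None = None
    column_mapping: str | None = None
    # synthetic-observer overrides (None = study-condition defaults)
    observer: dict | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def polarity(self) -> str:
        return PROFILES[self.profile]["polarity"]

    def observer_config(self) -> ObserverConfig:
        base = dict(self.observer or {})
        base.setdefault("seed", self.seed)
        return ObserverConfig.from_dict(base)


def _to_py(o):
    """JSON fallback for numpy scalar types."""
    if isinstance(o, np.generic):
        return o.item()
    raise TypeError(f"Object of type {type(o).__name__} is not JSON serializable")


def _paired_test(x: np.ndarray, y: np.ndarray) -> dict:
    """Matched contrast of two condition vectors (rank-based with rank-biserial)."""
    from .psychometrics import pse_group_test as _gt

    res = _gt(x - y, alternative="two-sided")
    return {
        "mean_difference": float(np.mean(x - y)),
        **res.to_dict(),
    }


def behavioral_contrasts(
    distractor_set: pd.DataFrame, target_set: pd.DataFrame
) -> dict:
    """Routine condition contrasts on the preprocessed trial sets.

    Produces (i) distractor-condition mean RTs and the matched HP-vs-LP
    contrast, (ii) the target-at-HP vs target-at-LP contrast on
    distractor-absent horizontal-target trials, and (iii) gradient means by
    circular distance from the HP location with a Greenhouse-Geisser-corrected
    repeated-measures omnibus and Holm-corrected pairwise tests.  Participants
    missing a condition are dropped from that contrast with a log line.
    """
    import pingouin as pg

    out: dict = {}
    cond_means = (
        distractor_set.groupby(["participant", "condition"])["rt"].mean().unstack()
    )
    out["condition_means"] = {
        c: float(cond_means[c].mean()) for c in cond_means.columns
    }
    hp_lp = cond_means.dropna(subset=["HP", "LP"]) if {"HP", "LP"} <= set(
        cond_means.columns
    ) else cond_means.iloc[0:0]
    dropped = sorted(set(cond_means.index) - set(hp_lp.index))
    if dropped:
        logger.info("dropped from HP-vs-LP contrast (missing condition): %s", dropped)
    if len(hp_lp) >= 2:
        out["hp_vs_lp"] = _paired_test(
            hp_lp["HP"].to_numpy(), hp_lp["LP"].to_numpy()
        )

    tgt = target_set.copy()
    tgt["target_at_hp"] = tgt["target_location"] == tgt["hp_location"]
    tgt_means = tgt.groupby(["participant", "target_at_hp"])["rt"].mean().unstack()
    if tgt_means.shape[1] == 2:
        both = tgt_means.dropna()
        if len(both) >= 2:
            out["target_hp_vs_lp"] = _paired_test(
                both[True].to_numpy(), both[False].to_numpy()
            )

    grad_src = distractor_set[distractor_set["condition"] != "absent"]
    grad = (
        grad_src.groupby(["participant", "gradient_distance"])["rt"].mean()
        .reset_index()
    )
    grad["gradient_distance"] = grad["gradient_distance"].astype(int)
    out["gradient_means"] = {
        int(k): float(v)
        for k, v in grad.groupby("gradient_distance")["rt"].mean().items()
    }
    complete = grad.groupby("participant")["gradient_distance"].nunique()
    full_ids = complete[complete == grad["gradient_distance"].nunique()].index
    grad_full = grad[grad["participant"].isin(full_ids)]
    if grad_full["participant"].nunique() >= 3 and grad_full["gradient_distance"].nunique() >= 2:
        aov = pg.rm_anova(
            data=grad_full, dv="rt", within="gradient_distance",
            subject="participant", correction=True,
        )
        row = aov.iloc[0]
        pcol = "p_GG_corr" if "p_GG_corr" in aov.columns and np.isfinite(
            row.get("p_GG_corr", np.nan)
        ) else "p_unc"
        out["gradient_anova"] = {"F": float(row["F"]), "p": float(row[pcol])}
        pw = pg.pairwise_tests(
            data=grad_full, dv="rt", within="gradient_distance",
            subject="participant", parametric=False, padjust="holm",
        )
        out["gradient_pairwise"] = [
            {
                "A": int(r["A"]), "B": int(r["B"]),
                "p_holm": float(r.get("p_corr", r["p_unc"])),
            }
            for _, r in pw.iterrows()
        ]
    return out


@dataclass
class RunReport:
    """Headline numbers of one pipeline run; serialized as sorted-key JSON."""

    config: dict
    seed: int
    version: str
    filter_report: dict
    n_participants_kept: int
    contrasts: dict
    staircase: dict
    psychometrics: dict
    model_comparison: dict
    per_participant_models: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, allow_nan=True,
                          default=_to_py)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_inputs(config: AnalysisConfig, outdir: Path):
    if config.mode == "synthetic":
        profile = PROFILES[config.profile]
        sc = StaircaseConfig(polarity=profile["polarity"])
        search, probes, logs = simulate_cohort(
            config.n_participants,
            observer=config.observer_config(),
            seed=config.seed,
            staircase_config=sc,
            standard_value=profile["standard_value"],
            color_set=profile["color_set"],
        )
        write_table(search, outdir / "search_trials.csv")
        write_table(probes, outdir / "probe_trials.csv")
        write_table(logs, outdir / "staircase_log.csv")
        return search, probes, logs
    if config.search_csv is None:
        raise ValueError("osf_csv mode requires search_csv")
    search = load_mapped_csv(config.search_csv, config.column_mapping)
    probes = read_table(config.probe_csv) if config.probe_csv else pd.DataFrame()
    logs = read_table(config.staircase_csv) if config.staircase_csv else pd.DataFrame()
    return search, probes, logs


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute all stages in order and write stage artifacts plus the report.

    Stage failures abort with the stage name; the partial report written so
    far is persisted as ``report_partial.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial: dict = {}
    stage = "simulate/load"
    try:
        search, probes, logs = _load_inputs(config, outdir)

        stage = "participant_exclusions"
        report = FilterReport()
        if len(probes):
            summaries = summarize_sessions(search, probes)
            rules = ExclusionRules(
                probe_style="accuracy" if config.profile == "exp2" else "wrong_rate",
                missing_screen="keep",
            )
            kept, report = participant_exclusions(summaries, rules, report)
            search = search[search["participant"].isin(kept)]
            probes = probes[probes["participant"].isin(kept)]
            logs = logs[logs["participant"].isin(kept)] if len(logs) else logs
        else:
            kept = sorted(search["participant"].unique())
        partial["n_participants_kept"] = len(kept)

        stage = "preprocess"
        distractor_set = preprocess_search(
            search, role="distractor", rt_low=config.rt_low,
            rt_high=config.rt_high, sd_k=config.sd_k, report=report,
        )
        target_set = preprocess_search(
            search, role="target", rt_low=config.rt_low,
            rt_high=config.rt_high, sd_k=config.sd_k, report=report,
        )
        write_table(distractor_set, outdir / "distractor_set.csv")
        write_table(target_set, outdir / "target_set.csv")
        report.to_json(outdir / "filter_report.json")
        partial["filter_report"] = report.to_dict()

        stage = "contrasts"
        contrasts = behavioral_contrasts(distractor_set, target_set)
        partial["contrasts"] = contrasts

        stage = "staircase"
        staircase_summary: dict = {}
        if len(logs):
            n_blocks = int(pd.to_numeric(logs["block"]).max())
            ends = ending_points(logs, n_blocks)
            write_table(ends, outdir / "staircase_endpoints.csv")
            diffs = staircase_difference(ends)
            ok = diffs["difference"].dropna()
            staircase_summary = {
                "mean_lp_minus_hp": float(ok.mean()) if len(ok) else None,
                "n_participants": int(len(ok)),
            }
            if len(ok) >= 2 and float(ok.std(ddof=1)) > 0:
                staircase_summary["group_test"] = pse_group_test(ok).to_dict()
        partial["staircase"] = staircase_summary

        stage = "psychometrics"
        psych: dict = {}
        if len(probes):
            pses = fit_participant_pses(probes)
            write_table(pses, outdir / "participant_pses.csv")
            agg = aggregate_psychometric(probes)
            usable = pses[pses["converged"]]["pse"].dropna()
            psych = {
                "aggregate_pse": agg.pse if agg.converged else None,
                "aggregate_slope": agg.slope,
                "mean_pse": float(usable.mean()) if len(usable) else None,
                "n_converged": int(len(usable)),
            }
            if len(usable) >= 2 and float(usable.std(ddof=1)) > 0:
                alternative = "less" if config.profile == "exp2" else "two-sided"
                psych["group_test"] = pse_group_test(usable, alternative).to_dict()
        partial["psychometrics"] = psych

        stage = "mixture"
        absent = distractor_set[distractor_set["condition"] == "absent"]["rt"].to_numpy()
        hp = distractor_set[distractor_set["condition"] == "HP"]["rt"].to_numpy()
        lp = distractor_set[distractor_set["condition"] == "LP"]["rt"].to_numpy()
        base = fit_baseline(absent, seed=config.seed)
        comp = compare_models(
            hp, lp, base.params, objective=config.objective,
            n_starts=config.n_starts, seed=config.seed,
        )
        model_summary = comp.to_dict()
        model_summary["baseline_family_table"] = base.family_table.to_dict("records")
        (outdir / "model_comparison.json").write_text(
            json.dumps(model_summary, indent=2, sort_keys=True, default=_to_py)
        )
        partial["model_comparison"] = model_summary

        per_part = None
        if config.fit_per_participant:
            stage = "mixture_per_participant"
            data = {}
            for pid, grp in distractor_set.groupby("participant"):
                data[pid] = (
                    grp[grp["condition"] == "absent"]["rt"].to_numpy(),
                    grp[grp["condition"] == "HP"]["rt"].to_numpy(),
                    grp[grp["condition"] == "LP"]["rt"].to_numpy(),
                )
            table, group = per_participant_comparison(
                data, objective=config.objective, seed=config.seed
            )
            write_table(table, outdir / "per_participant_models.csv")
            per_part = group
    except Exception:
        (outdir / "report_partial.json").write_text(
            json.dumps(partial, indent=2, sort_keys=True, default=str)
        )
        logger.error("pipeline failed at stage %r", stage)
        raise

    config_dict = asdict(config)
    config_dict.pop("outdir")  # artifact location, not part of the analysis identity
    run = RunReport(
        config=config_dict,
        seed=config.seed,
        version=__version__,
        filter_report=report.to_dict(),
        n_participants_kept=len(kept),
        contrasts=contrasts,
        staircase=staircase_summary,
        psychometrics=psych,
        model_comparison=model_summary,
        per_participant_models=per_part,
    )
    run.to_json(outdir / "report.json")
    return run


def save_diagnostic_plots(outdir: str | Path, report: RunReport) -> list[Path]:
    """Optional figures: RT histograms with fitted curves, psychometric curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .mixture import ExGaussParams, exgauss_pdf
    from .psychometrics import bin_equal_count, combined_salience, fit_psychometric

    outdir = Path(outdir)
    made: list[Path] = []
    dist = read_table(outdir / "distractor_set.csv")
    mc = report.model_comparison
    base = ExGaussParams(**mc["fits"]["capture"]["baseline"])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    grid = np.linspace(300, 2000, 400)
    for ax, cond in zip(axes, ["absent", "HP", "LP"]):
        rts = dist[dist["condition"] == cond]["rt"]
        ax.hist(rts, bins=40, density=True, alpha=0.5, color="#888888")
        if cond == "absent":
            ax.plot(grid, exgauss_pdf(grid, base), "k-")
        else:
            fit = mc["fits"]["capture"]
            p = fit["p_capture_hp" if cond == "HP" else "p_capture_lp"]
            curve = ExGaussParams(**fit["capture_curve_hp"])
            ax.plot(
                grid,
                (1 - p) * exgauss_pdf(grid, base) + p * exgauss_pdf(grid, curve),
                "r-",
            )
        ax.set_title(cond)
        ax.set_xlabel("RT (ms)")
    fig.tight_layout()
    path = outdir / "rt_mixture_fits.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    probe_path = outdir / "probe_trials.csv"
    if probe_path.exists():
        probes = read_table(probe_path)
        scores = combined_salience(probes["hp_value"], probes["lp_value"])
        bins = bin_equal_count(scores, probes["chose_hp"].to_numpy(dtype=bool))
        fit = fit_psychometric(bins, str(probes["polarity"].iloc[0]))
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.scatter(bins["label"], bins["p_hp"], color="#e07020")
        xg = np.linspace(bins["label"].min() - 20, bins["label"].max() + 20, 300)
        ax.plot(xg, fit.predict(xg), "b-")
        ax.axvline(fit.midpoint, color="b", ls="--", lw=0.8)
        ax.set_xlabel("combined salience (deg)")
        ax.set_ylabel("P(choose HP)")
        fig.tight_layout()
        path = outdir / "psychometric_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    return made
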