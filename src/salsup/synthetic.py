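"""Synthetic observer and task-schedule generator.

Emulates the additional-singleton sessions that the downstream analysis
expects: five blocks of 144 visual-search trials (targets balanced over eight
ring locations, a salient distractor on 88% of trials, half of the present
distractors at one fixed high-probability midline location), probe trials
inserted after search trials with probability 0.40, probe brightness values
produced live by the adaptive staircases, and search RTs drawn from a
two-component ex-Gaussian mixture with condition-dependent capture
probability.

The observer's perceptual bias is modeled as a subjective-brightness offset at
the high-probability side: a patch of physical value ``v`` at the HP location
is perceived as ``v + true_pse_shift`` (negative shift = perceived dimmer).
Under that convention the LP-minus-HP staircase ending difference converges to
``2 * true_pse_shift`` and the reported point of subjective equality equals
``true_pse_shift`` (see :mod:`salsup.psychometrics` for the sign convention).

Location indexing: eight positions 0-7 counterclockwise, 0 = leftmost point of
the horizontal midline, 4 = rightmost; the HP location is 0 or 4.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .mixture import ExGaussParams, exgauss_rvs
from .staircase import STAIRCASE_LOG_COLUMNS, StaircaseConfig, StaircasePair

logger = logging.getLogger("salsup.synthetic")

__all__ = [
    "ObserverConfig",
    "ScheduleSlot",
    "SessionSchedule",
    "make_schedule",
    "simulate_search_trial",
    "simulate_probe_choice",
    "simulate_session",
    "simulate_cohort",
    "write_table",
    "read_table",
    "SEARCH_COLUMNS",
    "PROBE_COLUMNS",
    "STANDARD_VALUE",
    "N_LOCATIONS",
    "HORIZONTAL_LOCATIONS",
]

N_LOCATIONS = 8
#: Ring positions on the horizontal midline (leftmost, rightmost).
HORIZONTAL_LOCATIONS = (0, 4)
#: Spectrum position of the fixed standard probe color.
STANDARD_VALUE = 187.0

SEARCH_COLUMNS = [
    "participant", "block", "trial_index", "target_location",
    "distractor_location", "hp_location", "rt", "correct", "captured",
]
PROBE_COLUMNS = [
    "participant", "block", "trial_index", "hp_value", "lp_value",
    "standard_side", "chose_hp", "polarity", "color_set",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Generative parameters of one simulated observer.

    Defaults are the study conditions the analysis targets: baseline and
    capture RT curves with medians near 714 and 929 ms, capture probabilities
    0.44 (HP) / 0.70 (LP), a perceived-brightness deficit of 9 spectrum
    degrees at the HP side, and 92.8% search accuracy.
    """

    true_pse_shift: float = -9.0        # degrees; negative = HP perceived dimmer
    psychometric_slope: float = 0.05    # 1/degrees
    baseline_params: ExGaussParams = field(
        default_factory=lambda: ExGaussParams(K=1.2, loc=640.0, scale=72.0)
    )
    capture_params: ExGaussParams = field(
        default_factory=lambda: ExGaussParams(K=1.0, loc=850.0, scale=90.0)
    )
    p_capture_hp: float = 0.44
    p_capture_lp: float = 0.70
    accuracy_rate: float = 0.928
    lapse_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_capture_hp", "p_capture_lp", "accuracy_rate", "lapse_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be positive")

    def to_dict(self) -> dict:
        return {
            "true_pse_shift": self.true_pse_shift,
            "psychometric_slope": self.psychometric_slope,
            "baseline_params": self.baseline_params.to_dict(),
            "capture_params": self.capture_params.to_dict(),
            "p_capture_hp": self.p_capture_hp,
            "p_capture_lp": self.p_capture_lp,
            "accuracy_rate": self.accuracy_rate,
            "lapse_rate": self.lapse_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverConfig":
        d = dict(d)
        for key in ("baseline_params", "capture_params"):
            if isinstance(d.get(key), dict):
                d[key] = ExGaussParams(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ObserverConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


@dataclass(frozen=True)
class ScheduleSlot:
    kind: Literal["search", "probe"]
    block: int
    target_location: int | None = None
    distractor_location: int | None = None


@dataclass
class SessionSchedule:
    """Ordered trial slots for one session; probes immediately follow searches."""

    slots: list[ScheduleSlot]
    hp_location: int
    n_blocks: int
    presence_rate: float
    hp_share: float
    probe_rate: float

    @property
    def n_search(self) -> int:
        return sum(1 for s in self.slots if s.kind == "search")

    @property
    def n_probe(self) -> int:
        return sum(1 for s in self.slots if s.kind == "probe")


def _randomized_round(x: float, rng: np.random.Generator) -> int:
    """floor(x) + Bernoulli(frac(x)) so counts are exact in expectation."""
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def make_schedule(
    presence_rate: float = 0.88,
    hp_share: float = 0.5,
    probe_rate: float = 0.40,
    n_blocks: int = 5,
    seed: int = 0,
    hp_location: int = 0,
    trials_per_block: int = 144,
) -> SessionSchedule:
    """Build a session schedule with the study's count structure.

    Per block: ``trials_per_block`` search trials with targets exactly
    balanced over the eight locations; a distractor on a ``presence_rate``
    fraction of them (fractional counts resolved by randomized rounding), of
    which an ``hp_share`` fraction sits at ``hp_location`` and the rest are
    uniform over the other seven locations; the distractor never coincides
    with the target.  After every search trial a probe slot is inserted with
    probability ``probe_rate``.
    """
    for name, v in (("presence_rate", presence_rate), ("hp_share", hp_share),
                    ("probe_rate", probe_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if hp_location not in HORIZONTAL_LOCATIONS:
        raise ValueError(f"hp_location must be one of {HORIZONTAL_LOCATIONS}")
    if trials_per_block % N_LOCATIONS:
        raise ValueError("trials_per_block must be divisible by the number of locations")

    rng = np.random.default_rng(seed)
    per_loc = trials_per_block // N_LOCATIONS
    slots: list[ScheduleSlot] = []
    other_locs = np.array([l for l in range(N_LOCATIONS) if l != hp_location])
    for block in range(1, n_blocks + 1):
        targets = np.repeat(np.arange(N_LOCATIONS), per_loc)
        rng.shuffle(targets)
        n_present = _randomized_round(presence_rate * trials_per_block, rng)
        n_hp = _randomized_round(hp_share * n_present, rng)
        if n_hp > n_present:
            raise ValueError("hp_share requires more HP trials than present trials")
        present_idx = rng.choice(trials_per_block, size=n_present, replace=False)
        distractors = np.full(trials_per_block, -1)
        d_locs = np.concatenate(
            [np.full(n_hp, hp_location), rng.choice(other_locs, size=n_present - n_hp)]
        )
        rng.shuffle(d_locs)
        distractors[present_idx] = d_locs
        # resolve target/distractor collisions by swapping with a compatible trial
        conflicts = np.flatnonzero((distractors >= 0) & (distractors == targets))
        for i in conflicts:
            swapped = False
            for j in rng.permutation(present_idx):
                if j == i:
                    continue
                if distractors[j] != targets[i] and distractors[i] != targets[j]:
                    distractors[i], distractors[j] = distractors[j], distractors[i]
                    swapped = True
                    break
            if not swapped:  # fall back: redraw a low-probability location
                choices = other_locs[other_locs != targets[i]]
                distractors[i] = rng.choice(choices)
        for t in range(trials_per_block):
            slots.append(
                ScheduleSlot(
                    kind="search",
                    block=block,
                    target_location=int(targets[t]),
                    distractor_location=None if distractors[t] < 0 else int(distractors[t]),
                )
            )
            if rng.random() < probe_rate:
                slots.append(ScheduleSlot(kind="probe", block=block))
    return SessionSchedule(
        slots=slots,
        hp_location=hp_location,
        n_blocks=n_blocks,
        presence_rate=presence_rate,
        hp_share=hp_share,
        probe_rate=probe_rate,
    )


def _draw_rt(params: ExGaussParams, rng: np.random.Generator) -> float:
    """One RT; values at or below zero are resampled so the density stays proper."""
    while True:
        rt = float(exgauss_rvs(params, 1, rng)[0])
        if rt > 0:
            return rt


def simulate_search_trial(
    slot: ScheduleSlot,
    observer: ObserverConfig,
    hp_location: int,
    rng: np.random.Generator,
) -> dict:
    """Simulate one search response for a schedule slot.

    Distractor-absent trials draw from the baseline curve.  Present trials
    first draw a capture event with the condition's probability and then draw
    the RT from the capture or baseline curve accordingly.
    """
    if slot.kind != "search":
        raise ValueError("slot is not a search slot")
    d = slot.distractor_location
    if d is None:
        p_capture = 0.0
    elif d == hp_location:
        p_capture = observer.p_capture_hp
    else:
        p_capture = observer.p_capture_lp
    captured = bool(rng.random() < p_capture)
    params = observer.capture_params if captured else observer.baseline_params
    rt = _draw_rt(params, rng)
    correct = bool(rng.random() < observer.accuracy_rate)
    return {
        "target_location": slot.target_location,
        "distractor_location": d,
        "hp_location": hp_location,
        "rt": rt,
        "correct": correct,
        "captured": captured,
    }


def probe_choice_probability(
    hp_value: float,
    lp_value: float,
    polarity: Literal["brighter", "darker"],
    observer: ObserverConfig,
) -> float:
    """P(observer selects the HP side) for given physical probe values.

    The HP patch's subjective brightness is its physical value plus
    ``true_pse_shift``; the choice is a lapse-mixed logistic comparison of
    subjective brightness (mirrored for the darker task).
    """
    subj_diff = (hp_value + observer.true_pse_shift) - lp_value
    p_bright = float(expit(observer.psychometric_slope * subj_diff))
    p = p_bright if polarity == "brighter" else 1.0 - p_bright
    return observer.lapse_rate / 2.0 + (1.0 - observer.lapse_rate) * p


def simulate_probe_choice(
    hp_value: float,
    lp_value: float,
    polarity: Literal["brighter", "darker"],
    observer: ObserverConfig,
    rng: np.random.Generator,
) -> bool:
    """Draw one probe response; True if the HP side was chosen."""
    return bool(rng.random() < probe_choice_probability(hp_value, lp_value, polarity, observer))


def _participant_streams(seed: int, participant: str) -> dict[str, np.random.Generator]:
    """Independent substreams per (seed, participant).

    Separate streams for search RTs, probe choices, staircase initialisation
    and standard-side draws mean that inserting or removing probe slots never
    perturbs the search RT sequence.
    """
    key = zlib.crc32(str(participant).encode("utf-8"))
    root = np.random.SeedSequence(entropy=(seed, key))
    names = ("search", "probe", "staircase", "side")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def simulate_session(
    observer: ObserverConfig,
    schedule: SessionSchedule,
    participant: str = "p001",
    staircase_config: StaircaseConfig | None = None,
    standard_value: float = STANDARD_VALUE,
    color_set: str = "red",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run one full simulated session.

    Probe brightness values come live from the staircase pair exactly as in a
    real session: on each probe slot the standard side is drawn at random, the
    other side shows its staircase's current value, the simulated choice feeds
    back into the staircase, and both staircases reset at block boundaries
    starting from their previous ending points.

    Returns (search table, probe table, staircase log) with the documented
    CSV schemas.
    """
    cfg = staircase_config or StaircaseConfig()
    streams = _participant_streams(observer.seed, participant)
    search_rows: list[dict] = []
    probe_rows: list[dict] = []
    log_rows: list[dict] = []
    pair: StaircasePair | None = None
    prev_ends: dict[str, float] | None = None
    current_block = 0
    trial_index = 0
    probe_index = 0
    for slot in schedule.slots:
        if slot.block != current_block:
            if pair is not None:
                prev_ends = pair.ending_values()
            pair = StaircasePair(cfg, streams["staircase"], previous_ends=prev_ends)
            current_block = slot.block
        if slot.kind == "search":
            trial_index += 1
            row = simulate_search_trial(slot, observer, schedule.hp_location, streams["search"])
            row.update(participant=participant, block=slot.block, trial_index=trial_index)
            search_rows.append(row)
        else:
            probe_index += 1
            standard_side = "HP" if streams["side"].random() < 0.5 else "LP"
            tested_side = "LP" if standard_side == "HP" else "HP"
            staircased_value = pair.value(tested_side)
            hp_value = standard_value if standard_side == "HP" else staircased_value
            lp_value = standard_value if standard_side == "LP" else staircased_value
            chose_hp = simulate_probe_choice(
                hp_value, lp_value, cfg.polarity, observer, streams["probe"]
            )
            choice_side = "HP" if chose_hp else "LP"
            step_before = pair.states[tested_side].step
            state = pair.update(tested_side, choice_side)
            probe_rows.append(
                {
                    "participant": participant,
                    "block": slot.block,
                    "trial_index": trial_index,
                    "hp_value": hp_value,
                    "lp_value": lp_value,
                    "standard_side": standard_side,
                    "chose_hp": chose_hp,
                    "polarity": cfg.polarity,
                    "color_set": color_set,
                }
            )
            log_rows.append(
                {
                    "participant": participant,
                    "block": slot.block,
                    "probe_index": probe_index,
                    "tested_side": tested_side,
                    "value_shown": staircased_value,
                    "step_before": step_before,
                    "step_after": state.step,
                    "choice_side": choice_side,
                    "value_after": state.current_value,
                }
            )
    search = pd.DataFrame(search_rows, columns=SEARCH_COLUMNS)
    probes = pd.DataFrame(probe_rows, columns=PROBE_COLUMNS)
    logs = pd.DataFrame(log_rows, columns=STAIRCASE_LOG_COLUMNS)
    search["distractor_location"] = search["distractor_location"].astype("Int64")
    return search, probes, logs


def simulate_cohort(
    n_participants: int,
    observer: ObserverConfig | None = None,
    seed: int = 0,
    schedule_kwargs: dict | None = None,
    staircase_config: StaircaseConfig | None = None,
    standard_value: float = STANDARD_VALUE,
    color_set: str = "red",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; participant ``i`` gets an independent schedule and streams.

    The HP location alternates between the two midline positions across
    participants, mirroring the counterbalancing of the task.
    """
    observer = observer or ObserverConfig()
    schedule_kwargs = dict(schedule_kwargs or {})
    searches, probes, logs = [], [], []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        kw = dict(schedule_kwargs)
        kw.setdefault("hp_location", HORIZONTAL_LOCATIONS[i % 2])
        schedule = make_schedule(seed=seed * 100_003 + i, **kw)
        obs_i = replace(observer, seed=seed)
        s, p, l = simulate_session(
            obs_i, schedule, participant=pid, staircase_config=staircase_config,
            standard_value=standard_value, color_set=color_set,
        )
        searches.append(s)
        probes.append(p)
        logs.append(l)
    return (
        pd.concat(searches, ignore_index=True),
        pd.concat(probes, ignore_index=True),
        pd.concat(logs, ignore_index=True),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV with full float precision (lossless round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "distractor_location" in df.columns:
        df["distractor_location"] = df["distractor_location"].astype("Int64")
    return df
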