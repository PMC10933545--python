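"""Study-design configuration for the affective reward-memory experiments.

Two canonical two-stage designs are encoded here.  In both, participants
first learn the reward probability of abstract shapes in two-alternative
reinforcement-learning (RL) blocks whose two shapes carry complementary
probabilities (p vs. 1-p).  A single rigged wheel-of-fortune (WoF) draw
between blocks delivers a large win, loss, or blank outcome, inducing a
discrete mood state under which the post-draw shapes are encoded.  One or
two days later a preference test probes value-based recall: shapes are
paired exhaustively and the participant chooses the one they remember as
more rewarding.

Lab design (``study1``): 14 shapes over 3 learning days.  Each day runs a
30-trial 0.7/0.3 baseline block (the same two shapes on all days), the WoF
draw (+£15 / -£11 / £0 across the three days), then two 90-trial blocks at
0.9/0.1 and 0.8/0.2.  The preference test (400 trials x 2 days) presents
post-win and post-loss shapes on fixed, counterbalanced screen sides.

Online design (``study2``): 24 shapes over 2 learning days.  Each day runs
three 40-trial pre-WoF blocks at 0.9/0.1, 0.75/0.25, 0.6/0.4, the WoF draw
(+£14 / -£7), and three post-WoF blocks at the same probabilities.  The
single preference test (456 trials) randomises screen sides.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: WoF condition labels for stimuli.
WOF_CONDITIONS = ("baseline_pre", "post_win", "post_loss", "post_neutral")
SIDE_RULES = ("free", "left_only", "right_only")


class DesignError(ValueError):
    """Raised for invalid or unknown study-design configuration."""


@dataclass(frozen=True)
class StimulusSpec:
    """One learned shape and its encoding context."""

    stim_id: str
    reward_prob: float
    wof_condition: str  # one of WOF_CONDITIONS
    day: int
    side_rule: str = "free"  # one of SIDE_RULES
    black_pixels: int = 0  # luminance proxy (black pixel count of the fractal)

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward_prob <= 1.0:
            raise DesignError(f"reward_prob out of [0,1]: {self.reward_prob}")
        if self.wof_condition not in WOF_CONDITIONS:
            raise DesignError(f"unknown wof_condition: {self.wof_condition}")
        if self.side_rule not in SIDE_RULES:
            raise DesignError(f"unknown side_rule: {self.side_rule}")
        if self.black_pixels < 0:
            raise DesignError("black_pixels must be nonnegative")


@dataclass(frozen=True)
class RLBlockSpec:
    """One reinforcement-learning block (two shapes, complementary probabilities)."""

    day: int
    position_in_day: int
    prob_pair: tuple[float, float]
    n_trials: int
    phase: str  # "pre_wof" | "post_wof"
    stimuli: tuple[str, str]  # (higher-probability stim, lower-probability stim)

    def __post_init__(self) -> None:
        p, q = self.prob_pair
        if abs(p + q - 1.0) > 1e-9:
            raise DesignError(f"block probabilities must sum to 1, got {self.prob_pair}")
        if self.phase not in ("pre_wof", "post_wof"):
            raise DesignError(f"unknown phase: {self.phase}")


@dataclass(frozen=True)
class WoFSpec:
    """One wheel-of-fortune draw. Magnitude in integer pence (whole-pence currency)."""

    outcome: str  # "win" | "loss" | "blank"
    magnitude_pence: int
    day: int

    def __post_init__(self) -> None:
        if self.outcome not in ("win", "loss", "blank"):
            raise DesignError(f"unknown WoF outcome: {self.outcome}")


@dataclass(frozen=True)
class PreferenceTestSpec:
    """Shape of the preference test."""

    n_trials: int
    n_blocks: int = 3
    equal_value_priority: float = 1.0
    sidedness: str = "random"  # "sided" | "random"

    def __post_init__(self) -> None:
        if self.sidedness not in ("sided", "random"):
            raise DesignError(f"unknown sidedness: {self.sidedness}")
        if not 0.0 <= self.equal_value_priority <= 1.0:
            raise DesignError("equal_value_priority must be in [0,1]")


@dataclass
class StudyDesign:
    """A fully enumerated study design."""

    study_id: str
    n_learning_days: int
    n_preference_days: int
    stimuli: dict[str, StimulusSpec]
    blocks: list[RLBlockSpec]
    wof_schedule: list[WoFSpec]
    preference_spec: PreferenceTestSpec
    mood_sampling_points: list[str]
    counterbalance_arm: int = 0
    win_side_day1: str = "left"  # preference-test side of post-win shapes (sided mode)
    schema_version: int = SCHEMA_VERSION

    # ---- convenience ---------------------------------------------------
    def stim_ids(self) -> list[str]:
        return list(self.stimuli)

    def wof_outcome_for_day(self, day: int) -> str:
        for w in self.wof_schedule:
            if w.day == day:
                return w.outcome
        raise DesignError(f"no WoF draw scheduled on day {day}")

    def win_side(self, test_day: int = 1) -> str:
        """Screen side of post-win shapes on a given preference-test day.

        Sides are swapped between the two preference-test days of the lab
        design to counterbalance within participant.
        """
        side = self.win_side_day1
        if test_day % 2 == 0:
            side = "right" if side == "left" else "left"
        return side

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimuli"] = {k: asdict(v) for k, v in self.stimuli.items()}
        d["blocks"] = [asdict(b) for b in self.blocks]
        d["wof_schedule"] = [asdict(w) for w in self.wof_schedule]
        d["preference_spec"] = asdict(self.preference_spec)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise DesignError(f"unsupported schema_version: {d.get('schema_version')}")
        stimuli = {k: StimulusSpec(**v) for k, v in d["stimuli"].items()}
        blocks = [
            RLBlockSpec(**{**b, "prob_pair": tuple(b["prob_pair"]),
                           "stimuli": tuple(b["stimuli"])})
            for b in d["blocks"]
        ]
        wof = [WoFSpec(**w) for w in d["wof_schedule"]]
        pref = PreferenceTestSpec(**d["preference_spec"])
        return cls(
            study_id=d["study_id"],
            n_learning_days=d["n_learning_days"],
            n_preference_days=d["n_preference_days"],
            stimuli=stimuli,
            blocks=blocks,
            wof_schedule=wof,
            preference_spec=pref,
            mood_sampling_points=list(d["mood_sampling_points"]),
            counterbalance_arm=d.get("counterbalance_arm", 0),
            win_side_day1=d.get("win_side_day1", "left"),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "StudyDesign":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Canonical designs
# ---------------------------------------------------------------------------

# Black-pixel counts of the post-win / post-loss fractals (ordered 90, 80,
# 20, 10 % reward probability).  These are per-stimulus luminance proxies of
# the actual lab-design fractals; counts for baseline and post-neutral shapes
# were not catalogued and carry synthetic mid-range values.
_STUDY1_WIN_PIXELS = {0.9: 3103, 0.8: 3325, 0.2: 6448, 0.1: 7005}
_STUDY1_LOSS_PIXELS = {0.9: 2298, 0.8: 3944, 0.2: 2714, 0.1: 9201}
_STUDY1_NEUTRAL_PIXELS = {0.9: 3000, 0.8: 3600, 0.2: 5200, 0.1: 6800}
_STUDY1_BASELINE_PIXELS = {0.7: 4100, 0.3: 5400}

_WOF_OUTCOME_MAGNITUDE = {
    "study1": {"win": 1500, "loss": -1100, "blank": 0},
    "study2": {"win": 1400, "loss": -700},
}

_CONDITION_OF_OUTCOME = {"win": "post_win", "loss": "post_loss", "blank": "post_neutral"}


def _study1_wof_order(arm: int) -> list[str]:
    orders = list(itertools.permutations(["win", "loss", "blank"]))
    return list(orders[arm % 6])


def _study2_wof_order(arm: int) -> list[str]:
    return ["win", "loss"] if arm % 2 == 0 else ["loss", "win"]


def build_canonical_design(study_id: str, counterbalance_arm: int = 0) -> StudyDesign:
    """Build one of the two canonical designs.

    ``counterbalance_arm`` permutes the WoF outcome order across days and, for
    the lab design, selects the preference-test side of post-win shapes; it
    never changes the block/probability structure.
    """
    if study_id == "study1":
        return _build_study1(counterbalance_arm)
    if study_id == "study2":
        return _build_study2(counterbalance_arm)
    raise DesignError(f"unknown study_id: {study_id!r} (expected 'study1' or 'study2')")


def _build_study1(arm: int) -> StudyDesign:
    order = _study1_wof_order(arm)
    win_side = "left" if (arm // 6) % 2 == 0 else "right"
    stimuli: dict[str, StimulusSpec] = {}
    blocks: list[RLBlockSpec] = []
    wof: list[WoFSpec] = []

    # Baseline 0.7/0.3 block reuses the same two shapes on all 3 days.
    for p in (0.7, 0.3):
        sid = f"base_{int(p * 100)}"
        stimuli[sid] = StimulusSpec(
            sid, p, "baseline_pre", day=1, side_rule="free",
            black_pixels=_STUDY1_BASELINE_PIXELS[p],
        )
    for day in range(1, 4):
        outcome = order[day - 1]
        cond = _CONDITION_OF_OUTCOME[outcome]
        wof.append(WoFSpec(outcome, _WOF_OUTCOME_MAGNITUDE["study1"][outcome], day))
        blocks.append(RLBlockSpec(day, 1, (0.7, 0.3), 30, "pre_wof",
                                  ("base_70", "base_30")))
        for pos, (p_hi, p_lo) in enumerate([(0.9, 0.1), (0.8, 0.2)], start=2):
            pair = []
            for p in (p_hi, p_lo):
                sid = f"d{day}_{cond[5:]}_{int(p * 100)}"
                if cond == "post_win":
                    px = _STUDY1_WIN_PIXELS[p]
                    rule = "left_only" if win_side == "left" else "right_only"
                elif cond == "post_loss":
                    px = _STUDY1_LOSS_PIXELS[p]
                    rule = "right_only" if win_side == "left" else "left_only"
                else:
                    px = _STUDY1_NEUTRAL_PIXELS[p]
                    rule = "free"
                stimuli[sid] = StimulusSpec(sid, p, cond, day, rule, px)
                pair.append(sid)
            blocks.append(RLBlockSpec(day, pos, (p_hi, p_lo), 90, "post_wof",
                                      tuple(pair)))

    return StudyDesign(
        study_id="study1",
        n_learning_days=3,
        n_preference_days=2,
        stimuli=stimuli,
        blocks=blocks,
        wof_schedule=wof,
        preference_spec=PreferenceTestSpec(n_trials=400, n_blocks=3,
                                           equal_value_priority=1.0,
                                           sidedness="sided"),
        mood_sampling_points=["start", "pre_wof", "post_wof", "end"],
        counterbalance_arm=arm,
        win_side_day1=win_side,
    )


def _study2_black_pixels(day: int, position: int, p: float) -> int:
    # Synthetic but deterministic per-stimulus counts in the catalogued range.
    return int(2000 + 600 * day + 350 * position + 4000 * (1 - p))


def _build_study2(arm: int) -> StudyDesign:
    order = _study2_wof_order(arm)
    stimuli: dict[str, StimulusSpec] = {}
    blocks: list[RLBlockSpec] = []
    wof: list[WoFSpec] = []
    probs = [(0.9, 0.1), (0.75, 0.25), (0.6, 0.4)]

    for day in range(1, 3):
        outcome = order[day - 1]
        wof.append(WoFSpec(outcome, _WOF_OUTCOME_MAGNITUDE["study2"][outcome], day))
        for phase, phase_positions in (("pre_wof", (1, 2, 3)), ("post_wof", (4, 5, 6))):
            cond = "baseline_pre" if phase == "pre_wof" else _CONDITION_OF_OUTCOME[outcome]
            for pos, (p_hi, p_lo) in zip(phase_positions, probs):
                pair = []
                for p in (p_hi, p_lo):
                    tag = "pre" if phase == "pre_wof" else cond[5:]
                    sid = f"d{day}_b{pos}_{tag}_{int(round(p * 100))}"
                    stimuli[sid] = StimulusSpec(
                        sid, p, cond, day, "free",
                        _study2_black_pixels(day, pos, p),
                    )
                    pair.append(sid)
                blocks.append(RLBlockSpec(day, pos, (p_hi, p_lo), 40, phase,
                                          tuple(pair)))

    return StudyDesign(
        study_id="study2",
        n_learning_days=2,
        n_preference_days=1,
        stimuli=stimuli,
        blocks=blocks,
        wof_schedule=wof,
        preference_spec=PreferenceTestSpec(n_trials=456, n_blocks=3,
                                           equal_value_priority=1.0,
                                           sidedness="random"),
        mood_sampling_points=["start", "post_b1", "post_b2", "pre_wof",
                              "post_wof", "post_b4", "post_b5", "end"],
        counterbalance_arm=arm,
    )


# ---------------------------------------------------------------------------
# Pairing grids
# ---------------------------------------------------------------------------

def enumerate_pairing_grid(design: StudyDesign, ordered: bool = True
                           ) -> list[tuple[str, str]]:
    """All distinct stimulus pairs: n(n-1) ordered or n(n-1)/2 unordered."""
    ids = design.stim_ids()
    if len(ids) < 2:
        raise DesignError("pairing grid requires at least 2 stimuli")
    if ordered:
        return list(itertools.permutations(ids, 2))
    return list(itertools.combinations(ids, 2))


def equal_value_contrasts(design: StudyDesign) -> list[tuple[str, str]]:
    """Unordered pairs of distinct stimuli with equal reward probability but
    different WoF condition — the equal-value cross-condition comparisons."""
    out = []
    for a, b in itertools.combinations(design.stimuli.values(), 2):
        if a.reward_prob == b.reward_prob and a.wof_condition != b.wof_condition:
            out.append((a.stim_id, b.stim_id))
    return out


def count_condition_level_contrasts(design: StudyDesign) -> int:
    """Number of distinct (probability level, condition pair) contrasts spanned
    by :func:`equal_value_contrasts` (collapses duplicate stimuli per cell)."""
    seen = set()
    for a, b in equal_value_contrasts(design):
        sa, sb = design.stimuli[a], design.stimuli[b]
        key = (sa.reward_prob, tuple(sorted([sa.wof_condition, sb.wof_condition])))
        seen.add(key)
    return len(seen)


# ---------------------------------------------------------------------------
# Preference-trial generation
# ---------------------------------------------------------------------------

def _sided_admissible(design: StudyDesign, a: str, b: str) -> bool:
    """Whether a pair can be shown under sided presentation (the two shapes
    must not demand the same exclusive side)."""
    ra, rb = design.stimuli[a].side_rule, design.stimuli[b].side_rule
    if ra == "free" or rb == "free":
        return True
    return ra != rb


def _assign_sides(design: StudyDesign, a: str, b: str, test_day: int,
                  rng: np.random.Generator) -> tuple[str, str]:
    """Return (left_stim, right_stim) respecting side rules on this test day.

    Side rules are stored for test day 1; they flip on even test days along
    with the win side.
    """
    flip = test_day % 2 == 0

    def wants_left(sid: str):
        rule = design.stimuli[sid].side_rule
        if rule == "free":
            return None
        on_left = rule == "left_only"
        return (not on_left) if flip else on_left

    wa, wb = wants_left(a), wants_left(b)
    if wa is None and wb is None:
        return (a, b) if rng.random() < 0.5 else (b, a)
    if wa is True or wb is False:
        return (a, b)
    return (b, a)


def generate_preference_trials(design: StudyDesign, seed: int,
                               test_day: int = 1) -> pd.DataFrame:
    """Generate one preference test's trial templates.

    Every admissible unordered pair is covered once; remaining slots are
    filled by resampling equal-value cross-condition pairs (with probability
    ``equal_value_priority``, otherwise uniformly from the grid), matching
    the tests' emphasis on equal-probability comparisons.  Under sided
    presentation, pairs whose two shapes demand the same exclusive side are
    not presentable and are excluded from the grid.
    """
    rng = np.random.default_rng(seed)
    spec = design.preference_spec
    pairs = enumerate_pairing_grid(design, ordered=False)
    if spec.sidedness == "sided":
        pairs = [p for p in pairs if _sided_admissible(design, *p)]
    eq_pairs = [p for p in equal_value_contrasts(design)
                if spec.sidedness != "sided" or _sided_admissible(design, *p)]

    n = spec.n_trials
    if n < len(pairs):
        warnings.warn(
            f"n_trials={n} < grid size {len(pairs)}: full pair coverage "
            "is not guaranteed", stacklevel=2)
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=n, replace=False)]
    else:
        chosen = list(pairs)
        n_fill = n - len(pairs)
        fill_from_eq = rng.random(n_fill) < spec.equal_value_priority
        for use_eq in fill_from_eq:
            pool = eq_pairs if (use_eq and eq_pairs) else pairs
            chosen.append(pool[rng.integers(len(pool))])

    order = rng.permutation(len(chosen))
    rows = []
    block_size = int(np.ceil(len(chosen) / spec.n_blocks))
    for idx, k in enumerate(order):
        a, b = chosen[k]
        left, right = _assign_sides(design, a, b, test_day, rng)
        sl, sr = design.stimuli[left], design.stimuli[right]
        rows.append({
            "phase": "preference",
            "day": test_day,
            "block": idx // block_size + 1,
            "trial_idx": idx,
            "left_stim": left,
            "right_stim": right,
            "left_prob": sl.reward_prob,
            "right_prob": sr.reward_prob,
            "left_condition": sl.wof_condition,
            "right_condition": sr.wof_condition,
        })
    return pd.DataFrame(rows)
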