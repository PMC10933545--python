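"""Synthetic multi-subject datasets with the statistical structure the
analysis pipeline assumes.

A simulated participant is a softmax Rescorla-Wagner learner during the RL
blocks and a probability-weighting chooser during the preference test, with
condition-specific (delta, gamma) arms attached to the WoF condition under
which each shape was encoded.  Mood ratings shift after the WoF draw in
proportion to its monetary outcome, and (optionally) a pupil trace is
generated around every preference trial:

* a pre-choice phasic component whose amplitude decreases with the
  subjective expected value of the to-be-chosen shape,
* a sustained post-choice component over the 4-s outcome-delivery window
  whose amplitude follows the valence x probability crossover (win below
  loss/neutral for low-probability choices, above for high-probability
  choices) scaled by the subject's own generative weighting-curve bias,
* AR(1) Gaussian noise and Poisson blinks marked as invalid runs.

Ground-truth parameters are always stored alongside the data so parameter
recovery never re-enters the generator.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import learning as _learning
from .design import StudyDesign, StimulusSpec, build_canonical_design, \
    generate_preference_trials
from .valuation import weight_probability, auc_weighting_curve
from scipy.special import expit


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

@dataclass
class AgentParams:
    """Ground-truth generative parameters of one simulated participant."""

    alpha: float = 0.35
    beta_learn: float = 6.0
    delta_win: float = 0.9
    gamma_win: float = 1.3
    delta_loss: float = 1.0
    gamma_loss: float = 0.8
    delta_neutral: float = 1.0
    gamma_neutral: float = 1.0
    beta_pref: float = 5.0
    mood_gain: float = 0.015  # normalized-mood shift per pound of WoF outcome
    pupil_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta_learn", "delta_win", "gamma_win",
                     "delta_loss", "gamma_loss", "delta_neutral",
                     "gamma_neutral", "beta_pref"):
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be strictly positive")
        if self.pupil_gain < 0:
            raise SynthError("pupil_gain must be nonnegative")

    def arm_of_condition(self, condition: str) -> tuple[float, float]:
        if condition == "post_win":
            return self.delta_win, self.gamma_win
        if condition == "post_loss":
            return self.delta_loss, self.gamma_loss
        return self.delta_neutral, self.gamma_neutral

    def true_delta_auc(self) -> float:
        """AuC(win arm) - AuC(loss arm) of the generative weighting curves."""
        return (auc_weighting_curve(self.delta_win, self.gamma_win)
                - auc_weighting_curve(self.delta_loss, self.gamma_loss))


#: Population means and SDs used when emulating the two cohorts.  The win
#: arm carries higher curvature and slightly lower elevation than the loss
#: arm, producing the crossover of the weighting trajectories and a positive
#: mean weighting-curve bias of moderate effect size.
DEFAULT_POPULATION: dict[str, tuple[float, float]] = {
    "alpha": (0.35, 0.15),
    "beta_learn": (6.0, 2.0),
    "delta_win": (0.9, 0.25),
    "gamma_win": (1.3, 0.3),
    "delta_loss": (1.0, 0.25),
    "gamma_loss": (0.8, 0.3),
    "delta_neutral": (1.0, 0.15),
    "gamma_neutral": (1.0, 0.15),
    "beta_pref": (5.0, 2.0),
    "mood_gain": (0.015, 0.005),
    "pupil_gain": (1.0, 0.3),
}

#: Same marginals but no win/loss asymmetry: null cohorts for type-I checks.
NULL_POPULATION: dict[str, tuple[float, float]] = {
    **DEFAULT_POPULATION,
    "delta_win": (1.0, 0.25), "gamma_win": (1.0, 0.3),
    "delta_loss": (1.0, 0.25), "gamma_loss": (1.0, 0.3),
    "mood_gain": (0.0, 0.0),
}

_PARAM_CLIP = {
    "alpha": (0.02, 0.98), "beta_learn": (0.5, 25.0),
    "beta_pref": (0.5, 25.0), "pupil_gain": (0.0, 5.0),
    "mood_gain": (-1.0, 1.0),
}
_WEIGHT_CLIP = (0.2, 4.0)


def draw_agent(hyper: dict[str, tuple[float, float]],
               rng: np.random.Generator) -> AgentParams:
    kwargs = {}
    for name, (mu, sd) in hyper.items():
        if sd < 0:
            raise SynthError(f"negative SD for {name}")
        v = rng.normal(mu, sd) if sd > 0 else mu
        lo, hi = _PARAM_CLIP.get(name, _WEIGHT_CLIP)
        kwargs[name] = float(np.clip(v, lo, hi))
    return AgentParams(**kwargs)


# ---------------------------------------------------------------------------
# Pupil trace generation
# ---------------------------------------------------------------------------

@dataclass
class PupilTraceSpec:
    """Generative model of one trial's pupil trace."""

    fs: float = 500.0
    baseline_noise_sd: float = 0.15
    ar_coefficient: float = 0.97
    blink_rate: float = 0.1  # blinks per second
    blink_duration_ms: tuple[float, float] = (100.0, 400.0)
    kernel_shape: float = 10.1  # gamma-family impulse response ...
    kernel_tmax: float = 0.93  # ... peaking at ~930 ms
    pre_choice_ref: float = 0.5  # EV level at which the phasic response is 0
    sustained_gain: dict = field(default_factory=dict)  # (valence, level) -> gain
    gain: float = 1.0  # overall amplitude scale (subject pupil_gain)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SynthError("fs must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise SynthError("ar_coefficient must be in [0, 1)")


def default_sustained_gain(bias: float, base: float = 0.25,
                           prob_boost: float = 0.10,
                           crossover_gain: float = 3.0,
                           fixed_crossover: float = 0.12) -> dict:
    """Sustained-response amplitudes per (valence, probability level).

    Non-win cells sit at ``base`` (+ ``prob_boost`` for high-probability
    choices); the win cell is shifted upward for high- and downward for
    low-probability choices by a population-level component
    (``fixed_crossover``) plus a behaviour-coupled component
    (``crossover_gain * bias``), so the cohort shows the valence crossover
    and individual pupil indices track individual weighting-curve bias.
    """
    out = {}
    for v in ("win", "loss", "neutral", "baseline"):
        for lvl, boost in (("low", 0.0), ("high", prob_boost)):
            amp = base + boost
            if v == "win":
                shift = fixed_crossover + crossover_gain * bias
                amp += shift * (1.0 if lvl == "high" else -1.0)
            out[(v, lvl)] = amp
    return out


def pupil_response_kernel(spec: PupilTraceSpec, duration_s: float = 3.0
                          ) -> np.ndarray:
    """Gamma-family impulse response h(t) = (t/tmax)^n exp(n (1 - t/tmax)),
    normalised to peak 1 at t = tmax."""
    t = np.arange(0.0, duration_s, 1.0 / spec.fs)
    n, tmax = spec.kernel_shape, spec.kernel_tmax
    with np.errstate(divide="ignore"):
        h = (t / tmax) ** n * np.exp(n * (1.0 - t / tmax))
    h[0] = 0.0
    return h


_VALENCE_OF_CONDITION = {"post_win": "win", "post_loss": "loss",
                         "post_neutral": "neutral", "baseline_pre": "baseline"}


def simulate_pupil_trial(ev_chosen: float, valence: str, prob_level: str,
                         spec: PupilTraceSpec, seed: int, rt: float = 1.44,
                         baseline_dur: float = 2.0, outcome_dur: float = 4.0,
                         gap_dur: float = 0.5
                         ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One trial's pupil samples and validity mask.

    Timeline: ``baseline_dur`` of rest, stimulus onset, ``rt`` seconds of
    deliberation, choice, ``outcome_dur`` of outcome display, ``gap_dur``.
    Returns (samples, valid, stim_onset_s, choice_s) with times relative to
    the trial start.
    """
    if not np.isfinite(ev_chosen):
        raise SynthError("ev_chosen must be finite")
    rng = np.random.default_rng(seed)
    fs = spec.fs
    n = int(round((baseline_dur + rt + outcome_dur + gap_dur) * fs))
    stim_onset = baseline_dur
    choice_t = baseline_dur + rt

    signal = np.zeros(n)
    kernel = pupil_response_kernel(spec)

    # pre-choice phasic response: larger for lower-EV choices
    amp_pre = spec.gain * (spec.pre_choice_ref - ev_chosen)
    i0 = int(round(stim_onset * fs))
    seg = min(len(kernel), n - i0)
    signal[i0:i0 + seg] += amp_pre * kernel[:seg]

    # sustained post-choice component: kernel-smoothed boxcar over outcome
    amp_sus = spec.gain * spec.sustained_gain.get((valence, prob_level), 0.0)
    i1 = int(round(choice_t * fs))
    box = np.zeros(n - i1)
    box[: int(round(outcome_dur * fs))] = 1.0
    smooth = np.convolve(box, kernel)[: n - i1]
    peak = smooth.max() if smooth.size and smooth.max() > 0 else 1.0
    signal[i1:] += amp_sus * smooth / peak

    # AR(1) noise with stationary sd = baseline_noise_sd
    if spec.baseline_noise_sd > 0:
        from scipy.signal import lfilter

        innov_sd = spec.baseline_noise_sd * np.sqrt(1 - spec.ar_coefficient ** 2)
        e = rng.normal(0.0, innov_sd, n)
        e[0] = rng.normal(0.0, spec.baseline_noise_sd)  # stationary start
        noise = lfilter([1.0], [1.0, -spec.ar_coefficient], e)
        signal += noise

    valid = np.ones(n, dtype=bool)
    if spec.blink_rate > 0:
        n_blinks = rng.poisson(spec.blink_rate * n / fs)
        for _ in range(n_blinks):
            dur = rng.uniform(*spec.blink_duration_ms) / 1000.0
            start = rng.integers(0, n)
            stop = min(n, start + int(round(dur * fs)))
            valid[start:stop] = False
    signal[~valid] = np.nan
    return signal, valid, stim_onset, choice_t


# ---------------------------------------------------------------------------
# Subject and cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectDataset:
    subject_id: str
    design: StudyDesign
    agent_params: AgentParams
    learning_trials: pd.DataFrame
    preference_trials: pd.DataFrame
    mood_ratings: pd.DataFrame
    pupil_samples: pd.DataFrame | None = None
    pupil_events: pd.DataFrame | None = None


def _generative_weights(trials: pd.DataFrame, agent: AgentParams,
                        design: StudyDesign) -> tuple[np.ndarray, np.ndarray]:
    """Subjective weights of the left and right option of every trial.

    Under sided presentation the affective distortion attaches to the screen
    side carrying the post-WoF win (or loss) shapes, so every shape shown on
    the win side is weighted by the win arm and every shape on the loss side
    by the loss arm.  With randomised sides the distortion attaches to the
    shape's own encoding condition.
    """
    wl = np.empty(len(trials))
    wr = np.empty(len(trials))
    if design.preference_spec.sidedness == "sided":
        day = trials["day"].to_numpy()
        for d_test in np.unique(day):
            win_left = design.win_side(int(d_test)) == "left"
            m = day == d_test
            for col, out, is_left in (("left_prob", wl, True),
                                      ("right_prob", wr, False)):
                arm = ((agent.delta_win, agent.gamma_win)
                       if is_left == win_left
                       else (agent.delta_loss, agent.gamma_loss))
                out[m] = weight_probability(
                    trials.loc[m, col].to_numpy(dtype=float), *arm)
    else:
        for col_cond, col_prob, out in (("left_condition", "left_prob", wl),
                                        ("right_condition", "right_prob", wr)):
            cond = trials[col_cond].to_numpy()
            prob = trials[col_prob].to_numpy(dtype=float)
            for c in np.unique(cond):
                d, g = agent.arm_of_condition(c)
                m = cond == c
                out[m] = weight_probability(prob[m], d, g)
    return wl, wr


def _preference_choice_prob_left(trials: pd.DataFrame, agent: AgentParams,
                                 design: StudyDesign) -> np.ndarray:
    wl, wr = _generative_weights(trials, agent, design)
    return expit(agent.beta_pref * (wl - wr))


def _simulate_mood(design: StudyDesign, agent: AgentParams,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Normalized happiness ratings at the design's sampling points.

    The WoF outcome shifts mood by mood_gain x outcome (in pounds), decaying
    geometrically over subsequent sampling points within the day.
    """
    likert = design.study_id == "study1"
    baseline = float(np.clip(rng.normal(0.62, 0.08), 0.1, 0.9))
    rows = []
    points = design.mood_sampling_points
    post_idx = points.index("post_wof")
    for wof in design.wof_schedule:
        shift = agent.mood_gain * wof.magnitude_pence / 100.0
        for k, label in enumerate(points):
            mu = baseline
            if k >= post_idx:
                mu = baseline + shift * (0.8 ** (k - post_idx))
            val = float(np.clip(mu + rng.normal(0.0, 0.05), 0.0, 1.0))
            if likert:
                raw = int(np.clip(round(1 + val * 8), 1, 9))
                norm = (raw - 1) / 8.0
                scale = "likert_1_9"
            else:
                raw = round(val * 100.0, 1)
                norm = raw / 100.0
                scale = "vas_0_100"
            rows.append({"day": wof.day, "timepoint": label,
                         "wof_outcome": wof.outcome, "rating_raw": raw,
                         "rating_norm": norm, "scale": scale})
    return pd.DataFrame(rows)


def _simulate_pupil_session(trials: pd.DataFrame, agent: AgentParams,
                            design: StudyDesign, spec: PupilTraceSpec,
                            rng: np.random.Generator
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples, valid = [], []
    events = []
    t0 = 0.0
    trials = trials.reset_index(drop=True)
    wl, wr = _generative_weights(trials, agent, design)
    for i, row in enumerate(trials.itertuples()):
        chosen_left = row.choice == "left"
        cond = row.left_condition if chosen_left else row.right_condition
        prob = row.left_prob if chosen_left else row.right_prob
        ev = float(wl[i] if chosen_left else wr[i])
        valence = _VALENCE_OF_CONDITION[cond]
        level = "high" if prob > 0.5 else "low"
        rt = float(np.clip(rng.lognormal(np.log(1.35), 0.3), 0.4, 4.0))
        sig, ok, stim_onset, choice_t = simulate_pupil_trial(
            ev, valence, level, spec, seed=int(rng.integers(2 ** 31)), rt=rt)
        samples.append(sig)
        valid.append(ok)
        events.append({"trial_id": row.trial_idx,
                       "stim_onset_s": t0 + stim_onset,
                       "choice_s": t0 + choice_t})
        t0 += len(sig) / spec.fs
    sig = np.concatenate(samples)
    ok = np.concatenate(valid)
    time = np.arange(len(sig)) / spec.fs
    pupil = pd.DataFrame({"time_s": time, "pupil": sig,
                          "valid": ok.astype(int)})
    return pupil, pd.DataFrame(events)


def make_subject_trace_spec(agent: AgentParams,
                            base_spec: PupilTraceSpec | None = None
                            ) -> PupilTraceSpec:
    """Attach a subject's gain and behaviour-coupled sustained amplitudes."""
    spec = base_spec or PupilTraceSpec()
    spec = dataclasses.replace(
        spec, gain=agent.pupil_gain,
        sustained_gain=default_sustained_gain(agent.true_delta_auc()))
    return spec


def simulate_subject(design: StudyDesign, agent: AgentParams, seed: int,
                     with_pupil: bool = False,
                     trace_spec: PupilTraceSpec | None = None,
                     subject_id: str = "sub-001") -> SubjectDataset:
    """Simulate one participant end to end."""
    rng = np.random.default_rng(seed)

    learn_frames = []
    total = 1500
    for block in design.blocks:
        df = _learning.simulate_learning_block(
            block, agent.alpha, agent.beta_learn,
            seed=int(rng.integers(2 ** 31)), start_total_pence=total)
        total = int(df["running_total"].iloc[-1])
        learn_frames.append(df)
    learning_trials = pd.concat(learn_frames, ignore_index=True)

    pref_frames = []
    for test_day in range(1, design.n_preference_days + 1):
        trials = generate_preference_trials(
            design, seed=int(rng.integers(2 ** 31)), test_day=test_day)
        p_left = _preference_choice_prob_left(trials, agent, design)
        trials = trials.copy()
        trials["choice"] = np.where(rng.random(len(trials)) < p_left,
                                    "left", "right")
        pref_frames.append(trials)
    preference_trials = pd.concat(pref_frames, ignore_index=True)

    mood = _simulate_mood(design, agent, rng)

    pupil_samples = pupil_events = None
    if with_pupil:
        spec = make_subject_trace_spec(agent, base_spec=trace_spec)
        day1 = preference_trials[preference_trials["day"] == 1]
        pupil_samples, pupil_events = _simulate_pupil_session(
            day1, agent, design, spec, rng)

    for df in (learning_trials, preference_trials, mood):
        df.insert(0, "subject_id", subject_id)
    if pupil_samples is not None:
        pupil_samples.insert(0, "subject_id", subject_id)
        pupil_events.insert(0, "subject_id", subject_id)
    return SubjectDataset(subject_id, design, agent, learning_trials,
                          preference_trials, mood, pupil_samples, pupil_events)


def randomize_stimulus_labels(design: StudyDesign, seed: int) -> StudyDesign:
    """Shuffle which shape identity carries which probability/condition slot
    (the online design randomises this per participant)."""
    rng = np.random.default_rng(seed)
    old_ids = design.stim_ids()
    new_ids = [f"s{i:02d}" for i in rng.permutation(len(old_ids))]
    mapping = dict(zip(old_ids, new_ids))
    stimuli = {mapping[k]: dataclasses.replace(v, stim_id=mapping[k])
               for k, v in design.stimuli.items()}
    blocks = [dataclasses.replace(b, stimuli=(mapping[b.stimuli[0]],
                                              mapping[b.stimuli[1]]))
              for b in design.blocks]
    return dataclasses.replace(design, stimuli=stimuli, blocks=blocks)


def simulate_population(design_or_study: StudyDesign | str, n_subjects: int,
                        hyper: dict | None = None, seed: int = 0,
                        with_pupil: bool = False,
                        trace_spec: PupilTraceSpec | None = None
                        ) -> list[SubjectDataset]:
    """Simulate a cohort; counterbalance arms alternate across subjects and
    per-subject randomness derives from a seed sequence off ``seed``."""
    if n_subjects < 1:
        raise SynthError("n_subjects must be >= 1")
    hyper = hyper or DEFAULT_POPULATION
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        if isinstance(design_or_study, str):
            design = build_canonical_design(design_or_study, counterbalance_arm=i)
        elif design_or_study.study_id in ("study1", "study2"):
            # rebuild so the arm actually permutes the WoF schedule / sides,
            # keeping any customised preference spec
            design = build_canonical_design(design_or_study.study_id,
                                            counterbalance_arm=i)
            design.preference_spec = design_or_study.preference_spec
        else:
            design = dataclasses.replace(design_or_study, counterbalance_arm=i)
        if design.study_id == "study2":
            design = randomize_stimulus_labels(design,
                                               seed=int(rng.integers(2 ** 31)))
        agent = draw_agent(hyper, rng)
        sub = simulate_subject(design, agent, seed=int(rng.integers(2 ** 31)),
                               with_pupil=with_pupil, trace_spec=trace_spec,
                               subject_id=f"sub-{i + 1:03d}")
        out.append(sub)
    return out


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(datasets: list[SubjectDataset], outdir: str) -> None:
    """One directory per cohort: delimited-text tables plus ground truth."""
    os.makedirs(outdir, exist_ok=True)
    for name in ("learning_trials", "preference_trials", "mood_ratings"):
        df = pd.concat([getattr(d, name) for d in datasets], ignore_index=True)
        fname = {"learning_trials": "learning.tsv",
                 "preference_trials": "preference.tsv",
                 "mood_ratings": "mood.tsv"}[name]
        df.to_csv(os.path.join(outdir, fname), sep="\t", index=False)
    pupil = [d.pupil_samples for d in datasets if d.pupil_samples is not None]
    if pupil:
        pd.concat(pupil, ignore_index=True).to_csv(
            os.path.join(outdir, "pupil.tsv.gz"), sep="\t", index=False)
        pd.concat([d.pupil_events for d in datasets
                   if d.pupil_events is not None], ignore_index=True).to_csv(
            os.path.join(outdir, "events.tsv"), sep="\t", index=False)
    truth = {d.subject_id: dataclasses.asdict(d.agent_params) for d in datasets}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    datasets[0].design.to_json(os.path.join(outdir, "design.json"))
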