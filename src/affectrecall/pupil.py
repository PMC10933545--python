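"""Pupillometry preprocessing and model-based analysis.

The pipeline order is fixed: linear interpolation across invalid runs
(blinks), zero-phase Butterworth low-pass at 3.75 Hz, z-transform across
the whole session, then event-locked epoching with 2-s pre-event baseline
subtraction.  Trials whose outcome window is more than 50% interpolated are
excluded (strictly more than: exactly 50% is kept).

Two epochs per trial are analysed: a stimulus-locked pre-choice window and
a choice-locked 0-4 s outcome window (the chosen shape stays on screen for
4 s with no feedback).  The first-level GLM regresses, at every time point,
the pupil value across trials on trial-wise regressors (model-derived
expected value of the chosen shape, absolute expected-value difference as
choice difficulty, and the two shapes' black-pixel counts as luminance
controls).  Second-level inference is a one-sample t test across subjects
at every time point, with significant runs reported only beyond a minimum
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import signal as sps
from scipy import stats


class PupilError(ValueError):
    pass


@dataclass
class PupilSession:
    """One subject's continuous recording plus trial event markers."""

    subject_id: str
    fs: float
    samples: np.ndarray
    valid: np.ndarray  # bool; False inside blink/missing runs
    events: pd.DataFrame  # trial_id, stim_onset_s, choice_s
    interpolated: np.ndarray | None = None  # set by interpolate_invalid

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.samples) != len(self.valid):
            raise PupilError("samples and validity must have equal length")

    @classmethod
    def from_tables(cls, pupil: pd.DataFrame, events: pd.DataFrame,
                    subject_id: str | None = None, fs: float | None = None
                    ) -> "PupilSession":
        """Build from the pupil.tsv / events.tsv schema."""
        if subject_id is not None:
            pupil = pupil[pupil["subject_id"] == subject_id]
            events = events[events["subject_id"] == subject_id]
        elif "subject_id" in pupil.columns:
            subject_id = str(pupil["subject_id"].iloc[0])
        if fs is None:
            dt = np.median(np.diff(pupil["time_s"].to_numpy()))
            fs = 1.0 / dt
        return cls(subject_id or "unknown", float(fs),
                   pupil["pupil"].to_numpy(dtype=float),
                   pupil["valid"].to_numpy() > 0,
                   events.reset_index(drop=True))


@dataclass
class PupilEpoch:
    trial_id: int
    samples: np.ndarray  # baseline-corrected, event-locked
    times: np.ndarray  # seconds relative to the locking event
    baseline_mean: float
    frac_interpolated: float
    included: bool


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def interpolate_invalid(session: PupilSession) -> PupilSession:
    """Linearly interpolate across invalid runs; leading/trailing invalid
    runs are held at the nearest valid value.  The invalid mask is kept as
    ``interpolated`` for exclusion accounting."""
    ok = session.valid & np.isfinite(session.samples)
    if ok.sum() < 2:
        raise PupilError("fewer than 2 valid samples; cannot interpolate")
    idx = np.arange(len(session.samples))
    filled = np.interp(idx, idx[ok], session.samples[ok])
    return replace(session, samples=filled, valid=np.ones_like(ok),
                   interpolated=~ok)


def lowpass(session: PupilSession, cutoff: float = 3.75,
            order: int = 3) -> PupilSession:
    """Zero-phase (forward-backward) Butterworth low-pass."""
    if session.fs <= 2 * cutoff:
        raise PupilError("sampling rate must exceed twice the cutoff")
    sos = sps.butter(order, cutoff, btype="low", fs=session.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(session.samples) <= 3 * padlen:
        raise PupilError("signal too short for zero-phase filtering")
    filtered = sps.sosfiltfilt(sos, session.samples)
    return replace(session, samples=filtered)


def zscore_session(session: PupilSession) -> PupilSession:
    sd = float(np.std(session.samples))
    if sd == 0:
        raise PupilError("zero-variance session cannot be z-scored")
    z = (session.samples - np.mean(session.samples)) / sd
    return replace(session, samples=z)


def preprocess(session: PupilSession, cutoff: float = 3.75,
               order: int = 3) -> PupilSession:
    """Fixed pipeline: interpolate -> low-pass -> z-score."""
    return zscore_session(lowpass(interpolate_invalid(session), cutoff, order))


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(session: PupilSession, event_s: float,
                       window: tuple[float, float], trial_id: int = 0,
                       baseline_dur: float = 2.0,
                       outcome_window: tuple[float, float] | None = None,
                       max_interp_frac: float = 0.5) -> PupilEpoch:
    """Event-locked epoch minus the mean of the ``baseline_dur`` seconds
    before the event.  The inclusion flag applies the strict >50% rule to
    the interpolated fraction of the outcome window (defaults to the epoch
    window itself)."""
    fs = session.fs
    n = len(session.samples)
    i_ev = int(round(event_s * fs))
    i0, i1 = i_ev + int(round(window[0] * fs)), i_ev + int(round(window[1] * fs))
    ib = i_ev - int(round(baseline_dur * fs))
    if ib < 0 or i0 < 0 or i1 > n:
        raise PupilError(
            f"epoch or baseline outside recording for event at {event_s:.3f}s")
    baseline = float(np.mean(session.samples[ib:i_ev]))
    seg = session.samples[i0:i1] - baseline
    times = (np.arange(i0, i1) - i_ev) / fs

    interp = session.interpolated
    if interp is None:
        interp = np.zeros(n, dtype=bool)
    if outcome_window is None:
        j0, j1 = i0, i1
    else:
        j0 = i_ev + int(round(outcome_window[0] * fs))
        j1 = i_ev + int(round(outcome_window[1] * fs))
    frac = float(np.mean(interp[j0:j1])) if j1 > j0 else 0.0
    return PupilEpoch(trial_id, seg, times, baseline,
                      frac, included=frac <= max_interp_frac)


def extract_epochs(session: PupilSession, lock: str = "choice",
                   window: tuple[float, float] = (0.0, 4.0),
                   baseline_dur: float = 2.0) -> list[PupilEpoch]:
    """Epoch every trial, locked to ``choice`` or ``stim`` onset.

    The interpolation fraction driving inclusion is always computed over
    the choice-locked 0-4 s outcome window.
    """
    col = {"choice": "choice_s", "stim": "stim_onset_s"}[lock]
    out = []
    for row in session.events.itertuples():
        ev = getattr(row, col)
        # outcome window relative to the locking event
        off = row.choice_s - ev
        out.append(epoch_and_baseline(session, ev, window,
                                      trial_id=int(row.trial_id),
                                      baseline_dur=baseline_dur,
                                      outcome_window=(off, off + 4.0)))
    return out


# ---------------------------------------------------------------------------
# Trial-wise GLM
# ---------------------------------------------------------------------------

def first_level_glm(epochs: list[PupilEpoch], regressors: pd.DataFrame
                    ) -> pd.DataFrame:
    """OLS of pupil value across trials, at every time point, on z-scored
    trial regressors plus an intercept.  Only included epochs (and their
    regressor rows) enter.  Returns a time x regressor coefficient table."""
    keep = [i for i, e in enumerate(epochs) if e.included]
    if len(keep) < 10:
        raise PupilError(f"only {len(keep)} included epochs (< 10)")
    Y = np.vstack([epochs[i].samples for i in keep])
    times = epochs[keep[0]].times
    X = regressors.iloc[keep].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise PupilError("regressors must be finite")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(regressors.columns, sd) if s == 0]
        raise PupilError(f"constant regressor column(s): {bad}")
    Xz = (X - X.mean(axis=0)) / sd
    Xd = np.column_stack([Xz, np.ones(len(keep))])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        corr = np.corrcoef(Xz, rowvar=False)
        pairs = [
            (regressors.columns[i], regressors.columns[j])
            for i in range(len(sd)) for j in range(i + 1, len(sd))
            if abs(corr[i, j]) > 0.999]
        raise PupilError(f"rank-deficient design; collinear columns: {pairs}")
    betas, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    cols = list(regressors.columns) + ["intercept"]
    out = pd.DataFrame(betas.T, columns=cols)
    out.insert(0, "time_s", times)
    return out


def second_level_test(beta_timecourses: np.ndarray, times: np.ndarray,
                      alpha: float = 0.05, min_run_s: float = 0.1) -> dict:
    """One-sample t vs 0 at every time point across subjects; reports the
    threshold-crossing runs longer than ``min_run_s`` and the |t| peak."""
    B = np.asarray(beta_timecourses, dtype=float)
    if B.shape[0] < 3:
        raise PupilError("need at least 3 subjects")
    if np.allclose(B, 0.0):
        t = np.zeros(B.shape[1])
        p = np.ones(B.shape[1])
    else:
        t, p = stats.ttest_1samp(B, 0.0, axis=0)
        t = np.nan_to_num(t)
        p = np.nan_to_num(p, nan=1.0)
    sig = p < alpha
    fs = 1.0 / np.median(np.diff(times))
    min_len = int(round(min_run_s * fs))
    runs = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j < len(sig) and sig[j]:
                j += 1
            if j - i >= min_len:
                runs.append((float(times[i]), float(times[j - 1])))
            i = j
        else:
            i += 1
    k = int(np.argmax(np.abs(t)))
    return {"t": t, "p": p, "times": times, "significant_runs": runs,
            "peak_time_s": float(times[k]), "peak_t": float(t[k]),
            "peak_p": float(p[k]), "df": B.shape[0] - 1}


# ---------------------------------------------------------------------------
# Outcome-window binning, rmANOVA, pupil bias index
# ---------------------------------------------------------------------------

def bin_outcome_epoch(epoch: PupilEpoch, bin_width: float = 1.0,
                      n_bins: int = 4) -> np.ndarray:
    """Mean of the baseline-corrected samples in consecutive bins from the
    locking event."""
    t = epoch.times
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        m = (t >= lo) & (t < hi)
        if not m.any():
            raise PupilError(f"bin [{lo}, {hi}) s is outside the epoch")
        out[b] = float(np.mean(epoch.samples[m]))
    return out


def valence_by_time_anova(cell_means: pd.DataFrame,
                          dv: str = "pupil") -> pd.DataFrame:
    """Repeated-measures ANOVA valence x timebin (within-subject), with
    Greenhouse-Geisser correction when sphericity is violated.

    ``cell_means`` is long-format with columns subject, valence, bin, and
    the dv; every subject must contribute every cell (incomplete subjects
    are dropped).
    """
    n_cells = cell_means.groupby("subject").size()
    full = int(n_cells.max())
    complete = n_cells[n_cells == full].index
    dropped = sorted(set(n_cells.index) - set(complete))
    df = cell_means[cell_means["subject"].isin(complete)]
    aov = pg.rm_anova(data=df, dv=dv, within=["valence", "bin"],
                      subject="subject", correction=True, detailed=True)
    aov.attrs["dropped_subjects"] = dropped
    return aov


def pupil_auc_index(bin_means: dict[tuple[str, str], np.ndarray],
                    bin_width: float = 1.0) -> float:
    """Sustained-dilation bias index for one subject.

    ``bin_means`` maps (valence, probability level) to the subject's mean
    binned outcome-window trace.  The index integrates (trapezoid over bin
    centres) the win-minus-mean(loss, neutral) contrast for high-probability
    choices and subtracts the same integral for low-probability choices.
    """
    def contrast_integral(level: str) -> float:
        try:
            win = np.asarray(bin_means[("win", level)], dtype=float)
            loss = np.asarray(bin_means[("loss", level)], dtype=float)
            neut = np.asarray(bin_means[("neutral", level)], dtype=float)
        except KeyError as e:
            raise PupilError(f"missing condition cell: {e}") from None
        c = win - (loss + neut) / 2.0
        centres = (np.arange(len(c)) + 0.5) * bin_width
        return float(np.trapezoid(c, centres))

    return contrast_integral("high") - contrast_integral("low")
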