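"""Group-level statistics, covariate regressions, and the end-to-end
pipeline.

Group inference follows the two-stage summary-statistics approach
throughout: a per-subject statistic (model fit, bias index, regression
coefficient, binned pupil response) followed by a cohort-level test.  The
cohort-level covariate model regresses each subject's weighting-curve bias
(delta AuC) on standardised depression scores, age, gender, and WoF order;
its intercept tests the positive-memory-bias hypothesis at zero covariates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import pupil as _pupil
from . import synthdata as _synth
from . import valuation as _val
from .design import build_canonical_design


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Simple statistical helpers (thin, but centralised so oracles test them)
# ---------------------------------------------------------------------------

def paired_t(a, b) -> dict:
    a, b = np.asarray(a, float), np.asarray(b, float)
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": len(a) - 1, "p": float(p),
            "mean_diff": float(np.mean(a - b))}


def one_sample_t(x, popmean: float = 0.0) -> dict:
    x = np.asarray(x, float)
    t, p = stats.ttest_1samp(x, popmean)
    return {"t": float(t), "df": len(x) - 1, "p": float(p),
            "mean": float(np.mean(x))}


def pearson_r(x, y) -> dict:
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return {"r": float(r), "df": len(x) - 2, "p": float(p)}


# ---------------------------------------------------------------------------
# Mood manipulation check
# ---------------------------------------------------------------------------

def mood_manipulation_check(mood: pd.DataFrame) -> dict:
    """Paired t-tests of pre- vs post-WoF happiness, per WoF outcome.

    Subjects missing either time point for an outcome are skipped for that
    outcome.  Positive mean_diff = happier after the draw.
    """
    out = {}
    for outcome in sorted(mood["wof_outcome"].unique()):
        m = mood[mood["wof_outcome"] == outcome]
        wide = m.pivot_table(index="subject_id", columns="timepoint",
                             values="rating_norm", aggfunc="mean")
        if not {"pre_wof", "post_wof"}.issubset(wide.columns):
            continue
        wide = wide.dropna(subset=["pre_wof", "post_wof"])
        if len(wide) < 2:
            continue
        res = paired_t(wide["post_wof"], wide["pre_wof"])
        res["n"] = len(wide)
        out[outcome] = res
    return out


# ---------------------------------------------------------------------------
# Cohort preference fitting and bias table
# ---------------------------------------------------------------------------

def fit_cohort_preference(datasets: list[_synth.SubjectDataset],
                          test_day: int = 1, n_restarts: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Fit the weighting model per subject on one preference-test day and
    tabulate fits, benchmark comparisons and bias indices."""
    rows = []
    rng = np.random.default_rng(seed)
    for ds in datasets:
        trials = ds.preference_trials[ds.preference_trials["day"] == test_day]
        variant = ("study1_sided" if ds.design.preference_spec.sidedness == "sided"
                   else "study2_valence")
        fit = _val.fit_preference_model(trials, variant=variant,
                                        n_restarts=n_restarts,
                                        seed=int(rng.integers(2 ** 31)))
        null_fit, beta_fit = _val.fit_benchmarks(trials)
        if variant == "study1_sided":
            valence_fit = _val.sided_fit_to_valence_arms(
                fit, ds.design.win_side(test_day))
        else:
            valence_fit = fit
        bias = _val.positive_bias_index(valence_fit)
        rows.append({
            "subject_id": ds.subject_id,
            "variant": variant,
            "test_day": test_day,
            "nll_per_trial_full": fit.nll_per_trial,
            "nll_per_trial_beta_only": beta_fit.nll_per_trial,
            "nll_per_trial_random_null": null_fit.nll_per_trial,
            "beta": fit.params.beta,
            "delta_win": valence_fit.params.arms["win"][0],
            "gamma_win": valence_fit.params.arms["win"][1],
            "delta_loss": valence_fit.params.arms["loss"][0],
            "gamma_loss": valence_fit.params.arms["loss"][1],
            "auc_win": bias.auc_win,
            "auc_loss": bias.auc_loss,
            "delta_auc": bias.delta_auc,
            "model_free_diff": _val.model_free_bias(trials),
        })
    return pd.DataFrame(rows)


def bias_group_tests(bias_table: pd.DataFrame) -> dict:
    """Cohort-level tests on the bias table: positive-bias t-test, model
    comparisons, and the model-free correlation."""
    out = {"delta_auc": one_sample_t(bias_table["delta_auc"])}
    out["full_vs_random_null"] = paired_t(
        bias_table["nll_per_trial_full"],
        bias_table["nll_per_trial_random_null"])
    out["full_vs_beta_only"] = paired_t(
        bias_table["nll_per_trial_full"],
        bias_table["nll_per_trial_beta_only"])
    out["model_free_correlation"] = pearson_r(
        bias_table["delta_auc"], bias_table["model_free_diff"])
    return out


# ---------------------------------------------------------------------------
# Covariate regression on the bias index
# ---------------------------------------------------------------------------

def bias_covariate_regression(bundle: pd.DataFrame) -> pd.DataFrame:
    """OLS: delta_auc ~ intercept + zBDI + age + gender + wof_order.

    ``bundle`` has one row per subject with complete covariates; the BDI
    column is standardised and the remaining covariates are mean-centred,
    so the intercept estimates the covariate-adjusted mean bias and its
    t-test is the positive-bias confirmation.  Returns the coefficient
    table.
    """
    required = ["delta_auc", "bdi", "age", "gender", "wof_order"]
    missing = [c for c in required if c not in bundle.columns]
    if missing:
        raise ReportError(f"bundle lacks columns: {missing}")
    b = bundle.dropna(subset=required)
    if len(b) < 10:
        raise ReportError(f"only {len(b)} subjects with complete covariates")
    z_bdi = (b["bdi"] - b["bdi"].mean()) / b["bdi"].std()
    X = pd.DataFrame({"z_bdi": z_bdi,
                      "age": b["age"] - b["age"].mean(),
                      "gender": b["gender"] - b["gender"].mean(),
                      "wof_order": b["wof_order"] - b["wof_order"].mean()})
    Xd = sm.add_constant(X.astype(float), prepend=True)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        corr = X.astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [(i, j) for i in corr.index for j in corr.columns
                 if i < j and corr.loc[i, j] > 0.999]
        raise ReportError(f"collinear covariates: {pairs}")
    res = sm.OLS(b["delta_auc"].astype(float), Xd).fit()
    out = pd.DataFrame({"coef": res.params, "t": res.tvalues, "p": res.pvalues})
    out.index.name = "regressor"
    return out.reset_index()


# ---------------------------------------------------------------------------
# Pupil cohort analysis
# ---------------------------------------------------------------------------

def _subject_fitted_params(bias_row: pd.Series, variant: str,
                           win_side: str) -> _val.WeightingParams:
    arms_valence = {"win": (bias_row["delta_win"], bias_row["gamma_win"]),
                    "loss": (bias_row["delta_loss"], bias_row["gamma_loss"])}
    if variant == "study2_valence":
        return _val.WeightingParams(arms=arms_valence, beta=bias_row["beta"],
                                    variant=variant)
    loss_side = "right" if win_side == "left" else "left"
    return _val.WeightingParams(
        arms={win_side: arms_valence["win"], loss_side: arms_valence["loss"]},
        beta=bias_row["beta"], variant="study1_sided")


def analyze_pupil_cohort(datasets: list[_synth.SubjectDataset],
                         bias_table: pd.DataFrame,
                         pre_window: tuple[float, float] = (0.0, 1.5),
                         min_epochs: int = 10) -> dict:
    """Full model-based pupil analysis of a cohort.

    Per subject: preprocess the session, epoch stimulus- and choice-locked,
    run the trial-wise GLM on the pre-choice window with model-derived
    regressors, bin the outcome window, and compute the sustained-dilation
    bias index.  Cohort level: one-sample t time-course on the EV betas,
    valence x timebin rmANOVA per probability level, and the correlation of
    the pupil index with the behavioural bias index.
    """
    ev_betas, cell_rows, auc_rows = [], [], []
    times = None
    bias_by_subject = bias_table.set_index("subject_id")
    for ds in datasets:
        if ds.pupil_samples is None:
            continue
        row = bias_by_subject.loc[ds.subject_id]
        session = _pupil.PupilSession.from_tables(ds.pupil_samples,
                                                  ds.pupil_events)
        session = _pupil.preprocess(session)
        pre = _pupil.extract_epochs(session, lock="stim", window=pre_window)
        post = _pupil.extract_epochs(session, lock="choice", window=(0.0, 4.0))

        trials = (ds.preference_trials[ds.preference_trials["day"] == 1]
                  .reset_index(drop=True))
        params = _subject_fitted_params(row, row["variant"],
                                        ds.design.win_side(1))
        wl, wr = _val._weights_for(trials, params)
        chose_left = trials["choice"].to_numpy() == "left"
        ev_chosen = np.where(chose_left, wl, wr)
        px = {sid: s.black_pixels for sid, s in ds.design.stimuli.items()}
        regressors = pd.DataFrame({
            "ev_chosen": ev_chosen,
            "abs_ev_diff": np.abs(wl - wr),
            "black_pixels_left": trials["left_stim"].map(px).astype(float),
            "black_pixels_right": trials["right_stim"].map(px).astype(float),
        })
        try:
            betas = _pupil.first_level_glm(pre, regressors)
        except _pupil.PupilError:
            continue  # subject-level pupil dropout
        ev_betas.append(betas["ev_chosen"].to_numpy())
        times = betas["time_s"].to_numpy()

        cond = np.where(chose_left, trials["left_condition"],
                        trials["right_condition"])
        prob = np.where(chose_left, trials["left_prob"], trials["right_prob"])
        valence = pd.Series(cond).map(_synth._VALENCE_OF_CONDITION).to_numpy()
        level = np.where(prob > 0.5, "high", "low")
        bins = {}
        for i, ep in enumerate(post):
            if not ep.included:
                continue
            bins.setdefault((valence[i], level[i]), []).append(
                _pupil.bin_outcome_epoch(ep))
        cell_means = {k: np.mean(v, axis=0) for k, v in bins.items()}
        needed = {(v, l) for v in ("win", "loss", "neutral")
                  for l in ("high", "low")}
        if needed.issubset(cell_means):
            for (v, l), m in cell_means.items():
                if v == "baseline":
                    continue
                for b, val in enumerate(m):
                    cell_rows.append({"subject": ds.subject_id, "valence": v,
                                      "level": l, "bin": b + 1, "pupil": val})
            auc_rows.append({
                "subject_id": ds.subject_id,
                "pupil_auc": _pupil.pupil_auc_index(cell_means),
                "delta_auc": row["delta_auc"],
            })

    out = {"n_subjects": len(ev_betas)}
    if len(ev_betas) >= 3:
        out["ev_beta_second_level"] = _pupil.second_level_test(
            np.vstack(ev_betas), times)
    cells = pd.DataFrame(cell_rows)
    out["cell_means"] = cells
    out["rm_anova"] = {}
    for lvl in ("low", "high"):
        sub = cells[cells["level"] == lvl]
        if len(sub):
            out["rm_anova"][lvl] = _pupil.valence_by_time_anova(sub)
    auc_df = pd.DataFrame(auc_rows)
    out["pupil_auc_table"] = auc_df
    if len(auc_df) >= 3:
        out["behavior_pupil_correlation"] = pearson_r(
            auc_df["delta_auc"], auc_df["pupil_auc"])
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "study": "study2",
    "n_subjects": 8,
    "seed": 0,
    "with_pupil": False,
    "n_restarts": 10,
    "n_preference_trials": None,  # None = canonical
    "analyses": {"learning": True, "preference": True, "mood": True,
                 "pupil": False},
}


def config_hash(config: dict) -> str:
    text = json.dumps(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Simulate (or load) a cohort, run every enabled analysis stage, and
    write tagged delimited-text tables plus a machine-readable manifest."""
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["analyses"] = {**DEFAULT_CONFIG["analyses"],
                       **config.get("analyses", {})}
    h = config_hash(cfg)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": cfg, "config_hash": h, "stages": {}}

    design = build_canonical_design(cfg["study"])
    if cfg["n_preference_trials"]:
        design.preference_spec = dataclasses.replace(
            design.preference_spec, n_trials=int(cfg["n_preference_trials"]))
    datasets = _synth.simulate_population(
        design, cfg["n_subjects"], seed=cfg["seed"],
        with_pupil=cfg["with_pupil"])
    _synth.write_cohort(datasets, os.path.join(out_dir, "data"))
    manifest["stages"]["simulate"] = {
        "n_subjects": len(datasets),
        "n_preference_trials": int(sum(len(d.preference_trials)
                                       for d in datasets)),
    }

    def write(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df["config_hash"] = h
        df.to_csv(os.path.join(out_dir, name), sep="\t", index=False)

    summary_lines = [f"config_hash: {h}", f"study: {cfg['study']}",
                     f"n_subjects: {cfg['n_subjects']}"]

    if cfg["analyses"]["learning"]:
        acc = pd.concat([
            _learning_summary(ds) for ds in datasets], ignore_index=True)
        write(acc, "learning_accuracy.tsv")
        manifest["stages"]["learning"] = {"rows": len(acc)}
        summary_lines.append(
            f"mean P(correct) final block: "
            f"{acc.groupby('subject_id')['p_correct'].mean().mean():.3f}")

    if cfg["analyses"]["mood"]:
        mood = pd.concat([ds.mood_ratings for ds in datasets],
                         ignore_index=True)
        mood_res = mood_manipulation_check(mood)
        with open(os.path.join(out_dir, "mood_check.json"), "w") as fh:
            json.dump({"config_hash": h, "results": mood_res}, fh, indent=2)
        manifest["stages"]["mood"] = {k: v["p"] for k, v in mood_res.items()}

    bias_table = None
    if cfg["analyses"]["preference"]:
        bias_table = fit_cohort_preference(datasets,
                                           n_restarts=cfg["n_restarts"],
                                           seed=cfg["seed"])
        write(bias_table, "bias_table.tsv")
        group = bias_group_tests(bias_table)
        with open(os.path.join(out_dir, "group_tests.json"), "w") as fh:
            json.dump({"config_hash": h, "results": group}, fh, indent=2)
        manifest["stages"]["preference"] = {
            "rows": len(bias_table),
            "mean_delta_auc": float(bias_table["delta_auc"].mean()),
        }
        summary_lines.append(
            f"mean delta AuC: {bias_table['delta_auc'].mean():+.4f} "
            f"(one-sample t p = {group['delta_auc']['p']:.4f})")

    if cfg["analyses"]["pupil"] and cfg["with_pupil"]:
        if bias_table is None:
            raise ReportError("pupil analysis requires the preference stage")
        pup = analyze_pupil_cohort(datasets, bias_table)
        write(pup["pupil_auc_table"], "pupil_auc.tsv")
        manifest["stages"]["pupil"] = {"n_subjects": pup["n_subjects"]}

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write("\n".join(summary_lines) + "\n")
    return manifest


def _learning_summary(ds: _synth.SubjectDataset) -> pd.DataFrame:
    from .learning import accuracy_summary
    acc = accuracy_summary(ds.learning_trials)
    acc.insert(0, "subject_id", ds.subject_id)
    return acc
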