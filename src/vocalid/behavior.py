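"""The behavioral statistical analyses of the voice choice experiment.

Wraps the mixed-model engine into the concrete models fitted to the trial
table: intercept-only choice models per phase (with odds ratios), design-
parameter effects on choice with backwards elimination, the relation between
choice and the two continuous behavioral indices, the looking-time model
with acoustic-distance covariates and their gender interactions (plus simple
slopes), a signed-rank phase comparison, and the speaker-voice comparison
(owner vs control voices) by F and likelihood-ratio tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mixed import (
    BinomialMixedModel,
    LinearMixedModel,
    MixedModelResult,
    backwards_eliminate,
    wilcoxon_signed_rank,
)
from .speaker_space import PAPER_MARKERS

__all__ = [
    "build_design_matrix",
    "choice_intercept_model",
    "design_effects_model",
    "behavior_relation_model",
    "looking_time_model",
    "phase_comparison",
    "speaker_voice_comparison",
]

STAY_P = 0.1  # "tendency level" retention threshold for backwards elimination


def build_design_matrix(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Intercept + named columns; ``a:b`` builds the product of two columns."""
    out = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            out[t] = df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)
        else:
            out[t] = df[t].to_numpy(dtype=float)
    return out


def _drop_aliased(df: pd.DataFrame, terms) -> list:
    """Keep only terms whose design column adds rank (greedy, in order)."""
    X = build_design_matrix(df, terms)
    kept = []
    M = X[["Intercept"]].to_numpy()
    for t in terms:
        cand = np.column_stack([M, X[t].to_numpy()])
        if np.linalg.matrix_rank(cand) > M.shape[1]:
            kept.append(t)
            M = cand
    dropped = [t for t in terms if t not in kept]
    if dropped:
        warnings.warn(f"aliased fixed terms dropped: {dropped}")
    return kept


def _prep_choice_columns(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    df["side_left"] = (df["owner_side"] == "left").astype(float)
    df["last_owner"] = (df["last_speaker"] == "owner").astype(float)
    df["trial_c"] = df["trial_index"] - df["trial_index"].mean()
    return df


def choice_intercept_model(
    trials: pd.DataFrame, phase: str = "test"
) -> MixedModelResult:
    """Intercept-only binomial mixed model of choosing success for one phase.

    Random intercept for dog (speaker identity explains no variance in
    intercept-only models and is omitted).
    """
    df = trials[trials["phase"] == phase]
    if df.empty:
        raise ValueError(f"no trials in phase {phase!r}")
    X = build_design_matrix(df, [])
    return BinomialMixedModel(X, df["choice"], {"dog": df["dog_id"]}).fit()


def design_effects_model(
    trials: pd.DataFrame, stay_p: float = STAY_P
) -> tuple[MixedModelResult, list]:
    """Design-parameter effects on choosing success, with backwards elimination.

    Initial fixed terms: trial number, owner-speaks-last, owner's hiding
    side, speaker gender match.  Random intercepts: dog and control speaker
    (a factor whose variance collapses to zero is dropped).
    """
    df = _prep_choice_columns(trials[trials["phase"] == "test"])
    groups = {"dog": df["dog_id"], "speaker": df["control_speaker_id"]}

    def build(terms):
        X = build_design_matrix(df, terms)
        return BinomialMixedModel(X, df["choice"], groups).fit()

    return backwards_eliminate(
        build, ["trial_c", "last_owner", "side_left", "gender_different"], stay_p
    )


def behavior_relation_model(
    trials: pd.DataFrame, stay_p: float = STAY_P
) -> tuple[MixedModelResult, list]:
    """Choosing success as a function of looking time and choosing latency."""
    df = trials[trials["phase"] == "test"]
    groups = {"dog": df["dog_id"], "speaker": df["control_speaker_id"]}

    def build(terms):
        X = build_design_matrix(df, terms)
        return BinomialMixedModel(X, df["choice"], groups).fit()

    return backwards_eliminate(build, ["looking_time", "latency_s"], stay_p)


def looking_time_model(
    trials: pd.DataFrame,
    markers=PAPER_MARKERS,
    stay_p: float = STAY_P,
    eliminate: bool = True,
    include_speaker: bool = False,
) -> dict:
    """Gaussian mixed model of looking time on z-scored acoustic distances.

    The initial model holds the six marker distances, the speaker-gender
    difference indicator, and all distance-by-gender two-way interactions;
    backwards elimination then prunes it.  For every retained
    distance-by-gender interaction the per-gender simple slopes are
    recombined from the final coefficients and covariances (Satterthwaite
    df).  Trials with missing distances are dropped (count reported).
    """
    df = trials[trials["phase"] == "test"].copy()
    dist_cols = [f"dist_{m}_z" for m in markers]
    missing = [c for c in dist_cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing distance columns: {missing}")
    n0 = len(df)
    df = df.dropna(subset=dist_cols + ["looking_time"])
    n_dropped = n0 - len(df)
    if n_dropped:
        warnings.warn(f"{n_dropped} trials dropped for missing distances")

    groups = {"dog": df["dog_id"]}
    if include_speaker:
        groups["speaker"] = df["control_speaker_id"]

    main_terms = ["gender_different"] + dist_cols
    inter_terms = [f"{c}:gender_different" for c in dist_cols]
    # few distinct control speakers can alias distance columns; drop aliased
    # terms (as R's fixed-effect pivoting would) before elimination
    all_terms = _drop_aliased(df, main_terms + inter_terms)
    main_terms = [t for t in main_terms if t in all_terms]
    inter_terms = [t for t in inter_terms if t in all_terms]
    last_model = {}

    def build(terms):
        X = build_design_matrix(df, terms)
        model = LinearMixedModel(X, df["looking_time"], groups)
        res = model.fit(drop_zero_variance=True)
        last_model["model"] = model
        last_model["terms"] = list(terms)
        return res

    if eliminate:
        fit, elim_log = backwards_eliminate(build, main_terms + inter_terms, stay_p)
    else:
        fit, elim_log = build(main_terms + inter_terms), []

    model = last_model["model"]
    slopes = {}
    for m in markers:
        dterm, iterm = f"dist_{m}_z", f"dist_{m}_z:gender_different"
        if dterm in fit.params.index and iterm in fit.params.index:
            slopes[m] = {
                "same_gender": model.contrast(fit, {dterm: 1.0}),
                "different_gender": model.contrast(fit, {dterm: 1.0, iterm: 1.0}),
            }
    return {
        "fit": fit,
        "elimination_log": elim_log,
        "simple_slopes": slopes,
        "n_dropped_missing": n_dropped,
    }


def phase_comparison(trials: pd.DataFrame) -> dict:
    """Signed-rank comparison of per-dog choosing success, test vs olfaction.

    Only dogs that completed both phases contribute; per-dog success is the
    proportion of correct choices in each phase.
    """
    per = (
        trials.groupby(["dog_id", "phase"])["choice"].mean().unstack("phase")
    )
    per = per.dropna()
    if per.empty:
        raise ValueError("no dogs with both phases")
    z, p = wilcoxon_signed_rank(per["test"].to_numpy(), per["olfaction"].to_numpy())
    return {"Z": z, "p": p, "n_dogs": int(len(per))}


def _type_design(df: pd.DataFrame, with_type: bool, with_gender: bool, interaction: bool):
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    types = sorted(df["speaker_type"].unique())
    genders = sorted(df["gender"].unique())
    tcols, icols = [], []
    if with_type:
        for t in types[1:]:
            col = f"type_{t}"
            X[col] = (df["speaker_type"] == t).astype(float)
            tcols.append(col)
    if with_gender and len(genders) > 1:
        X["gender_male"] = (df["gender"] == "male").astype(float)
    if interaction and with_type and with_gender and len(genders) > 1:
        for t in types[1:]:
            col = f"type_{t}:gender_male"
            X[col] = X[f"type_{t}"] * X["gender_male"]
            icols.append(col)
    return X, tcols, icols


def speaker_voice_comparison(speakers: pd.DataFrame) -> dict:
    """Do owner voices differ from control voices on f0 mean or jitter?

    ``speakers`` has one row per speaker with columns speaker_type (e.g.
    owner_included / owner_excluded / control), gender, f0_mean, ppj.  The
    f0-mean comparison is a Gaussian model tested with an exact F test for
    speaker type (controlling gender); jitter uses a Gaussian model with log
    link and a likelihood-ratio chi-square.  The type-by-gender interaction
    is likelihood-ratio tested on the f0 model.
    """
    types = speakers["speaker_type"].unique()
    if len(types) < 2:
        raise ValueError("need >= 2 speaker types")
    genders = speakers["gender"].unique()
    if len(genders) < 2:
        warnings.warn("single-gender input: gender term dropped")
    df_t = len(types) - 1

    # f0 mean: OLS, exact F test for the type dummies
    Xf, tcols, _ = _type_design(speakers, True, True, False)
    Xr = Xf.drop(columns=tcols)
    y = speakers["f0_mean"].to_numpy(dtype=float)
    full = sm.OLS(y, Xf).fit()
    red = sm.OLS(y, Xr).fit()
    dfd = full.df_resid
    F = ((red.ssr - full.ssr) / df_t) / (full.ssr / dfd)
    p_f = float(stats.f.sf(F, df_t, dfd))

    # type x gender interaction: LR test on the f0 model
    inter = None
    if len(genders) > 1:
        Xi, _, icols = _type_design(speakers, True, True, True)
        if icols:
            fi = sm.OLS(y, Xi).fit()
            lr_i = 2 * (fi.llf - full.llf)
            inter = {
                "chi2": float(max(lr_i, 0.0)),
                "df": len(icols),
                "p": float(stats.chi2.sf(max(lr_i, 0.0), len(icols))),
            }

    # jitter: Gaussian with log link, LR chi-square for type
    yj = speakers["ppj"].to_numpy(dtype=float)
    fam = sm.families.Gaussian(link=sm.families.links.Log())
    gj_full = sm.GLM(yj, Xf, family=fam).fit()
    gj_red = sm.GLM(yj, Xr, family=fam).fit(scale=gj_full.scale)
    lr = 2 * (gj_full.llf - gj_red.llf)
    lr = float(max(lr, 0.0))

    return {
        "f0_mean": {"F": float(F), "df": (df_t, float(dfd)), "p": p_f},
        "ppj": {"chi2": lr, "df": df_t, "p": float(stats.chi2.sf(lr, df_t))},
        "interaction_f0": inter,
    }
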