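"""Two-way voice choice task simulator.

Generates trial skeletons under the experiment's pseudorandomization rules
(balanced hiding sides and last speakers per dog, no more than three
consecutive trials with the owner on the same side, per-trial control
speakers drawn without replacement) and simulates behavioral outcomes from a
configurable generative effect structure, so every downstream model can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["DesignConfig", "EffectConfig", "generate_design", "simulate_outcomes"]


@dataclass(frozen=True)
class DesignConfig:
    """Study design counts and pseudorandomization constraints."""

    n_dogs: int = 28
    n_test_trials: int = 10
    n_olfaction_trials: int = 2
    n_olfaction_dogs: int = 23
    n_controls: int = 14
    max_consecutive_same_side: int = 3
    owner_gender: str = "female"

    def validate(self) -> None:
        for name in ("n_dogs", "n_test_trials", "n_olfaction_trials", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_olfaction_dogs > self.n_dogs:
            raise ValueError("n_olfaction_dogs cannot exceed n_dogs")
        if self.n_test_trials > self.n_controls:
            raise ValueError("need at least one distinct control per test trial")
        if self.max_consecutive_same_side < 1:
            raise ValueError("max_consecutive_same_side must be >= 1")


@dataclass(frozen=True)
class EffectConfig:
    """Generative truth for behavioral outcomes.

    Choice model (log-odds scale): intercept, owner-on-left and
    owner-speaks-last effects, and a per-dog random intercept SD.  Looking
    time (percent of the stimulus window toward the owner's side): baseline,
    gender-difference shift, slopes on z-scored f0-mean and jitter distances
    and the f0-by-gender interaction (coded so the f0 slope applies to
    same-gender trials and the interaction adds for different-gender trials),
    plus dog-level and residual noise.  Latency is weakly negatively coupled
    to looking time and carries no true covariate effect.
    """

    choice_intercept: float = 1.601
    side_left: float = 0.688
    last_speaker_owner: float = 0.630
    trial_effect: float = 0.0
    gender_diff_choice: float = 0.0
    sigma_dog: float = 1.0
    looking_intercept: float = 55.0
    gender_diff_looking: float = -1.107
    f0_dist_slope: float = 5.613
    ppj_dist_slope: float = 4.010
    f0_gender_interaction: float = -8.956
    other_dist_slopes: dict = field(default_factory=dict)
    sigma_dog_looking: float = 5.0
    resid_sd_looking: float = 25.0
    latency_base_s: float = 6.0
    latency_looking_slope: float = -0.02
    latency_sd: float = 1.5


def _balanced_sequence(n: int, rng: np.random.Generator, max_run: int | None) -> np.ndarray:
    """Random 0/1 sequence with equal counts (odd n: extra assigned randomly)
    and, optionally, no run longer than max_run."""
    base = np.array([0] * (n // 2) + [1] * (n - n // 2))
    if n % 2:
        rng.shuffle(base)
    for _ in range(2000):
        seq = rng.permutation(base)
        if max_run is None:
            return seq
        run, longest, prev = 0, 0, None
        for v in seq:
            run = run + 1 if v == prev else 1
            prev = v
            longest = max(longest, run)
        if longest <= max_run:
            return seq
    raise RuntimeError(f"could not satisfy run constraint <= {max_run} for n={n}")


def generate_design(
    cfg: DesignConfig,
    seed: int,
    control_genders: list | None = None,
) -> pd.DataFrame:
    """Trial skeletons for all dogs: test phase plus olfaction-control phase.

    ``control_genders`` gives the gender of each control speaker (default:
    alternating female/male, i.e. a 50% male control set).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    if control_genders is None:
        control_genders = (["female", "male"] * cfg.n_controls)[: cfg.n_controls]
    if len(control_genders) != cfg.n_controls:
        raise ValueError("control_genders length must equal n_controls")
    control_ids = [f"control_{i + 1:02d}" for i in range(cfg.n_controls)]

    rows = []
    for d in range(cfg.n_dogs):
        dog = f"dog_{d + 1:02d}"
        sides = _balanced_sequence(
            cfg.n_test_trials, rng, cfg.max_consecutive_same_side
        )
        lasts = _balanced_sequence(cfg.n_test_trials, rng, None)
        ctrl_idx = rng.choice(cfg.n_controls, size=cfg.n_test_trials, replace=False)
        for t in range(cfg.n_test_trials):
            ci = int(ctrl_idx[t])
            rows.append(
                {
                    "dog_id": dog,
                    "phase": "test",
                    "trial_index": t + 1,
                    "owner_side": "left" if sides[t] else "right",
                    "last_speaker": "owner" if lasts[t] else "control",
                    "control_speaker_id": control_ids[ci],
                    "owner_gender": cfg.owner_gender,
                    "control_gender": control_genders[ci],
                }
            )
        if d < cfg.n_olfaction_dogs:
            o_sides = _balanced_sequence(cfg.n_olfaction_trials, rng, None)
            o_lasts = _balanced_sequence(cfg.n_olfaction_trials, rng, None)
            o_ctrl = rng.choice(
                cfg.n_controls, size=cfg.n_olfaction_trials, replace=False
            )
            for t in range(cfg.n_olfaction_trials):
                ci = int(o_ctrl[t])
                rows.append(
                    {
                        "dog_id": dog,
                        "phase": "olfaction",
                        "trial_index": t + 1,
                        "owner_side": "left" if o_sides[t] else "right",
                        "last_speaker": "owner" if o_lasts[t] else "control",
                        "control_speaker_id": control_ids[ci],
                        "owner_gender": cfg.owner_gender,
                        "control_gender": control_genders[ci],
                    }
                )
    df = pd.DataFrame(rows)
    df["gender_different"] = (df["owner_gender"] != df["control_gender"]).astype(int)
    return df


def simulate_outcomes(
    skeletons: pd.DataFrame,
    eff: EffectConfig,
    seed: int,
    distances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach simulated choice, looking time and latency to trial skeletons.

    ``distances``, if given, maps ``control_speaker_id`` to z-scored marker
    distance columns (``dist_<marker>_z``); absent distances are treated as 0
    (their generative slopes then contribute nothing).  Olfaction trials use
    the same choice model as test trials; scoring follows the voice.
    """
    rng = np.random.default_rng(seed)
    df = skeletons.copy().reset_index(drop=True)
    if distances is not None:
        zcols = [c for c in distances.columns if c.startswith("dist_")]
        key = distances.drop_duplicates("control_speaker_id")[
            ["control_speaker_id"] + zcols
        ]
        df = df.merge(key, on="control_speaker_id", how="left")

    dogs = df["dog_id"].unique()
    u_choice = dict(zip(dogs, rng.normal(0.0, eff.sigma_dog, len(dogs))))
    u_look = dict(zip(dogs, rng.normal(0.0, eff.sigma_dog_looking, len(dogs))))

    def zcol(name):
        col = f"dist_{name}_z"
        return df[col].fillna(0.0).to_numpy() if col in df else np.zeros(len(df))

    f0z, ppjz = zcol("f0_mean"), zcol("ppj")
    gdiff = df["gender_different"].to_numpy()
    trial_c = df["trial_index"].to_numpy() - df["trial_index"].mean()

    eta = (
        eff.choice_intercept
        + eff.side_left * (df["owner_side"] == "left").to_numpy()
        + eff.last_speaker_owner * (df["last_speaker"] == "owner").to_numpy()
        + eff.trial_effect * trial_c
        + eff.gender_diff_choice * gdiff
        + np.array([u_choice[d] for d in df["dog_id"]])
    )
    df["choice"] = rng.binomial(1, expit(eta))

    look = (
        eff.looking_intercept
        + eff.gender_diff_looking * gdiff
        + eff.f0_dist_slope * f0z
        + eff.ppj_dist_slope * ppjz
        + eff.f0_gender_interaction * f0z * gdiff
        + np.array([u_look[d] for d in df["dog_id"]])
        + rng.normal(0.0, eff.resid_sd_looking, len(df))
    )
    for name, slope in eff.other_dist_slopes.items():
        look = look + slope * zcol(name)
    df["looking_time"] = np.clip(look, 0.0, 100.0)

    lat = (
        eff.latency_base_s
        + eff.latency_looking_slope * df["looking_time"].to_numpy()
        + rng.normal(0.0, eff.latency_sd, len(df))
    )
    df["latency_s"] = np.clip(lat, 0.3, 30.0)
    return df
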