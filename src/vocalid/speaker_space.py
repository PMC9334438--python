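"""Speaker identity space: collinearity filtering, LDA, markers, distances.

The discriminant analysis treats speakers as groups, solves the generalized
eigenproblem of between- vs pooled within-group covariance, and reports
standardized coefficients ("loadings": raw coefficients times within-group
feature SDs).  Features with |loading| above a threshold on at least one
discriminant function are the identity markers; per-trial acoustic distance
is the absolute difference between the two speakers' values on a marker.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

__all__ = [
    "collinearity_filter",
    "CollinearityFilter",
    "SpeakerLDA",
    "classification_success",
    "select_markers",
    "acoustic_distance",
    "distance_table",
    "PAPER_MARKERS",
]

log = logging.getLogger(__name__)

#: the six identity markers carried into the behavioral analyses
PAPER_MARKERS = ("f0_mean", "f0_sd", "dF", "HNR", "ent", "ppj")

LOADING_THRESHOLD = 1.3


def _canonical_rank(name: str) -> int:
    try:
        return FEATURE_NAMES.index(name)
    except ValueError:
        return len(FEATURE_NAMES)


def collinearity_filter(
    table: pd.DataFrame, features: list | None = None, r_max: float = 0.8
) -> list:
    """Greedily drop features until no retained pair has |Pearson r| >= r_max.

    Within the worst pair the feature with the larger mean absolute
    correlation to all other retained features is dropped (ties broken
    against the later feature in canonical battery order).
    """
    if not 0 < r_max <= 1:
        raise ValueError(f"r_max must lie in (0, 1], got {r_max}")
    if features is None:
        features = [c for c in table.columns if c in FEATURE_NAMES]
    sub = table[list(features)].dropna()
    if sub.empty:
        raise ValueError("no complete-case rows for correlation filtering")
    corr = sub.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)

    retained = list(range(len(features)))
    while True:
        c = corr[np.ix_(retained, retained)]
        if c.size == 0 or np.max(c) < r_max:
            break
        i_, j_ = np.unravel_index(np.argmax(c), c.shape)
        i, j = retained[i_], retained[j_]

        def badness(k):
            others = [m for m in retained if m != k]
            return float(np.mean(corr[k, others])) if others else 0.0

        bi, bj = badness(i), badness(j)
        if np.isclose(bi, bj):
            drop = max(i, j, key=lambda k: _canonical_rank(features[k]))
        else:
            drop = i if bi > bj else j
        retained.remove(drop)
    return [features[k] for k in retained]


class CollinearityFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`collinearity_filter`."""

    def __init__(self, r_max: float = 0.8, features: list | None = None):
        self.r_max = r_max
        self.features = features

    def fit(self, X: pd.DataFrame, y=None):
        self.retained_ = collinearity_filter(X, features=self.features, r_max=self.r_max)
        self.dropped_ = [
            f
            for f in (self.features or [c for c in X.columns if c in FEATURE_NAMES])
            if f not in self.retained_
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return X[self.retained_]


class SpeakerLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with speakers as groups, equal priors.

    Solves eigh(S_between, S_within_pooled); discriminant coefficients are
    scaled to unit pooled within-group variance of the scores (so the
    between/within ratio of each function is its eigenvalue), and
    ``loadings_`` are the coefficients standardized by within-group SDs.

    Parameters
    ----------
    ridge : float
        Relative ridge added to a (near-)singular within-group covariance.
    selection_threshold : float
        |loading| above which a feature counts as an identity marker.
    """

    def __init__(self, ridge: float = 1e-8, selection_threshold: float = LOADING_THRESHOLD):
        self.ridge = ridge
        self.selection_threshold = selection_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            self.feature_names_in_ = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        if np.any(~np.isfinite(X)):
            raise ValueError("LDA requires complete feature vectors (drop NaN rows first)")
        classes, codes = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 groups")
        counts = np.bincount(codes)
        if np.any(counts < 2):
            raise ValueError("need >= 2 sentences per speaker for within-group covariance")
        n, p = X.shape
        g = len(classes)

        means = np.vstack([X[codes == k].mean(axis=0) for k in range(g)])
        grand = X.mean(axis=0)
        sw = np.zeros((p, p))
        for k in range(g):
            d = X[codes == k] - means[k]
            sw += d.T @ d
        sw /= n - g
        dm = means - grand
        sb = (dm * counts[:, None]).T @ dm / (g - 1)

        # solve in within-SD-standardized space: numerically scale-invariant
        sd = np.sqrt(np.diag(sw))
        sd = np.where(sd > 0, sd, 1.0)
        sw_s = sw / np.outer(sd, sd)
        sb_s = sb / np.outer(sd, sd)
        swr = sw_s + self.ridge * np.eye(p)
        try:
            evals, evecs = linalg.eigh(sb_s, swr)
        except linalg.LinAlgError:
            log.warning("within-group covariance singular; ridge-regularized")
            evals, evecs = linalg.eigh(sb_s, sw_s + 1e-4 * np.eye(p))

        k = min(g - 1, p)
        order = np.argsort(evals)[::-1][:k]
        L = evecs[:, order]  # standardized coefficients ("loadings")
        # sign convention on the scale-invariant loadings: largest entry positive
        for j in range(L.shape[1]):
            i = np.argmax(np.abs(L[:, j]))
            if L[i, j] < 0:
                L[:, j] = -L[:, j]

        self.classes_ = classes
        self.eigenvalues_ = evals[order]
        self.scalings_ = L / sd[:, None]  # raw-feature-scale coefficients
        self.means_ = means
        self.within_sd_ = np.sqrt(np.diag(sw))
        self.loadings_ = L
        self.class_scores_ = means @ self.scalings_
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return X @ self.scalings_

    def predict(self, X):
        z = self.transform(X)
        d = ((z[:, None, :] - self.class_scores_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d, axis=1)]

    def loadings_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        cols = [f"LD{j + 1}" for j in range(self.loadings_.shape[1])]
        return pd.DataFrame(self.loadings_, index=self.feature_names_in_, columns=cols)


def select_markers(model: SpeakerLDA, threshold: float | None = None) -> list:
    """Features with |loading| > threshold on >= 1 discriminant function,
    ordered by their maximum absolute loading (descending)."""
    check_is_fitted(model, "loadings_")
    thr = model.selection_threshold if threshold is None else threshold
    maxload = np.max(np.abs(model.loadings_), axis=1)
    sel = [
        (model.feature_names_in_[i], maxload[i])
        for i in range(len(maxload))
        if maxload[i] > thr
    ]
    if not sel:
        warnings.warn(f"no feature exceeds |loading| > {thr}")
    sel.sort(key=lambda t: -t[1])
    return [name for name, _ in sel]


def classification_success(
    X, y, mode: str = "loo", **lda_kwargs
) -> float:
    """Percent of sentences assigned to the true speaker.

    ``loo`` refits the LDA without the held-out sentence; ``resubstitution``
    scores the training data.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mode == "resubstitution":
        m = SpeakerLDA(**lda_kwargs).fit(X, y)
        return 100.0 * float(np.mean(m.predict(X) == y))
    if mode == "loo":
        hits = 0
        n = len(y)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = SpeakerLDA(**lda_kwargs).fit(X[mask], y[mask])
            hits += int(m.predict(X[i : i + 1])[0] == y[i])
        return 100.0 * hits / n
    raise ValueError(f"unknown mode {mode!r}; use 'loo' or 'resubstitution'")


def acoustic_distance(owner, control, markers) -> dict:
    """Per-marker |owner - control| distance (symmetric, translation-invariant)."""
    out = {}
    for m in markers:
        a, b = float(owner[m]), float(control[m])
        out[m] = abs(a - b)
    return out


def distance_table(
    speaker_values: pd.DataFrame,
    trials: pd.DataFrame,
    markers=PAPER_MARKERS,
    owner_id: str = "owner",
) -> pd.DataFrame:
    """Raw and z-scored per-trial acoustic distances.

    ``speaker_values`` holds one row per speaker_id (speaker-level feature
    values, e.g. means over sentences); ``trials`` must carry a
    ``control_speaker_id`` column.  Z-scores are taken across the full trial
    table per marker.  Trials whose speakers miss a marker value are flagged
    via ``distance_missing``.
    """
    sv = speaker_values.set_index("speaker_id") if "speaker_id" in speaker_values else speaker_values
    owner = sv.loc[owner_id]
    out = trials.copy()
    missing = np.zeros(len(out), dtype=bool)
    for m in markers:
        vals = []
        for ctrl in out["control_speaker_id"]:
            a, b = owner[m], sv.loc[ctrl, m]
            vals.append(abs(float(a) - float(b)) if np.isfinite(a) and np.isfinite(b) else np.nan)
        col = np.asarray(vals)
        out[f"dist_{m}"] = col
        mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
        out[f"dist_{m}_z"] = (col - mu) / sd if sd > 0 else col * 0.0
        missing |= ~np.isfinite(col)
    out["distance_missing"] = missing
    return out
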