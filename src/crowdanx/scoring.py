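"""Individual anxiety scoring: the profile (user) factor and the topical factor.

A member's initial anxiety is a convex mix of two normalized components:

    a0 = lam * p + (1 - lam) * m,      0 <= lam <= 1

where ``p`` is predicted from the member's profile by a scorer trained on
linked SAS questionnaire records, and ``m`` measures how close the member's
message keywords are to anxiety anchor words in embedding space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .embeddings import WordEmbedding
from .lexicon import AnchorLexicon
from .text import extract_keywords

__all__ = [
    "SAS_MIN", "SAS_MAX", "SAS_BANDS", "band_sas_score", "normalize_sas",
    "CATEGORICAL_FEATURES", "NUMERIC_FEATURES", "PROFILE_FEATURES",
    "ScorerSettings", "ProfileScorer", "train_profile_scorer",
    "cross_validate_scorer", "score_profile",
    "NoTopicalEvidence", "message_anchor_similarity", "topical_anxiety",
    "initial_anxiety",
]

SAS_MIN = 25.0
SAS_MAX = 100.0

#: SAS index bands, half-open except the last: no(25-49), slight(50-59),
#: medium(60-69), extreme(70-100).
SAS_BANDS = (
    ("no", 25.0, 50.0),
    ("slight", 50.0, 60.0),
    ("medium", 60.0, 70.0),
    ("extreme", 70.0, 100.0),
)

SAS_BAND_ORDER = {name: i for i, (name, _, _) in enumerate(SAS_BANDS)}

CATEGORICAL_FEATURES = ("gender", "occupation", "location")
NUMERIC_FEATURES = ("age", "education_level", "income_band")
PROFILE_FEATURES = CATEGORICAL_FEATURES + NUMERIC_FEATURES


def band_sas_score(score: float) -> str:
    """Map a SAS index score to its anxiety band."""
    if not SAS_MIN <= score <= SAS_MAX:
        raise ValueError(f"SAS score {score} outside valid range [{SAS_MIN}, {SAS_MAX}]")
    for name, lo, hi in SAS_BANDS:
        if lo <= score < hi:
            return name
    return SAS_BANDS[-1][0]  # score == SAS_MAX


def normalize_sas(score) -> np.ndarray | float:
    """Min-max normalize SAS-scale scores to [0,1] by the fixed scale bounds
    (25 -> 0, 100 -> 1)."""
    return (np.asarray(score, dtype=float) - SAS_MIN) / (SAS_MAX - SAS_MIN)


@dataclass(frozen=True)
class ScorerSettings:
    """Training settings for the reference profile scorer.

    The reference architecture is a linear base (exact on the one-hot +
    numeric encoding) with a single-hidden-layer feed-forward residual
    stage.  When the base already interpolates the targets the residual
    stage is skipped, so noise-free targets are recovered exactly.
    """

    hidden_units: int = 16
    alpha: float = 10.0          # residual-stage L2 penalty; the stage only
                                 # needs to pick up real nonlinear structure,
                                 # so it is regularized hard against noise
    max_iter: int = 2000
    seed: int = 0
    residual_tol: float = 1e-6   # skip residual stage below this residual SD


class ProfileScorer:
    """Profile -> SAS-scale anxiety score, clipped to [25, 100]."""

    def __init__(self, settings: ScorerSettings = ScorerSettings()):
        self.settings = settings
        self._pre = None
        self._linear = None
        self._residual = None

    def fit(self, profiles: pd.DataFrame, sas: pd.DataFrame) -> "ProfileScorer":
        X_df, y = _link_training_frame(profiles, sas)
        if len(np.unique([band_sas_score(v) for v in y])) < 2:
            raise ValueError("degenerate training target: all SAS records fall in one band")
        s = self.settings
        # drop="first" keeps the one-hot design full rank, so the linear
        # base interpolates additive categorical effects exactly even for
        # level combinations absent from the training folds
        self._pre = ColumnTransformer(
            [("cat", OneHotEncoder(drop="first", handle_unknown="ignore"),
              list(CATEGORICAL_FEATURES)),
             ("num", "passthrough", list(NUMERIC_FEATURES))]
        )
        X = self._transform(X_df, fit=True)
        self._linear = LinearRegression().fit(X, y)
        resid = y - self._linear.predict(X)
        if np.std(resid) > s.residual_tol:
            pipe = Pipeline([
                ("scale", StandardScaler()),
                ("mlp", MLPRegressor(hidden_layer_sizes=(s.hidden_units,),
                                     solver="lbfgs", alpha=s.alpha,
                                     max_iter=s.max_iter, tol=1e-7,
                                     random_state=s.seed)),
            ])
            with warnings.catch_warnings():
                # the L2-regularized residual stage need not reach machine
                # tolerance; the iteration cap is part of the settings
                warnings.simplefilter("ignore", ConvergenceWarning)
                self._residual = pipe.fit(X, resid)
        else:
            self._residual = None
        return self

    def _transform(self, X_df: pd.DataFrame, fit: bool = False) -> np.ndarray:
        pre = self._pre
        X = pre.fit_transform(X_df) if fit else pre.transform(X_df)
        if hasattr(X, "toarray"):
            X = X.toarray()
        return np.asarray(X, dtype=float)

    def predict(self, profiles: pd.DataFrame) -> np.ndarray:
        if self._linear is None:
            raise RuntimeError("scorer has not been trained")
        missing = [c for c in PROFILE_FEATURES if c not in profiles.columns]
        if missing:
            raise ValueError(f"profile table is missing required feature(s): {missing}")
        X = self._transform(profiles[list(PROFILE_FEATURES)])
        pred = self._linear.predict(X)
        if self._residual is not None:
            pred = pred + self._residual.predict(X)
        return np.clip(pred, SAS_MIN, SAS_MAX)


def _link_training_frame(profiles: pd.DataFrame, sas: pd.DataFrame):
    if len(sas) < 30:
        raise ValueError(f"need >= 30 linked SAS records, got {len(sas)}")
    missing = [c for c in PROFILE_FEATURES if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table is missing required feature(s): {missing}")
    prof = profiles.set_index("user_id")
    unlinked = [u for u in sas["user_id"] if u not in prof.index]
    if unlinked:
        raise ValueError(f"SAS records reference unknown user ids: {unlinked[:10]}")
    X_df = prof.loc[sas["user_id"], list(PROFILE_FEATURES)].reset_index(drop=True)
    y = sas["score"].to_numpy(dtype=float)
    bad = (y < SAS_MIN) | (y > SAS_MAX)
    if bad.any():
        raise ValueError(f"SAS scores outside [{SAS_MIN}, {SAS_MAX}]: "
                         f"{y[bad][:5].tolist()}")
    return X_df, y


def train_profile_scorer(profiles: pd.DataFrame, sas: pd.DataFrame,
                         settings: ScorerSettings = ScorerSettings()) -> ProfileScorer:
    """Train the reference profile scorer on linked profile/SAS records."""
    return ProfileScorer(settings).fit(profiles, sas)


def cross_validate_scorer(profiles: pd.DataFrame, sas: pd.DataFrame,
                          folds: int = 3, seed: int = 0,
                          settings: ScorerSettings | None = None):
    """K-fold cross-validation with pooled out-of-fold predictions.

    Out-of-fold SAS predictions are banded and compared with the banded
    true scores using the directional precision/recall of
    :func:`crowdanx.stats.precision_recall`.
    """
    from .stats import precision_recall  # local import: stats is downstream

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(sas):
        raise ValueError(f"folds={folds} exceeds the {len(sas)} available records")
    settings = settings or ScorerSettings(seed=seed)
    sas = sas.reset_index(drop=True)
    pred = np.empty(len(sas))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_ix, test_ix in kf.split(sas):
        scorer = ProfileScorer(settings).fit(profiles, sas.iloc[train_ix])
        prof = profiles.set_index("user_id")
        X_test = prof.loc[sas.iloc[test_ix]["user_id"]].reset_index()
        pred[test_ix] = scorer.predict(X_test)
    # round to 1e-6 SAS points before banding so float error cannot flip a
    # prediction sitting exactly on a band edge
    model_bands = [SAS_BAND_ORDER[band_sas_score(round(v, 6))] for v in pred]
    truth_bands = [SAS_BAND_ORDER[band_sas_score(v)] for v in sas["score"]]
    return precision_recall(model_bands, truth_bands)


def score_profile(scorer: ProfileScorer, profile: pd.DataFrame | pd.Series) -> np.ndarray | float:
    """Profile-factor score(s) p in [0,1]: SAS prediction min-max normalized
    by the fixed scale bounds."""
    if isinstance(profile, pd.Series):
        p = normalize_sas(scorer.predict(profile.to_frame().T))
        return float(p[0])
    return normalize_sas(scorer.predict(profile))


class NoTopicalEvidence(Exception):
    """Raised when a member has no messages; callers fall back to lam=1."""


def message_anchor_similarity(text: str, lexicon: AnchorLexicon,
                              embedding: WordEmbedding, k: int = 5) -> float:
    """Similarity of one message to the anchor lexicon.

    Max over (message keyword, anchor word) pairs of weighted cosine
    similarity, clamped to [0, 1].  Messages with no embeddable keywords
    score 0.
    """
    best = 0.0
    for kw in extract_keywords(text, k=k):
        if kw not in embedding:
            continue
        for anchor in lexicon.words:
            if anchor not in embedding:
                continue
            sim = embedding.cosine(kw, anchor) * lexicon.weight(anchor)
            if sim > best:
                best = sim
    return float(np.clip(best, 0.0, 1.0))


def topical_anxiety(texts, lexicon: AnchorLexicon, embedding: WordEmbedding,
                    k: int = 5) -> float:
    """Topical-factor score m in [0,1]: mean per-message anchor similarity.

    Higher similarity to the anchor words indicates higher topical anxiety.
    Raises :class:`NoTopicalEvidence` when the member has no messages.
    """
    texts = list(texts)
    if not texts:
        raise NoTopicalEvidence("member has no messages; fall back to lam=1")
    return float(np.mean([message_anchor_similarity(t, lexicon, embedding, k) for t in texts]))


def initial_anxiety(p: float, m: float, lam: float) -> float:
    """Initial individual anxiety a0 = lam*p + (1-lam)*m."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0,1], got {lam}")
    p, m = np.asarray(p, dtype=float), np.asarray(m, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((m < 0) | (m > 1)):
        raise ValueError("p and m must be normalized into [0,1]")
    out = lam * p + (1.0 - lam) * m
    return float(out) if out.ndim == 0 else out
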