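"""Similarity scoring: per-entity cosines, fitted entity weights, final score.

Each person is compared against the target profile entity by entity with
cosine similarity between their occurrence-count vector over the featured
codes and the profile's weight vector, giving four scores in [0, 1]. An
ordinary-least-squares fit of the recruitment label on the four entity
scores supplies the entity weights; the weighted combination is min–max
scaled within each test set to give the final prediction score in [0, 1].
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_profile import TargetProfile
from .records import ENTITIES, PersonRecord, count_vector

# entity -> score column, in the canonical order
SCORE_COLUMNS: dict[str, str] = {
    "diagnosis": "s_diag",
    "procedure": "s_proc",
    "prescription": "s_presc",
    "lab_test": "s_lab",
}


@dataclass
class EntityScores:
    person_id: str
    s_diag: float
    s_proc: float
    s_presc: float
    s_lab: float
    final_raw: float = np.nan
    final_scaled: float = np.nan

    def as_array(self) -> np.ndarray:
        return np.array([self.s_diag, self.s_proc, self.s_presc, self.s_lab])


@dataclass
class EntityWeights:
    """OLS coefficients combining the four entity similarities."""

    w_diag: float
    w_proc: float
    w_presc: float
    w_lab: float
    intercept: float
    n_positive: int = 0
    n_negative: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.w_diag, self.w_proc, self.w_presc, self.w_lab])


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two nonnegative vectors.

    Lies in [0, 1] because all entries are nonnegative. If either vector
    is all-zero the similarity is defined as 0 (maximally dissimilar), so
    persons carrying none of the featured codes sink in the ranking.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def entity_scores(
    person: PersonRecord, profile: TargetProfile, binary: bool = False
) -> EntityScores:
    """The four per-entity similarity scores for one person."""
    s = {}
    for entity in ENTITIES:
        ep = profile[entity]
        if len(ep.codes) == 0:
            s[entity] = 0.0
            continue
        cv = count_vector(person, entity, ep.codes, binary=binary)
        s[entity] = cosine_similarity(cv.counts, ep.weights)
    return EntityScores(
        person_id=person.person_id,
        s_diag=s["diagnosis"],
        s_proc=s["procedure"],
        s_presc=s["prescription"],
        s_lab=s["lab_test"],
    )


def score_population(
    events: pd.DataFrame,
    person_ids: Sequence[str],
    profile: TargetProfile,
    binary: bool = False,
) -> pd.DataFrame:
    """Entity scores for many persons at once from a long-form event table.

    Equivalent to calling :func:`entity_scores` per person but computed
    with grouped aggregation, so test pools of tens of thousands of
    registrants score in seconds. Returns one row per requested person
    (columns ``person_id, s_diag, s_proc, s_presc, s_lab``); persons
    without events of an entity's featured codes score 0 for that entity.
    """
    person_ids = pd.Index(pd.unique(pd.Series(list(person_ids), dtype=object)))
    out = pd.DataFrame({"person_id": person_ids})
    events = events[events["person_id"].isin(person_ids)]
    for entity in ENTITIES:
        col = SCORE_COLUMNS[entity]
        ep = profile[entity]
        norm_w = float(np.linalg.norm(ep.weights))
        if len(ep.codes) == 0 or norm_w == 0.0:
            out[col] = 0.0
            continue
        weight_of = pd.Series(ep.weights, index=list(ep.codes), name="weight")
        sub = events[
            (events["entity"] == entity) & events["code"].isin(weight_of.index)
        ]
        if sub.empty:
            out[col] = 0.0
            continue
        counts = (
            sub.groupby(["person_id", "code"], sort=False, observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        if binary:
            counts["count"] = 1
        counts["weight"] = counts["code"].map(weight_of)
        counts["cw"] = counts["count"] * counts["weight"]
        counts["c2"] = counts["count"].astype(float) ** 2
        per_person = counts.groupby("person_id", sort=False)[["cw", "c2"]].sum()
        cos = per_person["cw"] / (np.sqrt(per_person["c2"]) * norm_w)
        out[col] = out["person_id"].map(cos).fillna(0.0)
    return out


def fit_entity_weights(training_scores: pd.DataFrame, labels) -> EntityWeights:
    """Ordinary least squares of the 0/1 label on the four entity scores.

    ``training_scores`` must contain the four ``s_*`` columns; ``labels``
    is aligned positionally. A rank-deficient design (e.g. a constant
    entity score) is resolved by the minimum-norm solution.
    """
    labels = np.asarray(labels, dtype=float)
    if len(training_scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(labels) < 5:
        raise ValueError("need at least 5 training rows to fit entity weights")
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "all training labels are identical; add non-participant "
            "(negative) rows to the regression training set"
        )
    X = training_scores[list(SCORE_COLUMNS.values())].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(design, labels, rcond=None)
    n_pos = int((labels == 1).sum())
    return EntityWeights(
        w_diag=float(coef[1]),
        w_proc=float(coef[2]),
        w_presc=float(coef[3]),
        w_lab=float(coef[4]),
        intercept=float(coef[0]),
        n_positive=n_pos,
        n_negative=int(len(labels) - n_pos),
    )


def final_score(scores: pd.DataFrame, weights: EntityWeights) -> np.ndarray:
    """Raw prediction score: intercept + weighted sum of entity scores."""
    X = scores[list(SCORE_COLUMNS.values())].to_numpy(dtype=float)
    return weights.intercept + X @ weights.as_array()


def scale_scores(raw_scores) -> np.ndarray:
    """Min–max scale raw scores to [0, 1] within one test set.

    Rank-preserving, so every ranking metric and the ROC AUC are unchanged
    by the scaling. When all raw scores are equal the scaled scores are
    all 0.5 by convention.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one score to scale")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)
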