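"""Featured-code selection and the central-tendency target profile.

The target profile is the idealised participant for one project: for each
entity, a list of *featured codes* chosen by their support among the
training participants, weighted by the central tendency (mean or median)
of each code's occurrence count across those participants.

The selection rule per entity: codes carried by at least 80% of training
participants are featured. If at least ``min_codes`` (default 10) pass,
all passing codes are kept. If some but fewer than ``min_codes`` pass, the
list is topped up to ``min_codes`` with the highest-support codes overall.
If no code reaches the threshold (sparse data), every observed code is
retained.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ENTITIES, PersonRecord, count_vector

SELECTION_META = ("threshold_met", "topped_up", "all_retained")


@dataclass
class EntityProfile:
    """Featured codes and their central-tendency weights for one entity."""

    codes: tuple[str, ...]
    weights: np.ndarray
    selection_meta: str
    support_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.codes = tuple(self.codes)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.codes) != len(self.weights):
            raise ValueError("codes and weights must have the same length")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("featured codes must not contain duplicates")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if self.selection_meta not in SELECTION_META:
            raise ValueError(f"unknown selection_meta {self.selection_meta!r}")


@dataclass
class TargetProfile:
    """Per-entity featured codes with weights — the idealised participant."""

    entities: dict[str, EntityProfile]

    def __getitem__(self, entity: str) -> EntityProfile:
        return self.entities[entity]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (entity, code, w, ep.selection_meta)
            for entity, ep in self.entities.items()
            for code, w in zip(ep.codes, ep.weights)
        ]
        return pd.DataFrame(rows, columns=["entity", "code", "weight", "selection_meta"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TargetProfile":
        df = pd.read_csv(path, dtype={"code": str})
        entities = {}
        for entity, grp in df.groupby("entity", sort=False):
            entities[entity] = EntityProfile(
                codes=tuple(grp["code"]),
                weights=grp["weight"].to_numpy(dtype=float),
                selection_meta=grp["selection_meta"].iloc[0],
            )
        return cls(entities)


def code_support(
    training_persons: Sequence[PersonRecord], entity: str
) -> dict[str, float]:
    """Fraction of training persons carrying each observed code at least once.

    A person contributes once per code regardless of repeat occurrences.
    """
    if not training_persons:
        raise ValueError("training set must not be empty")
    carriers: Counter = Counter()
    for person in training_persons:
        carriers.update(person.codes(entity))
    n = len(training_persons)
    return {code: k / n for code, k in carriers.items()}


def select_feature_codes(
    training_persons: Sequence[PersonRecord],
    entity: str,
    support_threshold: float = 0.8,
    min_codes: int = 10,
    top_up: bool = True,
) -> tuple[list[str], str]:
    """Choose the featured codes of one entity from training participants.

    Returns ``(codes, selection_meta)`` where ``selection_meta`` is one of
    ``threshold_met`` (>= ``min_codes`` codes passed the threshold — all
    passing codes returned), ``topped_up`` (some passed but fewer than
    ``min_codes`` — list extended with the next-highest-support codes; pass
    ``top_up=False`` to return only the passing codes), or ``all_retained``
    (no code passed — every observed code returned).

    Ties in support are broken lexicographically by code string, and the
    returned list is ordered by descending support then code, so the
    selection is deterministic.
    """
    support = code_support(training_persons, entity)
    ordered = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    passing = [code for code, s in ordered if s >= support_threshold]

    if len(passing) >= min_codes:
        return passing, "threshold_met"
    if passing:
        if not top_up:
            return passing, "topped_up"
        return [code for code, _ in ordered[:min_codes]], "topped_up"
    return [code for code, _ in ordered], "all_retained"


def build_target_profile(
    training_persons: Sequence[PersonRecord],
    support_threshold: float = 0.8,
    min_codes: int = 10,
    tendency: str = "mean",
    binary: bool = False,
    top_up: bool = True,
) -> TargetProfile:
    """Select featured codes for each entity and weight them.

    The weight of a featured code is the chosen central tendency (``mean``
    or ``median``) of its occurrence count across training participants
    (of its presence indicator when ``binary=True``). With a single
    training person the profile is simply that person's count vector.
    """
    if tendency not in ("mean", "median"):
        raise ValueError(f"tendency must be 'mean' or 'median', got {tendency!r}")
    agg = np.mean if tendency == "mean" else np.median
    entities: dict[str, EntityProfile] = {}
    for entity in ENTITIES:
        codes, meta = select_feature_codes(
            training_persons, entity, support_threshold, min_codes, top_up
        )
        if codes:
            counts = np.stack(
                [
                    count_vector(p, entity, codes, binary=binary).counts
                    for p in training_persons
                ]
            )
            weights = agg(counts.astype(float), axis=0)
        else:
            weights = np.zeros(0)
        entities[entity] = EntityProfile(
            codes=tuple(codes),
            weights=weights,
            selection_meta=meta,
            support_threshold=support_threshold,
        )
    return TargetProfile(entities)
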