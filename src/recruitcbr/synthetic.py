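"""Synthetic EAV cohort generator.

Emulates the statistical structure the case-based-reasoning analysis
assumes about registry EHR data, so the full pipeline can be exercised
end to end on data of known ground truth:

* four coded entities with sparse, heavy-tailed (Zipf-like) background
  code usage;
* a small participant cohort embedded in a large registrant pool;
* participants sharing per-entity *signature codes* at high within-cohort
  support, while non-participants carry them only rarely;
* a noisy database-query candidate set (the comparator recruitment
  strategy), generated independently of any similarity score.

Codes are synthetic tokens (e.g. ``D0042``); there is no calendar
structure and no comorbidity correlation between codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import ENTITIES, EVENT_COLUMNS, LABEL_COLUMNS

_ENTITY_PREFIX = {
    "diagnosis": "D",
    "procedure": "P",
    "prescription": "B",
    "lab_test": "L",
}


def _per_entity(value, caster=lambda x: x) -> dict[str, float]:
    """Broadcast a scalar to all four entities, or validate a mapping."""
    if isinstance(value, dict):
        missing = set(ENTITIES) - set(value)
        if missing:
            raise ValueError(f"per-entity parameter missing entities {sorted(missing)}")
        return {e: caster(value[e]) for e in ENTITIES}
    return {e: caster(value) for e in ENTITIES}


@dataclass
class CohortSpec:
    """Parameters of one synthetic project cohort.

    Defaults reflect the geometry of the real register: a pool of 30,000
    registrants per test fold, a participant cohort in the 2–28 range,
    heavy-tailed code usage (Zipf exponent 1.2), signature-code penetrance
    0.9 among participants against 0.02 background carriage.
    """

    n_registrants: int = 30_000
    n_participants: int = 14
    vocab_size: int | dict = 500
    background_shape: float | dict = 1.2
    events_per_person: float | dict = 8.0
    signature_codes: int | dict = 10
    signature_penetrance: float = 0.9
    background_carriage: float = 0.02
    db_sensitivity: float = 0.7
    db_specificity_slack: int = 100
    project_id: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        for name in ("signature_penetrance", "background_carriage", "db_sensitivity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        vocab = _per_entity(self.vocab_size, int)
        sig = _per_entity(self.signature_codes, int)
        for e in ENTITIES:
            if sig[e] > vocab[e]:
                raise ValueError(
                    f"infeasible spec: {sig[e]} signature codes exceed the "
                    f"vocabulary of {vocab[e]} for entity {e}"
                )
            if sig[e] >= vocab[e]:
                raise ValueError(
                    f"infeasible spec: entity {e} needs at least one "
                    "non-signature background code (vocab_size > signature_codes)"
                )
        shape = _per_entity(self.background_shape, float)
        if any(s <= 0 for s in shape.values()):
            raise ValueError("background_shape must be positive")


@dataclass
class SyntheticPopulation:
    """A generated cohort: events, labels and the signature-code truth."""

    events: pd.DataFrame
    labels: pd.DataFrame
    truth: dict[str, tuple[str, ...]]
    spec: CohortSpec = field(repr=False, default=None)


def _vocabulary(entity: str, size: int) -> np.ndarray:
    prefix = _ENTITY_PREFIX[entity]
    width = max(4, len(str(size)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, size + 1)])


def generate_population(spec: CohortSpec) -> SyntheticPopulation:
    """Draw one cohort deterministically from ``spec.seed``.

    Background events per person per entity number ``1 + Poisson(m - 1)``
    (guaranteeing every person passes the strict inclusion filter) with
    codes drawn from a Zipf-like distribution over the entity's
    non-signature vocabulary. Participants additionally carry each
    signature code with probability ``signature_penetrance``;
    non-participants with probability ``background_carriage``. The
    database-identified flag is set for participants with probability
    ``db_sensitivity`` plus a fixed-size slack set of non-participants.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _per_entity(spec.vocab_size, int)
    sig_n = _per_entity(spec.signature_codes, int)
    shape = _per_entity(spec.background_shape, float)
    mean_events = _per_entity(spec.events_per_person, float)

    n_total = spec.n_participants + spec.n_registrants
    person_ids = np.array(
        [f"P{i:04d}" for i in range(1, spec.n_participants + 1)]
        + [f"R{i:06d}" for i in range(1, spec.n_registrants + 1)]
    )
    is_participant = np.zeros(n_total, dtype=bool)
    is_participant[: spec.n_participants] = True

    truth: dict[str, tuple[str, ...]] = {}
    frames: list[pd.DataFrame] = []
    for entity in ENTITIES:
        codes_all = _vocabulary(entity, vocab[entity])
        # signature codes sit outside the background vocabulary so that
        # carriage probabilities are governed solely by the spec
        sig_codes = codes_all[vocab[entity] - sig_n[entity] :]
        bg_codes = codes_all[: vocab[entity] - sig_n[entity]]
        truth[entity] = tuple(sig_codes)

        ranks = np.arange(1, len(bg_codes) + 1, dtype=float)
        pmf = ranks ** (-shape[entity])
        pmf /= pmf.sum()

        lam = max(mean_events[entity] - 1.0, 0.0)
        n_events = 1 + rng.poisson(lam, size=n_total)
        total = int(n_events.sum())
        drawn = rng.choice(len(bg_codes), size=total, p=pmf)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(person_ids, n_events),
                    "entity": entity,
                    "code": bg_codes[drawn],
                }
            )
        )

        # signature carriage: one occurrence per carried code
        p_carry = np.where(
            is_participant, spec.signature_penetrance, spec.background_carriage
        )
        carry = rng.random((n_total, sig_n[entity])) < p_carry[:, None]
        who, which = np.nonzero(carry)
        if len(who):
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_ids[who],
                        "entity": entity,
                        "code": sig_codes[which],
                    }
                )
            )

    events = pd.concat(frames, ignore_index=True)
    events["event_date"] = None
    events["value"] = np.nan
    events["quantity"] = np.nan
    events = events[list(EVENT_COLUMNS)]
    events = events.sort_values(
        ["person_id", "entity", "code"], kind="stable", ignore_index=True
    )

    db_flag = np.zeros(n_total, dtype=np.int64)
    db_flag[: spec.n_participants] = (
        rng.random(spec.n_participants) < spec.db_sensitivity
    ).astype(np.int64)
    n_slack = min(spec.db_specificity_slack, spec.n_registrants)
    if n_slack:
        slack = rng.choice(spec.n_registrants, size=n_slack, replace=False)
        db_flag[spec.n_participants + slack] = 1

    labels = pd.DataFrame(
        {
            "person_id": person_ids,
            "project_id": spec.project_id,
            "recruited": is_participant.astype(np.int64),
            "db_identified": db_flag,
        }
    )[list(LABEL_COLUMNS)]

    return SyntheticPopulation(events=events, labels=labels, truth=truth, spec=spec)


def generate_null_population(spec: CohortSpec) -> SyntheticPopulation:
    """A cohort whose recruited labels are independent of every code.

    Signature penetrance is set equal to the background carriage, so the
    participant flag carries no signal; any downstream discrimination
    metric should be at chance level.
    """
    null_spec = replace(spec, signature_penetrance=spec.background_carriage)
    return generate_population(null_spec)
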