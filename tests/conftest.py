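import numpy as np
import pytest

from recruitcbr import CodedEvent, PersonRecord
from recruitcbr.records import ENTITIES


def make_person(pid, diagnosis=(), procedure=(), prescription=(), lab_test=()):
    """Build a PersonRecord from per-entity code lists (repeats allowed)."""
    by_entity = {
        "diagnosis": diagnosis,
        "procedure": procedure,
        "prescription": prescription,
        "lab_test": lab_test,
    }
    events = [
        CodedEvent(pid, entity, code)
        for entity in ENTITIES
        for code in by_entity[entity]
    ]
    return PersonRecord(pid, tuple(events))


@pytest.fixture
def mk_person():
    return make_person


@pytest.fixture
def full_coverage_person(mk_person):
    """One person with at least one event in every entity."""
    return mk_person(
        "p1",
        diagnosis=["D1", "D1", "D2"],
        procedure=["P1"],
        prescription=["B1", "B2"],
        lab_test=["L1"],
    )


@pytest.fixture(scope="session")
def small_population():
    """A small strong-signal synthetic cohort shared across tests."""
    from recruitcbr import CohortSpec, generate_population

    spec = CohortSpec(
        n_registrants=800,
        n_participants=10,
        vocab_size=120,
        signature_codes=8,
        events_per_person=6.0,
        seed=11,
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def small_config():
    from recruitcbr import PipelineConfig

    return PipelineConfig(
        n_random=500, n_negatives=100, n_bootstrap=50, seed=11
    )
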