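import pytest

from psynet.cohort import (
    CatalogEntry,
    CharacteristicCatalog,
    Cohort,
    CohortRecord,
    LabPanelPair,
    LabValues,
    Outcome,
    Sex,
)


@pytest.fixture
def small_catalog():
    return CharacteristicCatalog(
        (
            CatalogEntry("A", "trait A", "child"),
            CatalogEntry("B", "trait B", "child"),
            CatalogEntry("C", "trait C", "guardian"),
            CatalogEntry("D", "trait D", "guardian"),
        )
    )


def _rec(cid, chars, sex=Sex.MALE, dz=0.5, z_entry=2.5, labs=None, age=6.0):
    return CohortRecord(
        child_id=cid,
        sex=sex,
        age_years=age,
        characteristics=frozenset(chars),
        z_bmi_entry=z_entry,
        z_bmi_exit=z_entry - dz,
        labs=labs,
    )


@pytest.fixture
def tiny_cohort(small_catalog):
    """Three children, no labs, no labels."""
    records = (
        _rec("k1", {"A", "B"}, Sex.MALE),
        _rec("k2", {"A"}, Sex.FEMALE),
        _rec("k3", set(), Sex.FEMALE),
    )
    return Cohort(small_catalog, records)


@pytest.fixture
def labeled_cohort(small_catalog):
    """Four children per group with a hand-countable expression pattern."""
    impv = [
        _rec("i1", {"A", "B"}),
        _rec("i2", {"A", "B", "C"}),
        _rec("i3", {"A"}),
        _rec("i4", {"B"}),
    ]
    mc = [
        _rec("m1", {"A", "C"}),
        _rec("m2", {"C"}),
        _rec("m3", {"C", "D"}),
        _rec("m4", {"D"}),
    ]
    labels = {r.child_id: Outcome.IMPV for r in impv}
    labels.update({r.child_id: Outcome.MC for r in mc})
    return Cohort(small_catalog, tuple(impv + mc), labels)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded realization of the study-mirroring scenario."""
    from psynet.simulate import default_scenario, generate_cohort

    return generate_cohort(default_scenario(12345))


def make_labs(first=(20.0, 130.0, 3.5), last=(15.0, 100.0, 2.5)):
    return LabPanelPair(first=LabValues(*first), last=LabValues(*last))


@pytest.fixture
def rec_factory():
    return _rec
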