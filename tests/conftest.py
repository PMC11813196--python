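"""Shared fixtures: the shipped knowledge base plus small constructed ones."""

import pytest

from lbp_cds import Expression, KnowledgeBase, TRUE
from lbp_cds.knowledge_base import (
    ALL_DIAGNOSES,
    DiagnosisDefinition,
    EducationMaterial,
    ItemDefinition,
    TreatmentRecommendation,
    default_kb,
)


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return default_kb()


def make_kb(items, diagnoses, treatments=None, education=None, version="test-1"):
    """Assemble a KnowledgeBase from component lists (no file round trip)."""
    treatments = treatments if treatments is not None else [
        TreatmentRecommendation("t_all", "Education about condition", ALL_DIAGNOSES)
    ]
    education = education or []
    return KnowledgeBase(
        version=version,
        items={i.item_id: i for i in items},
        diagnoses={d.dx_id: d for d in diagnoses},
        treatments={t.treatment_id: t for t in treatments},
        education={e.edu_id: e for e in education},
    )


@pytest.fixture()
def minimal_kb() -> KnowledgeBase:
    """Smallest valid KB: one always-enabled item, one single-atom macro
    diagnosis, one ALL treatment."""
    item = ItemDefinition("q1", "The only question", "interview")
    dx = DiagnosisDefinition(
        dx_id="d1",
        name="Only diagnosis",
        level="macro",
        rule=Expression.atom("q1", "present"),
        evidence_atoms=(("q1", "present"),),
    )
    return make_kb([item], [dx])


@pytest.fixture()
def chain_kb() -> KnowledgeBase:
    """A enables B enables C: exercises cascading enablement retraction."""
    a = ItemDefinition("a", "Item A", "interview")
    b = ItemDefinition("b", "Item B", "interview",
                       enabled_when=Expression.atom("a", "present"))
    c = ItemDefinition("c", "Item C", "examination",
                       enabled_when=Expression.atom("b", "present"))
    dx = DiagnosisDefinition(
        dx_id="d1", name="Chain diagnosis", level="macro",
        rule=Expression.atom("c", "present"),
        evidence_atoms=(("a", "present"), ("b", "present"), ("c", "present")),
    )
    return make_kb([a, b, c], [dx])
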