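"""Diagnostic inference: rule triggering, evidence counting, likeliness
scale, suppression, ranking, and clinician selections."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from lbp_cds import (
    Expression,
    KBIntegrityError,
    NotFoundError,
    apply_suppression,
    evaluate_diagnoses,
    evaluate_expression,
    evaluate_findings,
    evidence_count,
    new_session,
    record_finding,
    set_dx_selection,
    supporting_findings,
)
from lbp_cds.inference import _evaluate_one
from lbp_cds.knowledge_base import (
    DiagnosisDefinition,
    ItemDefinition,
    SuppressionEntry,
)

from conftest import make_kb

PIRIFORMIS_FINDINGS = {
    "radiating_leg_pain": "present",
    "sciatic_notch_tenderness": "present",
    "buttock_pain": "present",
    "straight_leg_raise": "present",
    "prolonged_sitting_pain": "present",
}


def test_piriformis_rule_or_semantics(kb):
    rule = kb.diagnoses["piriformis_syndrome"].rule
    assert evaluate_expression(rule, {"buttock_pain": "present"}, kb) is True
    assert evaluate_expression(rule, {}, kb) is False
    assert evaluate_expression(rule, {"buttock_pain": "absent"}, kb) is False


def test_evaluate_expression_rejects_unresolvable_atoms(kb):
    with pytest.raises(KBIntegrityError):
        evaluate_expression(Expression.atom("ghost", "present"), {}, kb)


def test_evidence_count_full_and_partial(kb):
    dx = kb.diagnoses["piriformis_syndrome"]
    count, supporting = evidence_count(dx, PIRIFORMIS_FINDINGS)
    assert count == 5 and len(supporting) == 5
    count, supporting = evidence_count(dx, {"buttock_pain": "present"})
    assert count == 1
    assert supporting == frozenset({("buttock_pain", "present")})
    assert evidence_count(dx, {})[0] == 0


def test_scale_value_endpoints_match_likeliness_anchors(kb):
    """One satisfied finding grades 'less likely' (1); all five grade
    'more likely' (scale_max)."""
    dx = kb.diagnoses["piriformis_syndrome"]
    one = _evaluate_one(dx, {"buttock_pain": "present"})
    assert (one.triggered, one.evidence_count, one.scale_value) == (True, 1, 1)
    full = _evaluate_one(dx, PIRIFORMIS_FINDINGS)
    assert full.scale_value == dx.scale_max == 5


def test_untriggered_diagnoses_grade_zero(kb):
    session = new_session(kb)
    for ev in evaluate_diagnoses(kb, session):
        assert not ev.triggered
        assert ev.scale_value == 0
        assert ev.evidence_count == 0
        assert not ev.suppressed


def test_scale_value_range_and_ceiling_condition(kb):
    """scale in {0} u [1, scale_max]; equals scale_max iff all atoms hit."""
    findings_sets = [
        {},
        {"buttock_pain": "present"},
        {"buttock_pain": "present", "radiating_leg_pain": "present"},
        PIRIFORMIS_FINDINGS,
    ]
    for findings in findings_sets:
        for ev in evaluate_findings(kb, findings):
            dx = kb.diagnoses[ev.dx_id]
            assert ev.scale_value == 0 or 1 <= ev.scale_value <= dx.scale_max
            n_atoms = len(dx.evidence_atoms)
            if ev.triggered and n_atoms:
                assert (ev.scale_value == dx.scale_max) == (
                    ev.evidence_count == n_atoms
                ), ev.dx_id
                assert ev.scale_value == max(
                    1, math.ceil(dx.scale_max * ev.evidence_count / n_atoms)
                )


# ---------------------------------------------------------------------------
# Suppression
# ---------------------------------------------------------------------------

def _competing_kb(policy_pairs=(("weak", "strong"),)):
    items = [ItemDefinition(f"q{i}", f"Q{i}", "interview") for i in range(8)]
    strong = DiagnosisDefinition(
        "strong", "Strong dx", "macro",
        rule=Expression.any_of(*[Expression.atom(f"q{i}") for i in range(4)]),
        evidence_atoms=tuple((f"q{i}", "present") for i in range(4)),
    )
    weak = DiagnosisDefinition(
        "weak", "Weak dx", "macro",
        rule=Expression.any_of(*[Expression.atom(f"q{i}") for i in range(4, 8)]),
        evidence_atoms=tuple((f"q{i}", "present") for i in range(4, 8)),
        suppressors=tuple(SuppressionEntry(c) for d, c in policy_pairs if d == "weak"),
    )
    return make_kb(items, [strong, weak])


def test_strict_dominance_suppresses_and_names_the_competitor():
    kb2 = _competing_kb()
    findings = {f"q{i}": "present" for i in (0, 1, 2, 3, 4, 5, 6)}  # 4 vs 3
    evs = {e.dx_id: e for e in evaluate_findings(kb2, findings)}
    assert evs["weak"].suppressed
    assert "Strong dx" in evs["weak"].suppression_reason
    assert not evs["strong"].suppressed
    # counts are untouched by suppression
    assert evs["weak"].evidence_count == 3


def test_equal_counts_do_not_suppress():
    kb2 = _competing_kb()
    findings = {f"q{i}": "present" for i in (0, 1, 4, 5)}  # 2 vs 2
    evs = {e.dx_id: e for e in evaluate_findings(kb2, findings)}
    assert not evs["weak"].suppressed


def test_untriggered_competitor_does_not_suppress():
    kb2 = _competing_kb()
    findings = {f"q{i}": "present" for i in (4, 5)}  # strong untriggered
    evs = {e.dx_id: e for e in evaluate_findings(kb2, findings)}
    assert not evs["weak"].suppressed


def test_suppression_is_single_pass_not_transitive():
    """A suppressed middle competitor still dominates: dominance is read off
    pre-suppression counts only."""
    items = [ItemDefinition(f"q{i}", f"Q{i}", "interview") for i in range(9)]

    def dx(name, lo, hi, suppressor=None):
        return DiagnosisDefinition(
            name, name, "macro",
            rule=Expression.any_of(*[Expression.atom(f"q{i}") for i in range(lo, hi)]),
            evidence_atoms=tuple((f"q{i}", "present") for i in range(lo, hi)),
            suppressors=(SuppressionEntry(suppressor),) if suppressor else (),
        )

    # c (3 findings) suppressed by b (4); a (2) suppressed by... nothing: a's
    # suppressor is c, which despite being suppressed still counts 3 > 2.
    kb2 = make_kb(items, [dx("b", 0, 4), dx("c", 4, 7, "b"), dx("a", 7, 9, "c")])
    findings = {f"q{i}": "present" for i in range(9)}
    evs = {e.dx_id: e for e in evaluate_findings(kb2, findings)}
    assert evs["c"].suppressed
    assert evs["a"].suppressed  # c still dominates a in the single pass


def test_multifactorial_scenario_suppresses_piriformis(kb):
    from lbp_cds import multifactorial_scenario, replay_scenario

    session = replay_scenario(kb, multifactorial_scenario())
    evs = {e.dx_id: e for e in evaluate_diagnoses(kb, session)}
    pir = evs["piriformis_syndrome"]
    assert pir.triggered and pir.suppressed
    assert "Neurogenic claudication" in pir.suppression_reason


# ---------------------------------------------------------------------------
# Ranking determinism and monotonicity
# ---------------------------------------------------------------------------

def test_ranking_is_deterministic_and_total(kb):
    findings = dict(PIRIFORMIS_FINDINGS)
    first = [e.dx_id for e in evaluate_findings(kb, findings)]
    second = [e.dx_id for e in evaluate_findings(kb, findings)]
    assert first == second
    assert len(first) == len(set(first)) == len(kb.diagnoses)


def test_unsuppressed_rank_before_suppressed_then_by_scale_and_count(kb):
    from lbp_cds import multifactorial_scenario, replay_scenario

    session = replay_scenario(kb, multifactorial_scenario())
    evs = evaluate_diagnoses(kb, session)
    keys = [(e.suppressed, -e.scale_value, -e.evidence_count) for e in evs]
    assert keys == sorted(keys)


@st.composite
def negation_free_kb_and_findings(draw):
    n_items = draw(st.integers(min_value=2, max_value=8))
    items = [ItemDefinition(f"q{i}", f"Q{i}", "interview") for i in range(n_items)]
    diagnoses = []
    for d in range(draw(st.integers(min_value=1, max_value=3))):
        k = draw(st.integers(min_value=1, max_value=n_items))
        picked = draw(st.permutations(range(n_items)))[:k]
        atoms = tuple((f"q{i}", "present") for i in picked)
        diagnoses.append(DiagnosisDefinition(
            f"d{d}", f"D{d}", "macro",
            rule=Expression.any_of(*[Expression.atom(i, r) for i, r in atoms]),
            evidence_atoms=atoms,
        ))
    seq = draw(st.lists(st.integers(min_value=0, max_value=n_items - 1),
                        min_size=1, max_size=10))
    return make_kb(items, diagnoses), [f"q{i}" for i in seq]


@settings(max_examples=60, deadline=None)
@given(negation_free_kb_and_findings())
def test_adding_findings_never_decreases_counts_for_negation_free_rules(case):
    kb2, sequence = case
    findings = {}
    prev = {d: 0 for d in kb2.diagnoses}
    for iid in sequence:
        findings[iid] = "present"
        for ev in evaluate_findings(kb2, findings):
            assert ev.evidence_count >= prev[ev.dx_id]
            prev[ev.dx_id] = ev.evidence_count


# ---------------------------------------------------------------------------
# Traceability and selections
# ---------------------------------------------------------------------------

def test_supporting_findings_match_evidence_and_are_active(kb):
    session = new_session(kb)
    record_finding(session, "buttock_pain", "present")
    record_finding(session, "radiating_leg_pain", "present")
    sup = supporting_findings(kb, session, "piriformis_syndrome")
    assert sup == frozenset({("buttock_pain", "present"),
                             ("radiating_leg_pain", "present")})
    act = dict(session.findings)
    assert all(act.get(i) == r for i, r in sup)
    with pytest.raises(NotFoundError):
        supporting_findings(kb, session, "ghost_dx")


def test_dx_selection_lifecycle_and_override_marker(kb):
    session = new_session(kb)
    record_finding(session, "sensory_nerve_root_changes", "present")
    record_finding(session, "leg_symptoms_on_walking", "present")
    set_dx_selection(session, "neurogenic_claudication", "accepted")
    assert session.dx_selections["neurogenic_claudication"] == {"state": "accepted"}
    # accepting an untriggered diagnosis records the override
    set_dx_selection(session, "central_sensitization", "accepted")
    assert session.dx_selections["central_sensitization"]["override"] is True
    # reset removes the selection
    set_dx_selection(session, "central_sensitization", "undecided")
    assert "central_sensitization" not in session.dx_selections
    with pytest.raises(NotFoundError):
        set_dx_selection(session, "ghost", "accepted")
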