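"""Diagnostic inference: rule evaluation, evidence grading, suppression.

Each working diagnosis is *triggered* when its Boolean rule holds against
the active findings. Triggered diagnoses are graded on a likeliness scale:
``scale_value = ceil(scale_max * count / n_atoms)`` clamped to at least 1,
where ``count`` is the number of satisfied evidence atoms — 1 reads "less
likely", ``scale_max`` (default 5) "more likely". The mapping is monotone
in the evidence count and reaches the ceiling exactly when every evidence
atom is satisfied. Working diagnoses are deliberately non-definitive; the
grade summarizes how much of the recorded interview/examination evidence
points at each one, it is not a probability.

Suppression models the clinical judgment that a strongly supported
diagnosis can explain away an overlapping weaker one (e.g. neurogenic
claudication explaining away piriformis syndrome). Pairs are declared in
the knowledge base; the engine applies one pass of strict count dominance:
D is suppressed by its declared competitor C iff both are triggered and
C's evidence count strictly exceeds D's. Suppression flags the diagnosis
and records why; it never alters counts or grades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping

from .errors import KBIntegrityError, NotFoundError, ResponseDomainError
from .expressions import Expression
from .knowledge_base import DiagnosisDefinition, KnowledgeBase
from .session import DX_STATES, Session, active_findings

__all__ = [
    "DiagnosisEvidence",
    "apply_suppression",
    "evaluate_diagnoses",
    "evaluate_expression",
    "evaluate_findings",
    "evidence_count",
    "set_dx_selection",
    "supporting_findings",
]


@dataclass(frozen=True)
class DiagnosisEvidence:
    """Per-diagnosis inference result with full traceability."""

    dx_id: str
    name: str
    level: str
    triggered: bool
    evidence_count: int
    scale_value: int
    scale_max: int
    supporting: frozenset[tuple[str, str]]
    suppressed: bool = False
    suppression_reason: str | None = None
    graded: bool = True

    def to_dict(self) -> dict[str, Any]:
        return {
            "dx_id": self.dx_id,
            "name": self.name,
            "level": self.level,
            "triggered": self.triggered,
            "evidence_count": self.evidence_count,
            "scale_value": self.scale_value,
            "scale_max": self.scale_max,
            "supporting": [
                {"item": i, "response": r} for i, r in sorted(self.supporting)
            ],
            "suppressed": self.suppressed,
            "suppression_reason": self.suppression_reason,
        }


def evaluate_expression(
    expr: Expression, findings: Mapping[str, str], kb: KnowledgeBase | None = None
) -> bool:
    """Boolean rule evaluation; an atom holds iff the findings record exactly
    its required response (unanswered atoms are false). When *kb* is given,
    unresolvable atoms raise instead of silently evaluating false."""
    if kb is not None:
        for iid, _ in expr.atoms():
            if iid not in kb.items:
                raise KBIntegrityError(f"expression references unknown item {iid!r}")
    return expr.evaluate(findings)


def evidence_count(
    dx: DiagnosisDefinition, findings: Mapping[str, str]
) -> tuple[int, frozenset[tuple[str, str]]]:
    """Count satisfied evidence atoms; returns (count, supporting set)."""
    supporting = frozenset(
        (iid, resp) for iid, resp in dx.evidence_atoms if findings.get(iid) == resp
    )
    return len(supporting), supporting


def _scale(dx: DiagnosisDefinition, triggered: bool, count: int) -> int:
    if not triggered:
        return 0
    n = len(dx.evidence_atoms)
    if n == 0:
        return 1  # triggered by a constant-true rule: minimum grade
    value = math.ceil(dx.scale_max * count / n)
    return min(dx.scale_max, max(1, value))


def _evaluate_one(
    dx: DiagnosisDefinition, findings: Mapping[str, str]
) -> DiagnosisEvidence:
    triggered = dx.rule.evaluate(findings)
    count, supporting = evidence_count(dx, findings)
    return DiagnosisEvidence(
        dx_id=dx.dx_id,
        name=dx.name,
        level=dx.level,
        triggered=triggered,
        evidence_count=count,
        scale_value=_scale(dx, triggered, count),
        scale_max=dx.scale_max,
        supporting=supporting,
        graded=dx.graded,
    )


def apply_suppression(
    evidences: list[DiagnosisEvidence], kb: KnowledgeBase
) -> list[DiagnosisEvidence]:
    """One pass of declared pairwise suppression under strict count
    dominance. No transitive chaining: dominance is read off the
    pre-suppression evidence, so the order of pairs cannot matter."""
    by_id = {e.dx_id: e for e in evidences}
    out = []
    for ev in evidences:
        dx = kb.diagnoses[ev.dx_id]
        suppressed_by = None
        if ev.triggered:
            for entry in dx.suppressors:
                comp = by_id.get(entry.competitor)
                if comp is None:
                    raise KBIntegrityError(
                        f"suppressor of {ev.dx_id!r} references unknown "
                        f"diagnosis {entry.competitor!r}"
                    )
                if comp.triggered and comp.evidence_count > ev.evidence_count:
                    suppressed_by = comp
                    break
        if suppressed_by is not None:
            out.append(
                replace(
                    ev,
                    suppressed=True,
                    suppression_reason=(
                        f"rejected in favor of {suppressed_by.name}: overlapping "
                        f"presentation with stronger evidence "
                        f"({suppressed_by.evidence_count} vs {ev.evidence_count} findings)"
                    ),
                )
            )
        else:
            out.append(ev)
    return out


def _rank(kb: KnowledgeBase, evidences: list[DiagnosisEvidence]) -> list[DiagnosisEvidence]:
    order = {dx_id: n for n, dx_id in enumerate(kb.diagnoses)}
    return sorted(
        evidences,
        key=lambda e: (e.suppressed, -e.scale_value, -e.evidence_count, order[e.dx_id]),
    )


def evaluate_findings(
    kb: KnowledgeBase, findings: Mapping[str, str]
) -> list[DiagnosisEvidence]:
    """Evaluate every diagnosis against a findings map and rank the results.

    Ranking is a deterministic total order: unsuppressed before suppressed,
    then scale value descending, evidence count descending, knowledge-base
    declaration order as the final tie-break.
    """
    evidences = [_evaluate_one(dx, findings) for dx in kb.diagnoses.values()]
    return _rank(kb, apply_suppression(evidences, kb))


def evaluate_diagnoses(kb: KnowledgeBase, session: Session) -> list[DiagnosisEvidence]:
    """Evaluate all diagnoses against the session's *active* findings."""
    return evaluate_findings(kb, active_findings(session))


def supporting_findings(
    kb: KnowledgeBase, session: Session, dx_id: str
) -> frozenset[tuple[str, str]]:
    """Findings that constitute the evidence for one diagnosis — the set a
    UI highlights in the patient summary on hover."""
    if dx_id not in kb.diagnoses:
        raise NotFoundError(f"unknown diagnosis {dx_id!r}")
    _, supporting = evidence_count(kb.diagnoses[dx_id], active_findings(session))
    return supporting


def set_dx_selection(session: Session, dx_id: str, state: str) -> Session:
    """Record the clinician's accept/reject call on a working diagnosis.

    Accepting a diagnosis the model did not trigger is allowed — clinical
    judgment outranks the rules — but is marked ``override: true`` so the
    departure from the model stays visible in the record. Resetting to
    ``undecided`` removes the selection.
    """
    if dx_id not in session.kb.diagnoses:
        raise NotFoundError(f"unknown diagnosis {dx_id!r}")
    if state not in DX_STATES:
        raise ResponseDomainError(
            f"diagnosis selection state must be one of {DX_STATES}, got {state!r}"
        )
    if state == "undecided":
        session.dx_selections.pop(dx_id, None)
    else:
        entry: dict[str, Any] = {"state": state}
        if state == "accepted":
            ev = {e.dx_id: e for e in evaluate_diagnoses(session.kb, session)}[dx_id]
            if not ev.triggered:
                entry["override"] = True
        session.dx_selections[dx_id] = entry
    session.touch()
    return session
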