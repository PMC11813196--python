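"""Care planning: treatments and patient education for accepted diagnoses,
and export of a copy-pasteable clinical note.

Treatment recommendations are declared against diagnoses in the knowledge
base; some apply to every working diagnosis (the ``ALL`` sentinel). The
plan lists each applicable treatment once with the accepted diagnoses that
contribute to it, ordered by breadth of contribution (treatments indicated
by more of the accepted diagnoses first) — absent published evidence
weights, breadth is the only principled priority and is documented as
provisional. Education materials are the union over accepted diagnoses,
de-duplicated, in knowledge-base order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from .errors import EmptyPlanError, NotFoundError
from .inference import DiagnosisEvidence
from .knowledge_base import EducationMaterial, KnowledgeBase, TreatmentRecommendation
from .session import Session, summary

__all__ = [
    "CarePlan",
    "build_care_plan",
    "export_education",
    "export_note",
    "recommend_treatments",
    "select_education",
    "toggle_treatment",
]


@dataclass(frozen=True)
class CarePlan:
    """Selected diagnoses with their treatments and education materials."""

    accepted: tuple[str, ...]
    treatments: tuple[tuple[TreatmentRecommendation, tuple[str, ...]], ...]
    education: tuple[EducationMaterial, ...]
    generated: str = field(
        default_factory=lambda: datetime.now(timezone.utc).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "accepted": list(self.accepted),
            "treatments": [
                {
                    "treatment_id": t.treatment_id,
                    "name": t.name,
                    "contributing": list(contrib),
                }
                for t, contrib in self.treatments
            ],
            "education": [{"edu_id": e.edu_id, "title": e.title} for e in self.education],
            "generated": self.generated,
        }


def _check_dx_ids(kb: KnowledgeBase, dx_ids: Iterable[str]) -> list[str]:
    ids = list(dx_ids)
    for did in ids:
        if did not in kb.diagnoses:
            raise NotFoundError(f"unknown diagnosis {did!r}")
    return ids


def recommend_treatments(
    kb: KnowledgeBase, accepted: Sequence[str]
) -> list[tuple[TreatmentRecommendation, tuple[str, ...]]]:
    """Applicable treatments for the accepted diagnoses, each with its
    contributing diagnoses, de-duplicated and ordered by breadth."""
    accepted = _check_dx_ids(kb, accepted)
    if not accepted:
        raise EmptyPlanError("a care plan requires at least one accepted diagnosis")
    out: list[tuple[TreatmentRecommendation, tuple[str, ...]]] = []
    for t in kb.treatments.values():  # KB declaration order
        if t.applies_to_all:
            contributing = tuple(accepted)
        else:
            contributing = tuple(d for d in accepted if d in t.applies_to)
        if contributing:
            out.append((t, contributing))
    out.sort(
        key=lambda pair: (
            -len(pair[1]),
            list(kb.treatments).index(pair[0].treatment_id),
        )
    )
    return out


def select_education(kb: KnowledgeBase, accepted: Sequence[str]) -> list[EducationMaterial]:
    """Union of education materials across accepted diagnoses, each once,
    in knowledge-base declaration order."""
    accepted = _check_dx_ids(kb, accepted)
    wanted = {
        eid for did in accepted for eid in kb.diagnoses[did].education_ids
    }
    return [kb.education[eid] for eid in kb.education if eid in wanted]


def toggle_treatment(session: Session, treatment_id: str, enabled: bool) -> Session:
    """Turn a recommended treatment on or off for this encounter. The
    treatment must be in the current plan (i.e. recommended for the
    currently accepted diagnoses); all recommended treatments default ON."""
    accepted = [
        d for d, sel in session.dx_selections.items() if sel.get("state") == "accepted"
    ]
    recommended = {
        t.treatment_id for t, _ in recommend_treatments(session.kb, accepted)
    }
    if treatment_id not in recommended:
        raise NotFoundError(
            f"treatment {treatment_id!r} is not in the current plan"
        )
    session.treatment_selections[treatment_id] = enabled
    session.touch()
    return session


def build_care_plan(kb: KnowledgeBase, session: Session) -> CarePlan:
    """Assemble the plan from the session's accepted diagnoses, honoring
    per-session treatment toggles (unset = ON)."""
    accepted = [
        d for d, sel in session.dx_selections.items() if sel.get("state") == "accepted"
    ]
    treatments = [
        (t, contrib)
        for t, contrib in recommend_treatments(kb, accepted)
        if session.treatment_selections.get(t.treatment_id, True)
    ]
    education = tuple(select_education(kb, accepted))
    return CarePlan(
        accepted=tuple(accepted), treatments=tuple(treatments), education=education
    )


def export_note(
    session: Session, evidences: Sequence[DiagnosisEvidence], plan: CarePlan
) -> str:
    """Deterministic plain-text clinical note.

    A pure function of its arguments (wall-clock time is deliberately kept
    out of the body so identical sessions export byte-identical notes).
    Sections: patient summary, accepted working diagnoses with their grade
    and supporting findings, treatments with contributing diagnoses,
    education titles.
    """
    if not plan.accepted:
        raise EmptyPlanError("cannot export a note without accepted diagnoses")
    kb = session.kb
    ev_by_id = {e.dx_id: e for e in evidences}
    lines: list[str] = []
    lines.append("LOW BACK PAIN DECISION SUPPORT NOTE")
    lines.append("")
    lines.append("Patient summary")
    lines.append("---------------")
    lines.append(summary(session).render())
    lines.append("")
    lines.append("Accepted working diagnoses")
    lines.append("--------------------------")
    for dx_id in plan.accepted:
        dx = kb.diagnoses[dx_id]
        ev = ev_by_id.get(dx_id)
        if ev is None:
            lines.append(f"- {dx.name}")
            continue
        marker = " [clinician override]" if not ev.triggered else ""
        lines.append(
            f"- {dx.name} (evidence {ev.scale_value}/{ev.scale_max}){marker}"
        )
        for iid, resp in sorted(ev.supporting):
            lines.append(f"    * {kb.items[iid].text}: {resp}")
    lines.append("")
    lines.append("Treatment recommendations")
    lines.append("-------------------------")
    for t, contrib in plan.treatments:
        names = ", ".join(kb.diagnoses[d].name for d in contrib)
        lines.append(f"- {t.name}  (for: {names})")
    lines.append("")
    lines.append("Patient education")
    lines.append("-----------------")
    for edu in plan.education:
        lines.append(f"- {edu.title}")
    lines.append("")
    return "\n".join(lines)


def export_education(plan: CarePlan, directory: str | Path) -> list[Path]:
    """Write each selected education material as ``edu_<edu_id>.md``
    (the printable surface; PDF rendering is a front-end concern)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for edu in plan.education:
        path = directory / f"edu_{edu.edu_id}.md"
        path.write_text(f"# {edu.title}\n\n{edu.body}\n", encoding="utf-8")
        paths.append(path)
    return paths


def plan_to_json(plan: CarePlan) -> str:
    return json.dumps(plan.to_dict(), indent=2)
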