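"""One patient encounter: recorded findings, adaptive enablement, summary,
and persistence.

The adaptive logic works on the *active* findings: the greatest subset of
the recorded findings that is self-consistent with the enabling rules
(every item in the subset is enabled when enablement is evaluated against
the subset itself). Findings whose item becomes disabled are retained in
``findings`` but excluded from the active set, and come back automatically
if the item is re-enabled — the convention familiar from conditional form
fields. Enablement is therefore a pure function of the findings map, never
of the order in which findings were entered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

from .errors import (
    EnablementError,
    KBFormatError,
    KBIntegrityError,
    NotFoundError,
    ResponseDomainError,
    VersionMismatchError,
)
from .knowledge_base import ItemDefinition, KnowledgeBase, validate_kb

__all__ = [
    "PatientSummary",
    "Session",
    "active_findings",
    "enabled_items",
    "load_session",
    "new_session",
    "record_finding",
    "retract_finding",
    "save_session",
    "summary",
]

DX_STATES = ("accepted", "rejected", "undecided")

_PHASE_RANK = {"interview": 0, "examination": 1, "synthesis": 2}


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass
class Session:
    """Single-writer record of one encounter, bound to a knowledge base."""

    kb: KnowledgeBase
    kb_version: str
    findings: dict[str, str] = field(default_factory=dict)
    dx_selections: dict[str, dict[str, Any]] = field(default_factory=dict)
    treatment_selections: dict[str, bool] = field(default_factory=dict)
    created: str = field(default_factory=_now)
    modified: str = field(default_factory=_now)

    def touch(self) -> None:
        self.modified = _now()

    def to_dict(self) -> dict[str, Any]:
        return {
            "kb_version": self.kb_version,
            "findings": dict(self.findings),
            "dx_selections": {k: dict(v) for k, v in self.dx_selections.items()},
            "treatment_selections": dict(self.treatment_selections),
            "created": self.created,
            "modified": self.modified,
        }


@dataclass(frozen=True)
class PatientSummary:
    """Ordered rendering of the active findings (display text, not ids),
    grouped interview -> examination -> synthesis with clusters contiguous."""

    rows: tuple[tuple[str, str], ...]  # (item text, response)

    def __len__(self) -> int:
        return len(self.rows)

    def render(self) -> str:
        if not self.rows:
            return "(no findings recorded)"
        width = max(len(text) for text, _ in self.rows)
        return "\n".join(f"{text.ljust(width)}  {resp}" for text, resp in self.rows)


def new_session(kb: KnowledgeBase) -> Session:
    """Start an empty encounter. Refuses a knowledge base that fails
    validation (the engine's behavior is undefined on a cyclic or dangling
    model)."""
    report = validate_kb(kb)
    if not report.ok:
        first = report.errors[0]
        raise KBIntegrityError(
            f"knowledge base failed validation ({len(report.errors)} errors; "
            f"first: {first.code}: {first.message})"
        )
    return Session(kb=kb, kb_version=kb.version)


def active_findings(session: Session) -> dict[str, str]:
    """Greatest self-consistent subset of the recorded findings.

    Computed by iterated removal: drop every finding whose item is disabled
    under the current candidate set, repeat until stable. Terminates because
    the enabling graph is acyclic and each pass only shrinks the set.
    """
    kb = session.kb
    current = dict(session.findings)
    while True:
        kept = {
            iid: resp
            for iid, resp in current.items()
            if kb.items[iid].enabled_when.evaluate(current)
        }
        if kept == current:
            return kept
        current = kept


def _ordered(kb: KnowledgeBase, item_ids: list[str]) -> list[ItemDefinition]:
    """Contract ordering: interview before examination before synthesis,
    clusters contiguous (by first declaration), declaration order within."""
    decl = {iid: n for n, iid in enumerate(kb.items)}
    cluster_first: dict[str, int] = {}
    for iid in kb.items:
        c = kb.items[iid].cluster
        if c is not None and c not in cluster_first:
            cluster_first[c] = decl[iid]

    def key(iid: str) -> tuple[int, int, int]:
        item = kb.items[iid]
        group = cluster_first[item.cluster] if item.cluster else decl[iid]
        return (_PHASE_RANK[item.phase], group, decl[iid])

    return [kb.items[iid] for iid in sorted(item_ids, key=key)]


def enabled_items(session: Session) -> list[ItemDefinition]:
    """Items currently presented to the clinician, in display order.

    Recomputed from scratch on every call: an item is included iff its
    enabling condition holds against the active findings.
    """
    act = active_findings(session)
    enabled = [
        iid for iid, item in session.kb.items.items() if item.enabled_when.evaluate(act)
    ]
    return _ordered(session.kb, enabled)


def record_finding(session: Session, item_id: str, response: str) -> Session:
    """Record one finding on a currently enabled item."""
    kb = session.kb
    if item_id not in kb.items:
        raise KBIntegrityError(f"unknown item {item_id!r}")
    item = kb.items[item_id]
    if response not in item.response_domain:
        raise ResponseDomainError(
            f"response {response!r} not admissible for item {item_id!r} "
            f"(domain: {list(item.response_domain)})"
        )
    if not item.enabled_when.evaluate(active_findings(session)):
        raise EnablementError(
            f"item {item_id!r} is not enabled for the current findings"
        )
    session.findings[item_id] = response
    session.touch()
    return session


def retract_finding(session: Session, item_id: str) -> Session:
    """Remove a recorded finding; downstream enablement is recomputed by the
    next query (enablement is derived, never stored)."""
    if item_id not in session.findings:
        raise NotFoundError(f"no finding recorded for item {item_id!r}")
    del session.findings[item_id]
    session.touch()
    return session


def summary(session: Session) -> PatientSummary:
    """Patient summary panel: the active findings in display order."""
    act = active_findings(session)
    ordered = _ordered(session.kb, list(act))
    return PatientSummary(rows=tuple((i.text, act[i.item_id]) for i in ordered))


def save_session(session: Session, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(session.to_dict(), indent=2) + "\n", encoding="utf-8"
    )


def load_session(kb: KnowledgeBase, path: str | Path) -> Session:
    """Load a saved encounter; the knowledge-base version must match the one
    the session was written against."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise KBFormatError(f"{path}: not a readable session file: {exc}") from exc
    if not isinstance(doc, dict) or "kb_version" not in doc or "findings" not in doc:
        raise KBFormatError(f"{path}: missing session keys")
    if doc["kb_version"] != kb.version:
        raise VersionMismatchError(
            f"session was saved with KB version {doc['kb_version']!r}, "
            f"loaded KB is {kb.version!r}"
        )
    session = new_session(kb)
    for iid, resp in dict(doc["findings"]).items():
        if iid not in kb.items:
            raise KBIntegrityError(f"{path}: finding references unknown item {iid!r}")
        session.findings[iid] = resp
    session.dx_selections = {k: dict(v) for k, v in doc.get("dx_selections", {}).items()}
    session.treatment_selections = dict(doc.get("treatment_selections", {}))
    session.created = doc.get("created", session.created)
    session.modified = doc.get("modified", session.modified)
    return session
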