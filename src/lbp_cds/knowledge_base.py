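"""Declarative clinical model: items, adaptive enabling rules, diagnoses,
treatments, and patient education, with loading, validation, and census.

The knowledge base is the single source of clinical content. The engine
modules (:mod:`lbp_cds.session`, :mod:`lbp_cds.inference`,
:mod:`lbp_cds.plan`) interpret it but contain no clinical policy of their
own: which items exist, when they are enabled, which findings count toward
which working diagnosis, and which diagnoses may suppress which all live in
the KB file, so clinical review happens on a diffable document rather than
on code.

File dialect: canonical JSON (a YAML file with identical structure is also
accepted). Top-level keys ``version, metadata, items, diagnoses,
treatments, education``; each item may carry an ``enabled_when`` expression
(omitted = always enabled); expressions use the dialect of
:mod:`lbp_cds.expressions`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import networkx as nx
import yaml

from .errors import KBFormatError, KBIntegrityError
from .expressions import TRUE, Expression, parse_expression

__all__ = [
    "ALL_DIAGNOSES",
    "Census",
    "DiagnosisDefinition",
    "EducationMaterial",
    "ItemDefinition",
    "KnowledgeBase",
    "SuppressionEntry",
    "TreatmentRecommendation",
    "ValidationFinding",
    "ValidationReport",
    "default_kb",
    "default_kb_path",
    "kb_census",
    "load_kb",
    "save_kb",
    "validate_kb",
]

PHASES = ("interview", "examination", "synthesis")

#: Sentinel for treatments that apply to every working diagnosis.
ALL_DIAGNOSES = "ALL"

DEFAULT_RESPONSE_DOMAIN = ("present", "absent")
DEFAULT_SCALE_MAX = 5


@dataclass(frozen=True)
class ItemDefinition:
    """One interview/examination/synthesis input item.

    ``enabled_when`` is the item's enabling rule: the item is presented to
    the clinician only while the expression holds against the active
    findings. ``cluster`` groups items that clarify the same working
    diagnosis so they render contiguously.
    """

    item_id: str
    text: str
    phase: str
    cluster: str | None = None
    info: str | None = None
    enabled_when: Expression = TRUE
    response_domain: tuple[str, ...] = DEFAULT_RESPONSE_DOMAIN

    @property
    def always_enabled(self) -> bool:
        return self.enabled_when.is_always_true


@dataclass(frozen=True)
class SuppressionEntry:
    """Declares that a competing diagnosis may suppress this one."""

    competitor: str
    policy: str = "dominance"


@dataclass(frozen=True)
class DiagnosisDefinition:
    """A working diagnosis: trigger rule, counted evidence, display scale.

    ``rule`` decides whether the diagnosis is a candidate at all;
    ``evidence_atoms`` is the ordered list of findings counted toward its
    strength-of-evidence grade (every rule atom must be among them, so
    triggering and counting draw from the same findings). ``suppressors``
    lists competitors that reject this diagnosis when their own evidence is
    strictly stronger.
    """

    dx_id: str
    name: str
    level: str  # "macro" | "micro"
    rule: Expression
    evidence_atoms: tuple[tuple[str, str], ...]
    parent: str | None = None
    scale_max: int = DEFAULT_SCALE_MAX
    suppressors: tuple[SuppressionEntry, ...] = ()
    education_ids: tuple[str, ...] = ()
    graded: bool = True
    source: str = "published"


@dataclass(frozen=True)
class TreatmentRecommendation:
    treatment_id: str
    name: str
    applies_to: tuple[str, ...] | str  # ALL_DIAGNOSES or explicit dx ids
    priority_note: str | None = None

    @property
    def applies_to_all(self) -> bool:
        return self.applies_to == ALL_DIAGNOSES


@dataclass(frozen=True)
class EducationMaterial:
    edu_id: str
    title: str
    body: str
    reading_level_note: str | None = None


@dataclass
class KnowledgeBase:
    """Fully cross-linked clinical model (see module docstring)."""

    version: str
    items: dict[str, ItemDefinition]
    diagnoses: dict[str, DiagnosisDefinition]
    treatments: dict[str, TreatmentRecommendation]
    education: dict[str, EducationMaterial]
    metadata: dict[str, Any] = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def enabling_rules(self) -> dict[str, Expression]:
        """item_id -> enabling condition (exactly one per item)."""
        return {i.item_id: i.enabled_when for i in self.items.values()}

    def item_order(self, item_id: str) -> int:
        return list(self.items).index(item_id)

    def dx_order(self, dx_id: str) -> int:
        return list(self.diagnoses).index(dx_id)

    def enabling_graph(self) -> nx.DiGraph:
        """Directed graph: edge dep -> item when *item*'s enabling condition
        references *dep*. Must be acyclic for the adaptive logic to have a
        fixed point."""
        g = nx.DiGraph()
        g.add_nodes_from(self.items)
        for item in self.items.values():
            for dep, _resp in item.enabled_when.atoms():
                g.add_edge(dep, item.item_id)
        return g

    def treatments_for(self, dx_id: str) -> list[TreatmentRecommendation]:
        """Treatments applicable to one diagnosis, ALL-treatments included."""
        out = []
        for t in self.treatments.values():
            if t.applies_to_all or dx_id in t.applies_to:
                out.append(t)
        return out

    def find_item_by_text(self, fragment: str) -> ItemDefinition:
        """Locate an item whose display text contains *fragment*
        (case-insensitive); convenience for scripting against display labels."""
        frag = fragment.lower()
        hits = [i for i in self.items.values() if frag in i.text.lower()]
        if len(hits) != 1:
            raise KBIntegrityError(
                f"text fragment {fragment!r} matches {len(hits)} items, expected 1"
            )
        return hits[0]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def expr(e: Expression) -> Any:
            return e.to_json()

        items = []
        for i in self.items.values():
            d: dict[str, Any] = {"id": i.item_id, "text": i.text, "phase": i.phase}
            if i.cluster:
                d["cluster"] = i.cluster
            if i.info:
                d["info"] = i.info
            if not i.always_enabled:
                d["enabled_when"] = expr(i.enabled_when)
            if i.response_domain != DEFAULT_RESPONSE_DOMAIN:
                d["response_domain"] = list(i.response_domain)
            items.append(d)
        diagnoses = []
        for x in self.diagnoses.values():
            d = {
                "id": x.dx_id,
                "name": x.name,
                "level": x.level,
                "rule": expr(x.rule),
                "evidence_atoms": [{"item": a, "response": r} for a, r in x.evidence_atoms],
            }
            if x.parent:
                d["parent"] = x.parent
            if x.scale_max != DEFAULT_SCALE_MAX:
                d["scale_max"] = x.scale_max
            if x.suppressors:
                d["suppressors"] = [
                    {"dx": s.competitor, "policy": s.policy} for s in x.suppressors
                ]
            if x.education_ids:
                d["education"] = list(x.education_ids)
            if not x.graded:
                d["graded"] = False
            d["source"] = x.source
            diagnoses.append(d)
        treatments = []
        for t in self.treatments.values():
            d = {"id": t.treatment_id, "name": t.name}
            d["applies_to"] = "ALL" if t.applies_to_all else list(t.applies_to)
            if t.priority_note:
                d["priority_note"] = t.priority_note
            treatments.append(d)
        education = []
        for e in self.education.values():
            d = {"id": e.edu_id, "title": e.title, "body": e.body}
            if e.reading_level_note:
                d["reading_level_note"] = e.reading_level_note
            education.append(d)
        return {
            "version": self.version,
            "metadata": dict(self.metadata),
            "items": items,
            "diagnoses": diagnoses,
            "treatments": treatments,
            "education": education,
        }


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Census:
    """Structural counts by item class and diagnosis level."""

    total_items: int
    interview_always: int
    interview_conditional: int
    exam_always: int
    exam_conditional: int
    synthesis: int
    diagnoses_total: int
    macro: int
    micro: int

    def to_dict(self) -> dict[str, int]:
        return {
            "total_items": self.total_items,
            "interview_always": self.interview_always,
            "interview_conditional": self.interview_conditional,
            "exam_always": self.exam_always,
            "exam_conditional": self.exam_conditional,
            "synthesis": self.synthesis,
            "diagnoses_total": self.diagnoses_total,
            "macro": self.macro,
            "micro": self.micro,
        }


def kb_census(kb: KnowledgeBase) -> Census:
    """Count items by phase x (always vs conditionally enabled) and
    diagnoses by level. Synthesis items form their own class."""
    iv_a = iv_c = ex_a = ex_c = syn = 0
    for item in kb.items.values():
        if item.phase == "synthesis":
            syn += 1
        elif item.phase == "interview":
            if item.always_enabled:
                iv_a += 1
            else:
                iv_c += 1
        else:
            if item.always_enabled:
                ex_a += 1
            else:
                ex_c += 1
    macro = sum(1 for d in kb.diagnoses.values() if d.level == "macro")
    micro = sum(1 for d in kb.diagnoses.values() if d.level == "micro")
    return Census(
        total_items=len(kb.items),
        interview_always=iv_a,
        interview_conditional=iv_c,
        exam_always=ex_a,
        exam_conditional=ex_c,
        synthesis=syn,
        diagnoses_total=len(kb.diagnoses),
        macro=macro,
        micro=micro,
    )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_atom_list(raw: Any, where: str) -> tuple[tuple[str, str], ...]:
    if not isinstance(raw, list):
        raise KBFormatError(f"{where}: expected a list of atoms")
    out = []
    for a in raw:
        if not isinstance(a, dict) or "item" not in a:
            raise KBFormatError(f"{where}: each evidence atom needs an 'item' key")
        out.append((str(a["item"]), str(a.get("response", "present"))))
    return tuple(out)


def _build_kb(doc: Any, origin: str) -> KnowledgeBase:
    if not isinstance(doc, dict):
        raise KBFormatError(f"{origin}: top level must be a mapping")
    for key in ("version", "items", "diagnoses", "treatments", "education"):
        if key not in doc:
            raise KBFormatError(f"{origin}: missing top-level key {key!r}")

    items: dict[str, ItemDefinition] = {}
    for raw in doc["items"]:
        iid = str(raw["id"])
        if iid in items:
            raise KBFormatError(f"{origin}: duplicate item id {iid!r}")
        phase = raw.get("phase", "interview")
        if phase not in PHASES:
            raise KBFormatError(f"{origin}: item {iid!r} has unknown phase {phase!r}")
        cond = (
            parse_expression(raw["enabled_when"], f"item {iid} enabled_when")
            if "enabled_when" in raw
            else TRUE
        )
        items[iid] = ItemDefinition(
            item_id=iid,
            text=str(raw["text"]),
            phase=phase,
            cluster=raw.get("cluster"),
            info=raw.get("info"),
            enabled_when=cond,
            response_domain=tuple(raw.get("response_domain", DEFAULT_RESPONSE_DOMAIN)),
        )

    diagnoses: dict[str, DiagnosisDefinition] = {}
    for raw in doc["diagnoses"]:
        did = str(raw["id"])
        if did in diagnoses:
            raise KBFormatError(f"{origin}: duplicate diagnosis id {did!r}")
        diagnoses[did] = DiagnosisDefinition(
            dx_id=did,
            name=str(raw["name"]),
            level=str(raw.get("level", "micro")),
            parent=raw.get("parent"),
            rule=parse_expression(raw["rule"], f"diagnosis {did} rule"),
            evidence_atoms=_parse_atom_list(
                raw.get("evidence_atoms", []), f"diagnosis {did} evidence_atoms"
            ),
            scale_max=int(raw.get("scale_max", DEFAULT_SCALE_MAX)),
            suppressors=tuple(
                SuppressionEntry(str(s["dx"]), str(s.get("policy", "dominance")))
                for s in raw.get("suppressors", [])
            ),
            education_ids=tuple(raw.get("education", [])),
            graded=bool(raw.get("graded", True)),
            source=str(raw.get("source", "published")),
        )

    treatments: dict[str, TreatmentRecommendation] = {}
    for raw in doc["treatments"]:
        tid = str(raw["id"])
        if tid in treatments:
            raise KBFormatError(f"{origin}: duplicate treatment id {tid!r}")
        applies = raw.get("applies_to", ALL_DIAGNOSES)
        if applies == ALL_DIAGNOSES:
            applies_to: tuple[str, ...] | str = ALL_DIAGNOSES
        elif isinstance(applies, list) and applies:
            applies_to = tuple(str(d) for d in applies)
        else:
            raise KBFormatError(
                f"{origin}: treatment {tid!r} applies_to must be 'ALL' or a "
                "non-empty list of diagnosis ids"
            )
        treatments[tid] = TreatmentRecommendation(
            treatment_id=tid,
            name=str(raw["name"]),
            applies_to=applies_to,
            priority_note=raw.get("priority_note"),
        )

    education: dict[str, EducationMaterial] = {}
    for raw in doc["education"]:
        eid = str(raw["id"])
        if eid in education:
            raise KBFormatError(f"{origin}: duplicate education id {eid!r}")
        education[eid] = EducationMaterial(
            edu_id=eid,
            title=str(raw["title"]),
            body=str(raw.get("body", "")),
            reading_level_note=raw.get("reading_level_note"),
        )

    kb = KnowledgeBase(
        version=str(doc["version"]),
        items=items,
        diagnoses=diagnoses,
        treatments=treatments,
        education=education,
        metadata=dict(doc.get("metadata", {})),
    )
    _check_references(kb, origin)
    return kb


def _check_references(kb: KnowledgeBase, origin: str) -> None:
    """Hard integrity gate at load time: every cross-reference must resolve."""

    def need_item(iid: str, where: str) -> None:
        if iid not in kb.items:
            raise KBIntegrityError(f"{origin}: {where} references unknown item {iid!r}")

    for item in kb.items.values():
        for dep, _ in item.enabled_when.atoms():
            need_item(dep, f"item {item.item_id!r} enabling condition")
    for dx in kb.diagnoses.values():
        for iid, _ in dx.rule.atoms():
            need_item(iid, f"diagnosis {dx.dx_id!r} rule")
        for iid, _ in dx.evidence_atoms:
            need_item(iid, f"diagnosis {dx.dx_id!r} evidence")
        for sup in dx.suppressors:
            if sup.competitor not in kb.diagnoses:
                raise KBIntegrityError(
                    f"{origin}: diagnosis {dx.dx_id!r} suppressor references "
                    f"unknown diagnosis {sup.competitor!r}"
                )
        for eid in dx.education_ids:
            if eid not in kb.education:
                raise KBIntegrityError(
                    f"{origin}: diagnosis {dx.dx_id!r} references unknown "
                    f"education material {eid!r}"
                )
    for t in kb.treatments.values():
        if not t.applies_to_all:
            for did in t.applies_to:
                if did not in kb.diagnoses:
                    raise KBIntegrityError(
                        f"{origin}: treatment {t.treatment_id!r} applies to "
                        f"unknown diagnosis {did!r}"
                    )


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and cross-link a knowledge base from a JSON or YAML file.

    Raises :class:`KBFormatError` on parse failure and
    :class:`KBIntegrityError` on a dangling reference (the message names the
    missing id). Deeper structural findings (cycles, unsatisfiable rules,
    missing parents...) are reported by :func:`validate_kb`, which still
    works on a loaded-but-imperfect KB.
    """
    path = Path(path)
    if not path.exists():
        raise KBFormatError(f"knowledge base file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise KBFormatError(f"{path}: YAML parse error: {exc}") from exc
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise KBFormatError(
                f"{path}: JSON parse error at line {exc.lineno}: {exc.msg}"
            ) from exc
    return _build_kb(doc, str(path))


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Serialize to canonical JSON (stable key order, 2-space indent)."""
    Path(path).write_text(
        json.dumps(kb.to_dict(), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def default_kb_path() -> Path:
    """Path of the knowledge base shipped with the package."""
    return Path(__file__).parent / "data" / "default_kb.json"


def default_kb() -> KnowledgeBase:
    """Load the shipped default low back pain knowledge base."""
    return load_kb(default_kb_path())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    code: str
    message: str

    def to_dict(self) -> dict[str, str]:
        return {"severity": self.severity, "code": self.code, "message": self.message}


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(f.to_dict()) for f in self.findings)


def _expression_satisfiable(
    expr: Expression, kb: KnowledgeBase, limit: int = 4096
) -> bool | None:
    """Brute-force satisfiability over the referenced items' response domains
    plus 'unanswered'. Returns None when the search space exceeds *limit*
    (reported as unknown rather than guessed)."""
    if expr.is_always_true:
        return True
    item_ids = sorted({iid for iid, _ in expr.atoms()})
    domains = []
    for iid in item_ids:
        dom: list[str | None] = [None]
        if iid in kb.items:
            dom += list(kb.items[iid].response_domain)
        domains.append(dom)
    space = 1
    for d in domains:
        space *= len(d)
        if space > limit:
            return None
    for combo in itertools.product(*domains):
        findings = {iid: r for iid, r in zip(item_ids, combo) if r is not None}
        if expr.evaluate(findings):
            return True
    return False


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Structural validation beyond load-time reference resolution.

    Pure: the same knowledge base always yields the same report. Checks, in
    addition to the load-time invariants it re-asserts:

    * enabling-graph acyclicity (cycles reported with the member items);
    * items whose enabling condition can never be satisfied (unreachable);
    * diagnoses whose rule can never trigger;
    * micro diagnoses without a (macro) parent, macros with one;
    * rule atoms missing from ``evidence_atoms``;
    * atoms requiring a response outside the item's response domain;
    * orphan education/treatments and diagnoses left without any treatment.
    """
    report = ValidationReport()

    def err(code: str, message: str) -> None:
        report.findings.append(ValidationFinding("error", code, message))

    def warn(code: str, message: str) -> None:
        report.findings.append(ValidationFinding("warning", code, message))

    # enabling-graph cycles
    graph = kb.enabling_graph()
    try:
        cycles = list(nx.simple_cycles(graph))
    except nx.NetworkXError:  # pragma: no cover - defensive
        cycles = []
    for cyc in sorted(cycles):
        err("ENABLING_CYCLE", "enabling cycle among items: " + ", ".join(sorted(cyc)))

    # atom responses within domains (items + diagnosis rules/evidence)
    def check_domain(atoms: Iterable[tuple[str, str]], where: str) -> None:
        for iid, resp in atoms:
            item = kb.items.get(iid)
            if item is not None and resp not in item.response_domain:
                err(
                    "RESPONSE_OUT_OF_DOMAIN",
                    f"{where} requires {iid!r}={resp!r} but the item admits "
                    f"{list(item.response_domain)}",
                )

    for item in kb.items.values():
        check_domain(item.enabled_when.atoms(), f"item {item.item_id!r} enabling condition")
    for dx in kb.diagnoses.values():
        check_domain(dx.rule.atoms(), f"diagnosis {dx.dx_id!r} rule")
        check_domain(dx.evidence_atoms, f"diagnosis {dx.dx_id!r} evidence")

    # unreachable items / untriggerable rules (skipped when a cycle exists:
    # reachability is ill-defined without a fixed point)
    if not cycles:
        for item in kb.items.values():
            sat = _expression_satisfiable(item.enabled_when, kb)
            if sat is False:
                err(
                    "UNREACHABLE_ITEM",
                    f"item {item.item_id!r} can never be enabled "
                    "(enabling condition unsatisfiable)",
                )
            elif sat is None:
                warn(
                    "SATISFIABILITY_UNCHECKED",
                    f"item {item.item_id!r} enabling condition too large to check",
                )
    for dx in kb.diagnoses.values():
        sat = _expression_satisfiable(dx.rule, kb)
        if sat is False:
            err("UNTRIGGERABLE_RULE", f"diagnosis {dx.dx_id!r} rule can never trigger")
        elif sat is None:
            warn(
                "SATISFIABILITY_UNCHECKED",
                f"diagnosis {dx.dx_id!r} rule too large to check",
            )

    # hierarchy
    for dx in kb.diagnoses.values():
        if dx.level == "micro":
            if not dx.parent:
                err("MISSING_PARENT", f"micro diagnosis {dx.dx_id!r} has no parent")
            elif dx.parent not in kb.diagnoses:
                err(
                    "MISSING_PARENT",
                    f"micro diagnosis {dx.dx_id!r} names unknown parent {dx.parent!r}",
                )
            elif kb.diagnoses[dx.parent].level != "macro":
                err(
                    "BAD_PARENT_LEVEL",
                    f"micro diagnosis {dx.dx_id!r} parent {dx.parent!r} is not macro",
                )
        elif dx.level == "macro":
            if dx.parent:
                err("MACRO_WITH_PARENT", f"macro diagnosis {dx.dx_id!r} has a parent")
        else:
            err("BAD_LEVEL", f"diagnosis {dx.dx_id!r} has unknown level {dx.level!r}")
        if dx.scale_max < 1:
            err("BAD_SCALE_MAX", f"diagnosis {dx.dx_id!r} scale_max must be >= 1")
        missing = dx.rule.atoms() - set(dx.evidence_atoms)
        for iid, resp in sorted(missing):
            err(
                "RULE_ATOM_NOT_IN_EVIDENCE",
                f"diagnosis {dx.dx_id!r} rule atom ({iid!r}, {resp!r}) is not "
                "listed among its evidence atoms",
            )

    # orphans / coverage
    referenced_edu = {e for dx in kb.diagnoses.values() for e in dx.education_ids}
    for eid in kb.education:
        if eid not in referenced_edu:
            err("ORPHAN_EDUCATION", f"education material {eid!r} referenced by no diagnosis")
    has_all = any(t.applies_to_all for t in kb.treatments.values())
    for dx in kb.diagnoses.values():
        if not has_all and not kb.treatments_for(dx.dx_id):
            err("NO_TREATMENT", f"diagnosis {dx.dx_id!r} has no applicable treatment")
    return report
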