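"""Clinical scenario fixtures and a seeded synthetic-encounter generator.

Four fictional usability-test scenarios ship with the package — acute
nociceptive pain, chronic nociceptive pain, chronic nociceptive pain with
symptoms of neurogenic claudication, and radicular pain — plus a fifth
multifactorial scenario in which the model rejects piriformis syndrome in
favor of neurogenic claudication. The published study describes these
vignettes only by condition label; the findings scripts here are authored
against the default knowledge base to satisfy the corresponding rules and
are marked reconstructed in their narratives. What the fixtures pin down is
rank and suppression behavior, not vignette prose.

The random generator walks the enabling graph in topological order and
answers each item that is enabled at that point, so every generated script
replays on a fresh session without enablement errors by construction. The
default answer probability (0.3 present) yields sparse mixed encounters;
targeting a diagnosis raises its evidence atoms to 0.9 present so the
target triggers in the large majority of draws. Both values are arbitrary
exercise settings, configurable per call.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import KBFormatError, NotFoundError
from .knowledge_base import KnowledgeBase
from .session import Session, new_session, record_finding

__all__ = [
    "Scenario",
    "builtin_scenarios",
    "generate_random_scenario",
    "load_scenario",
    "multifactorial_scenario",
    "replay_scenario",
    "scenario_by_name",
]

_SCENARIO_DIR = Path(__file__).parent / "data" / "scenarios"

#: The four usability-test scenarios, in the order the study lists them.
BUILTIN_ORDER = (
    "acute_nociceptive",
    "chronic_nociceptive",
    "nociceptive_with_claudication",
    "radicular",
)


@dataclass(frozen=True)
class Scenario:
    """A replayable encounter script with its expected inference outcome."""

    scenario_id: str
    title: str
    narrative: str
    findings_script: tuple[tuple[str, str], ...]
    expected_top_dx: tuple[str, ...] = ()
    expected_suppressed: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "title": self.title,
            "narrative": self.narrative,
            "findings_script": [list(pair) for pair in self.findings_script],
            "expected_top_dx": list(self.expected_top_dx),
            "expected_suppressed": list(self.expected_suppressed),
        }


def load_scenario(path: str | Path) -> Scenario:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise KBFormatError(f"{path}: not a readable scenario file: {exc}") from exc
    return Scenario(
        scenario_id=str(doc["scenario_id"]),
        title=str(doc.get("title", doc["scenario_id"])),
        narrative=str(doc.get("narrative", "")),
        findings_script=tuple((str(i), str(r)) for i, r in doc["findings_script"]),
        expected_top_dx=tuple(doc.get("expected_top_dx", [])),
        expected_suppressed=tuple(doc.get("expected_suppressed", [])),
    )


def builtin_scenarios() -> list[Scenario]:
    """The four shipped usability-test scenarios (exactly four)."""
    return [load_scenario(_SCENARIO_DIR / f"{name}.json") for name in BUILTIN_ORDER]


def multifactorial_scenario() -> Scenario:
    """The complex multifactorial fixture: neurogenic claudication with
    overlying nociplastic pain; piriformis syndrome triggered but rejected."""
    return load_scenario(_SCENARIO_DIR / "multifactorial.json")


def scenario_by_name(name: str) -> Scenario:
    """Look up a shipped scenario by id (the four builtins or
    ``multifactorial``)."""
    for scenario in builtin_scenarios() + [multifactorial_scenario()]:
        if scenario.scenario_id == name:
            return scenario
    raise NotFoundError(f"no shipped scenario named {name!r}")


def replay_scenario(kb: KnowledgeBase, scenario: Scenario) -> Session:
    """Replay a findings script on a fresh session. Raises
    :class:`~lbp_cds.errors.EnablementError` if the script answers an item
    before its enabling condition holds — shipped and generated scenarios
    never do."""
    session = new_session(kb)
    for item_id, response in scenario.findings_script:
        record_finding(session, item_id, response)
    return session


def generate_random_scenario(
    kb: KnowledgeBase,
    seed: int,
    target_dx: str | None = None,
    p_present: float = 0.3,
    p_target: float = 0.9,
) -> Scenario:
    """Generate a deterministic synthetic encounter.

    Items are visited in topological order of the enabling graph (ties by
    knowledge-base declaration order); each item enabled at its turn is
    answered ``present`` with probability *p_present* and ``absent``
    otherwise. When *target_dx* is given, that diagnosis's evidence atoms
    are instead answered their required response with probability
    *p_target*, which makes the target trigger with probability
    ``1 - (1 - p_target)^k`` for a k-way OR rule.
    """
    if target_dx is not None and target_dx not in kb.diagnoses:
        raise NotFoundError(f"unknown diagnosis {target_dx!r}")
    rng = random.Random(seed)
    target_atoms: dict[str, str] = {}
    if target_dx is not None:
        target_atoms = {iid: resp for iid, resp in kb.diagnoses[target_dx].evidence_atoms}

    decl = {iid: n for n, iid in enumerate(kb.items)}
    order = list(
        nx.lexicographical_topological_sort(kb.enabling_graph(), key=decl.get)
    )
    findings: dict[str, str] = {}
    script: list[tuple[str, str]] = []
    for item_id in order:
        item = kb.items[item_id]
        if not item.enabled_when.evaluate(findings):
            continue
        if item_id in target_atoms:
            wanted = target_atoms[item_id]
            other = [r for r in item.response_domain if r != wanted]
            if rng.random() < p_target or not other:
                response = wanted
            else:
                response = rng.choice(other)
        else:
            if rng.random() < p_present and "present" in item.response_domain:
                response = "present"
            else:
                fallback = [r for r in item.response_domain if r != "present"]
                response = fallback[0] if fallback else item.response_domain[0]
        findings[item_id] = response
        script.append((item_id, response))

    suffix = f", targeting {target_dx}" if target_dx else ""
    return Scenario(
        scenario_id=f"random_{seed}" + (f"_{target_dx}" if target_dx else ""),
        title=f"Synthetic encounter (seed {seed}{suffix})",
        narrative=(
            "Synthetic encounter generated by walking the enabling graph in "
            f"topological order with seed {seed}{suffix}."
        ),
        findings_script=tuple(script),
    )
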