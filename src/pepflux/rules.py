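"""Declarative protease cleavage-rule grammar.

A :class:`CleavageRuleSet` describes an enzyme's specificity as positional
constraints over the P4..P4' context window around a peptide bond (P1 is the
residue on the N-terminal side of the scissile bond, P1' on the C-terminal
side).  A bond is cleavable when at least one ``license`` rule matches and no
``veto`` rule matches; vetoes take precedence.

Terminus semantics follow the PeptideCutter convention: a positive
membership constraint (``in``) fails at positions beyond the chain, while a
negative constraint (``not_in``) is vacuously satisfied there.  In
consequence a veto such as "P3 in {H,K,R}" cannot fire off the end of the
chain, and e.g. a C-terminal Leu at the final bond still licenses cleavage.

Rule sets are stored as YAML documents (see ``pepflux/data/enzymes.yaml``);
two pepsin variants are packaged, mirroring the published Keil tables:
``pepsin-ph1.3`` (hydrophobic P1/P1' = F, L) and ``pepsin-ph2`` (F, L, W, Y).
The package default for peptic digests is ``pepsin-ph2``, the variant that
reproduces the expected 147 cleavage sites on the bundled mature BSA chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

#: Supported window positions and their residue offsets relative to bond i
#: (bond i joins residues i and i+1, 1-based).
POSITION_OFFSETS = {
    "P4": -3,
    "P3": -2,
    "P2": -1,
    "P1": 0,
    "P1'": 1,
    "P2'": 2,
    "P3'": 3,
    "P4'": 4,
}

#: Default rule set used for peptic digests throughout the package.
DEFAULT_ENZYME = "pepsin-ph2"


class RuleError(ValueError):
    """Raised for malformed rule documents."""


@dataclass(frozen=True)
class PositionConstraint:
    """A constraint on one window position.

    Exactly one of *allowed* / *blocked* is set.  *allowed* requires the
    position to exist and hold one of the listed residues; *blocked* is
    satisfied when the position is beyond the chain or holds none of them.
    """

    position: str
    allowed: frozenset[str] | None = None
    blocked: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.position not in POSITION_OFFSETS:
            raise RuleError(
                f"unknown position {self.position!r}; use one of "
                f"{sorted(POSITION_OFFSETS)}"
            )
        if (self.allowed is None) == (self.blocked is None):
            raise RuleError("constraint needs exactly one of in/not_in")

    def satisfied(self, residue: str | None) -> bool:
        if self.allowed is not None:
            return residue is not None and residue in self.allowed
        return residue is None or residue not in self.blocked


@dataclass(frozen=True)
class CleavageRule:
    """One license or veto rule: a conjunction of positional constraints."""

    action: str  # "license" | "veto"
    constraints: tuple[PositionConstraint, ...]

    def __post_init__(self) -> None:
        if self.action not in ("license", "veto"):
            raise RuleError(f"rule action must be license or veto, got {self.action!r}")
        if not self.constraints:
            raise RuleError("a rule needs at least one positional constraint")

    def matches(self, residue_at) -> bool:
        """Evaluate against ``residue_at(offset) -> str | None``."""
        return all(
            c.satisfied(residue_at(POSITION_OFFSETS[c.position]))
            for c in self.constraints
        )


@dataclass(frozen=True)
class CleavageRuleSet:
    """An enzyme variant's complete specificity description."""

    enzyme: str
    variant: str
    rules: tuple[CleavageRule, ...]

    def __post_init__(self) -> None:
        if not any(r.action == "license" for r in self.rules):
            raise RuleError("rule set has no license rules; nothing could ever cleave")

    @property
    def licenses(self) -> tuple[CleavageRule, ...]:
        return tuple(r for r in self.rules if r.action == "license")

    @property
    def vetoes(self) -> tuple[CleavageRule, ...]:
        return tuple(r for r in self.rules if r.action == "veto")

    @property
    def name(self) -> str:
        return f"{self.enzyme} ({self.variant})"


def _parse_constraint(position: str, spec: dict) -> PositionConstraint:
    if not isinstance(spec, dict) or not set(spec) <= {"in", "not_in"}:
        raise RuleError(f"constraint at {position} must be {{in: [...]}} or {{not_in: [...]}}")
    if "in" in spec and "not_in" in spec:
        raise RuleError(f"constraint at {position} mixes in/not_in")
    if "in" in spec:
        return PositionConstraint(position, allowed=frozenset(spec["in"]))
    return PositionConstraint(position, blocked=frozenset(spec["not_in"]))


def rule_set_from_dict(doc: dict) -> CleavageRuleSet:
    """Build a rule set from a parsed YAML/JSON document."""
    rules = []
    for entry in doc.get("rules", []):
        constraints = tuple(
            _parse_constraint(pos, spec) for pos, spec in entry["where"].items()
        )
        rules.append(CleavageRule(action=entry["action"], constraints=constraints))
    return CleavageRuleSet(
        enzyme=doc.get("enzyme", "custom"),
        variant=doc.get("variant", ""),
        rules=tuple(rules),
    )


def _packaged_registry() -> dict:
    ref = resources.files("pepflux.data").joinpath("enzymes.yaml")
    return yaml.safe_load(ref.read_text())


def available_enzymes() -> list[str]:
    """Names of the packaged rule sets."""
    return sorted(_packaged_registry())


def load_rule_set(name_or_path: str = DEFAULT_ENZYME) -> CleavageRuleSet:
    """Load a packaged rule set by name, or a custom one from a YAML file.

    Packaged names: ``pepsin-ph2`` (default; alias ``pepsin``) and
    ``pepsin-ph1.3``.
    """
    registry = _packaged_registry()
    name = DEFAULT_ENZYME if name_or_path == "pepsin" else name_or_path
    if name in registry:
        return rule_set_from_dict(registry[name])
    path = Path(name_or_path)
    if path.exists():
        doc = yaml.safe_load(path.read_text())
        if isinstance(doc, dict) and "rules" not in doc and len(doc) == 1:
            doc = next(iter(doc.values()))
        return rule_set_from_dict(doc)
    raise RuleError(
        f"unknown enzyme {name_or_path!r}; packaged: {available_enzymes()}"
    )
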