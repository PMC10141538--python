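"""Phase I/II biotransformation rules and the metabolite enumeration engine.

A compound is described at moiety granularity: its elemental composition
plus a structural inventory (scaffold class, N-alkyl side chain, labile
groups). Biotransformations are named composition deltas gated by that
inventory — e.g. dihydrodiol formation needs a carbon-carbon double bond,
oxidative defluorination needs a fluorine. Composing rules breadth-first
up to a depth cap yields the candidate metabolite space that the annotator
matches against observed LC-HRMS features.
"""

from __future__ import annotations

import csv
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources

from .chem import (
    MONOISOTOPIC_MASS,
    ElementalComposition,
    monoisotopic_mass,
    parse_formula,
    protonated_mz,
)

__all__ = [
    "Scaffold",
    "Compound",
    "BiotransformationRule",
    "MetaboliteCandidate",
    "rule_catalog",
    "rule_delta_mass",
    "apply_rule",
    "enumerate_metabolites",
    "load_compounds",
    "get_compound",
]


class Scaffold(str, Enum):
    """The two core classes handled by the pipeline."""

    INDAZOLE_CARBOXAMIDE = "indazole-3-carboxamide"
    ISATIN_ACYL_HYDRAZONE = "isatin-acyl-hydrazone"


# Structural features tracked in a candidate's inventory. Counts, not
# booleans: hydroxyls accumulate across oxidation steps.
_FEATURES = (
    "side_chain",
    "alkene",
    "fluorine",
    "terminal_amide",
    "methyl_ester",
    "benzoyl",
    "hydroxyl",
    "carboxyl",
    "ketone",
)


@dataclass(frozen=True)
class Compound:
    """A parent drug: composition plus the structural inventory gating rules.

    ``side_chain_loss`` is the alkene-equivalent composition removed by
    N-dealkylation (e.g. C4H8 for an N-butyl chain).
    """

    name: str
    composition: ElementalComposition
    scaffold: Scaffold
    side_chain_kind: str  # alkyl | alkenyl | fluoroalkyl
    side_chain_loss: ElementalComposition
    has_terminal_amide: bool = False
    has_methyl_ester: bool = False
    has_fluorine: bool = False
    has_alkene: bool = False
    has_benzoyl: bool = False

    def __post_init__(self) -> None:
        if self.side_chain_kind not in ("alkyl", "alkenyl", "fluoroalkyl"):
            raise ValueError(f"unknown side-chain kind {self.side_chain_kind!r}")
        if self.has_fluorine != (self.composition["F"] >= 1):
            raise ValueError(f"{self.name}: fluorine flag inconsistent with composition")
        # the N-dealkylation loss must be subtractable from the molecule
        self.composition - self.side_chain_loss

    @property
    def mz(self) -> float:
        """Theoretical [M+H]+ of the parent."""
        return protonated_mz(self.composition)

    def initial_features(self) -> Mapping[str, int]:
        return {
            "side_chain": 1,
            "alkene": int(self.has_alkene),
            "fluorine": int(self.has_fluorine),
            "terminal_amide": int(self.has_terminal_amide),
            "methyl_ester": int(self.has_methyl_ester),
            "benzoyl": int(self.has_benzoyl),
            "hydroxyl": 0,
            "carboxyl": 0,
            "ketone": 0,
        }


@dataclass(frozen=True)
class BiotransformationRule:
    """A named composition delta with structural applicability gating.

    ``delta`` is a signed element-count change; ``None`` marks the
    parent-specific N-dealkylation loss resolved from the compound
    inventory at application time. ``requires_all`` / ``requires_any``
    are inventory features that must be present; ``consumes`` and
    ``produces`` update the inventory. ``terminal`` rules (conjugations)
    may not be followed by further steps.
    """

    id: str
    name: str
    delta: Mapping[str, int] | None
    phase: str = "I"
    requires_all: tuple[str, ...] = ()
    requires_any: tuple[str, ...] = ()
    consumes: tuple[str, ...] = ()
    produces: tuple[str, ...] = ()
    max_multiplicity: int = 1
    terminal: bool = False
    provisional: bool = False


def rule_catalog(include_provisional: bool = False) -> tuple[BiotransformationRule, ...]:
    """The fixed catalog of phase I/II biotransformations.

    Eleven rules cover the observed chemistry of both scaffold classes:
    hydroxylation (+O, up to trihydroxylation), dehydrogenation (-H2),
    alkene hydrogenation (+H2), ketone formation (+O -H2), carboxylation
    (+O2 -H2), dihydrodiol formation (+H2O2 across a double bond), terminal
    amide and methyl-ester hydrolysis, N-dealkylation (parent-specific
    chain loss), oxidative defluorination (C-F -> C-OH), and phase II
    glucuronidation (+C6H8O6 onto a free hydroxyl or carboxyl).

    ``include_provisional`` appends a benzamide-bond hydrolysis rule
    (-C7H4O, loss of the benzoyl group with H retention) for the isatin
    acyl hydrazone scaffold; its product compositions are not confirmed
    by printed m/z values, hence the flag.
    """
    catalog = (
        BiotransformationRule(
            id="hydroxylation", name="hydroxylation", delta={"O": 1},
            produces=("hydroxyl",), max_multiplicity=3,
        ),
        BiotransformationRule(
            id="dehydrogenation", name="dehydrogenation", delta={"H": -2},
            max_multiplicity=2,
        ),
        BiotransformationRule(
            id="hydrogenation", name="alkene hydrogenation", delta={"H": 2},
            requires_all=("alkene",), consumes=("alkene",),
        ),
        BiotransformationRule(
            id="ketone", name="oxidation to ketone", delta={"O": 1, "H": -2},
            produces=("ketone",),
        ),
        BiotransformationRule(
            id="carboxylation", name="oxidation to carboxylate",
            delta={"O": 2, "H": -2}, produces=("carboxyl",),
        ),
        BiotransformationRule(
            id="dihydrodiol", name="dihydrodiol formation",
            delta={"H": 2, "O": 2}, requires_all=("alkene",),
            consumes=("alkene",), produces=("hydroxyl", "hydroxyl"),
        ),
        BiotransformationRule(
            id="amide_hydrolysis", name="terminal amide hydrolysis",
            delta={"N": -1, "H": -1, "O": 1}, requires_all=("terminal_amide",),
            consumes=("terminal_amide",), produces=("carboxyl",),
        ),
        BiotransformationRule(
            id="ester_hydrolysis", name="methyl ester hydrolysis",
            delta={"C": -1, "H": -2}, requires_all=("methyl_ester",),
            consumes=("methyl_ester",), produces=("carboxyl",),
        ),
        BiotransformationRule(
            id="N_dealkylation", name="N-dealkylation", delta=None,
            requires_all=("side_chain",), consumes=("side_chain",),
        ),
        BiotransformationRule(
            id="oxidative_defluorination", name="oxidative defluorination",
            delta={"F": -1, "O": 1, "H": 1}, requires_all=("fluorine",),
            consumes=("fluorine",), produces=("hydroxyl",),
        ),
        BiotransformationRule(
            id="glucuronidation", name="glucuronidation",
            delta={"C": 6, "H": 8, "O": 6}, phase="II",
            requires_any=("hydroxyl", "carboxyl"), terminal=True,
        ),
    )
    if include_provisional:
        catalog = catalog + (
            BiotransformationRule(
                id="benzoyl_hydrolysis", name="benzamide-bond hydrolysis",
                delta={"C": -7, "H": -4, "O": -1}, requires_all=("benzoyl",),
                consumes=("benzoyl",), provisional=True,
            ),
        )
    return catalog


def rule_delta_mass(rule_id: str, parent: Compound) -> float:
    """Monoisotopic mass shift of one application of a rule to this parent."""
    rule = _catalog_by_id()[rule_id]
    if rule.delta is None:  # N-dealkylation: parent-specific chain loss
        return -monoisotopic_mass(parent.side_chain_loss)
    return sum(count * MONOISOTOPIC_MASS[element] for element, count in rule.delta.items())


_CATALOG_BY_ID: dict[str, BiotransformationRule] | None = None


def _catalog_by_id() -> dict[str, BiotransformationRule]:
    global _CATALOG_BY_ID
    if _CATALOG_BY_ID is None:
        _CATALOG_BY_ID = {r.id: r for r in rule_catalog(include_provisional=True)}
    return _CATALOG_BY_ID


@dataclass(frozen=True)
class MetaboliteCandidate:
    """A parent plus an ordered rule path, with the resulting composition.

    ``steps`` is the application order (breadth-first canonical); equality
    of candidates for deduplication purposes is (composition, step
    multiset), exposed as :attr:`key`.
    """

    parent: Compound
    steps: tuple[str, ...]
    composition: ElementalComposition
    features: Mapping[str, int] = field(repr=False, default_factory=dict)

    @property
    def mz(self) -> float:
        return protonated_mz(self.composition)

    @property
    def depth(self) -> int:
        return len(self.steps)

    @property
    def key(self) -> tuple:
        return (self.composition, tuple(sorted(Counter(self.steps).items())))

    @property
    def rule_path(self) -> str:
        """Compact ``rule(xN)`` display string, e.g. ``hydroxylation+glucuronidation``."""
        counts = Counter(self.steps)
        parts = []
        for rid in sorted(counts):
            parts.append(rid if counts[rid] == 1 else f"{rid}x{counts[rid]}")
        return "+".join(parts)

    def step_counts(self) -> Counter:
        return Counter(self.steps)


def root_candidate(parent: Compound) -> MetaboliteCandidate:
    """Depth-0 candidate representing the unchanged parent."""
    return MetaboliteCandidate(
        parent=parent, steps=(), composition=parent.composition,
        features=parent.initial_features(),
    )


def apply_rule(
    cand: MetaboliteCandidate, rule: BiotransformationRule
) -> MetaboliteCandidate | None:
    """Apply a rule to a candidate; returns ``None`` when inapplicable.

    Inapplicability covers: a terminal (phase II) step already present,
    the rule's multiplicity cap reached, a missing required structural
    feature, or a delta that would drive an element count negative.
    """
    if any(_catalog_by_id()[s].terminal for s in cand.steps):
        return None
    if Counter(cand.steps)[rule.id] >= rule.max_multiplicity:
        return None
    features = dict(cand.features) if cand.features else dict(
        cand.parent.initial_features()
    )
    if any(features.get(f, 0) < 1 for f in rule.requires_all):
        return None
    if rule.requires_any and not any(features.get(f, 0) >= 1 for f in rule.requires_any):
        return None
    delta = rule.delta
    if delta is None:
        delta = {e: -c for e, c in cand.parent.side_chain_loss.items()}
    try:
        composition = cand.composition.shift(delta)
    except ValueError:
        return None
    for f in rule.consumes:
        features[f] = max(0, features.get(f, 0) - 1)
    # removing the chain also removes anything riding on it
    if rule.id == "N_dealkylation":
        if cand.parent.side_chain_kind == "alkenyl":
            features["alkene"] = 0
        if cand.parent.side_chain_kind == "fluoroalkyl":
            features["fluorine"] = 0
    for f in rule.produces:
        features[f] = features.get(f, 0) + 1
    return MetaboliteCandidate(
        parent=cand.parent, steps=cand.steps + (rule.id,),
        composition=composition, features=features,
    )


def enumerate_metabolites(
    parent: Compound,
    catalog: Sequence[BiotransformationRule] | None = None,
    max_depth: int = 4,
    caps: Mapping[str, int] | None = None,
) -> list[MetaboliteCandidate]:
    """Breadth-first closure of rule application up to ``max_depth`` steps.

    Candidates are deduplicated by (composition, rule multiset); the
    retained path is the minimal-depth one reached first. The parent
    itself (depth 0) is not included. Result is sorted by
    (depth, m/z, rule path) for determinism.

    ``caps`` optionally overrides per-rule multiplicity caps by rule id.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if catalog is None:
        catalog = rule_catalog()
    if caps:
        catalog = [
            replace(r, max_multiplicity=caps.get(r.id, r.max_multiplicity))
            for r in catalog
        ]
    seen: set = set()
    results: list[MetaboliteCandidate] = []
    frontier = [root_candidate(parent)]
    seen.add(frontier[0].key)
    for _ in range(max_depth):
        next_frontier: list[MetaboliteCandidate] = []
        for cand in frontier:
            for rule in catalog:
                new = apply_rule(cand, rule)
                if new is None or new.key in seen:
                    continue
                seen.add(new.key)
                next_frontier.append(new)
                results.append(new)
        frontier = next_frontier
        if not frontier:
            break
    results.sort(key=lambda c: (c.depth, c.mz, c.steps))
    return results


# ---------------------------------------------------------------------------
# Compound registry

_FLAG_FIELDS = {
    "terminal_amide": "has_terminal_amide",
    "methyl_ester": "has_methyl_ester",
    "fluorine": "has_fluorine",
    "alkene": "has_alkene",
    "benzoyl": "has_benzoyl",
}


def _read_registry(path=None) -> tuple[dict[str, Compound], dict[str, str]]:
    if path is None:
        source = resources.files("phasemet").joinpath("data/compounds.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    registry: dict[str, Compound] = {}
    aliases: dict[str, str] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        flags = {
            _FLAG_FIELDS[f]: True
            for f in (row.get("flags") or "").split(";")
            if f
        }
        compound = Compound(
            name=row["name"],
            composition=parse_formula(row["formula"]),
            scaffold=Scaffold(row["scaffold"]),
            side_chain_kind=row["side_chain_kind"],
            side_chain_loss=parse_formula(row["side_chain_loss"]),
            **flags,
        )
        registry[compound.name] = compound
        for alias in (row.get("aliases") or "").split(";"):
            if alias:
                aliases[_norm(alias)] = compound.name
    return registry, aliases


def load_compounds(path=None) -> dict[str, Compound]:
    """Load the compound registry from its tab-separated table.

    Defaults to the registry shipped with the package (the six parent
    drugs); pass a path to extend or replace it with the same format:
    columns name, formula, scaffold, side_chain_kind, side_chain_loss,
    flags (semicolon-separated), aliases (optional, semicolon-separated).
    """
    return _read_registry(path)[0]


def _norm(name: str) -> str:
    return name.replace(" ", "").replace("-", "").upper()


def get_compound(name: str, registry: Mapping[str, Compound] | None = None) -> Compound:
    """Look up a parent by name, tolerant of spacing/hyphen/alias variants."""
    if registry is not None:
        reg, aliases = dict(registry), {}
    else:
        reg, aliases = _read_registry()
    if name in reg:
        return reg[name]
    target = _norm(name)
    for key, compound in reg.items():
        if _norm(key) == target:
            return compound
    if target in aliases:
        return reg[aliases[target]]
    raise KeyError(
        f"unknown parent compound {name!r}; known: {', '.join(sorted(reg))}"
    )
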