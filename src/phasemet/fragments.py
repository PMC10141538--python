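"""Diagnostic MS2 fragment ions and moiety-level modification localization.

Each scaffold class has a small library of characteristic product ions
(e.g. the indazole acylium cation at m/z 145.0396, the benzoyl oxonium
cation at m/z 105.0335). A metabolite's MS2 spectrum is interpreted by
matching peaks against (i) these ions unmodified, (ii) the ions shifted by
the candidate's biotransformation mass deltas, and (iii) either of those
minus a small neutral loss (water; HF for fluorinated species). A
modification is localized to the moiety whose diagnostic ions appear
shifted while a complementary moiety's ions appear unshifted — the same
moiety-level reasoning an analyst applies by hand, and deliberately no
finer: atom positions are never asserted.
"""

from __future__ import annotations

import csv
import itertools
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

from .chem import ElementalComposition, cation_mz, parse_formula, ppm_error
from .rules import Compound, MetaboliteCandidate, Scaffold, rule_delta_mass

__all__ = [
    "FragmentIon",
    "FragmentEvidence",
    "NEUTRAL_LOSS_MASS",
    "scaffold_fragments",
    "explain_fragment",
    "localize",
    "resolvable_moieties",
    "AMBIGUOUS",
]

#: Sentinel localization outcome when evidence is absent or conflicting.
AMBIGUOUS = "ambiguous"

#: Depth-1 neutral losses considered when explaining product ions.
NEUTRAL_LOSS_MASS: Mapping[str, float] = {
    "H2O": 18.0105646,
    "HF": 20.0062282,
}


@dataclass(frozen=True)
class FragmentIon:
    """A diagnostic product ion of a scaffold (even-electron cation).

    ``covers`` lists the atomic moieties contained in the ion (used for
    localization set logic); ``diagnostic_of`` is the display label.
    ``modified`` marks ions that already embed a biotransformation
    (e.g. hydroxybenzoyl = benzoyl + O); these never veto a localization.
    """

    id: str
    composition: ElementalComposition
    diagnostic_of: str
    covers: frozenset[str]
    scaffold: Scaffold
    parents: tuple[str, ...] = ()
    modified: bool = False

    @property
    def mz(self) -> float:
        return cation_mz(self.composition)


@dataclass(frozen=True)
class FragmentEvidence:
    """One explanation of an observed product-ion m/z."""

    observed_mz: float
    fragment_id: str
    shift_steps: tuple[str, ...]  # rule ids whose deltas were applied
    neutral_loss: str | None
    theoretical_mz: float
    ppm: float


_LIBRARY: tuple[FragmentIon, ...] | None = None


def _full_library() -> tuple[FragmentIon, ...]:
    global _LIBRARY
    if _LIBRARY is None:
        source = resources.files("phasemet").joinpath("data/fragments.tsv")
        rows = csv.DictReader(
            source.read_text(encoding="utf-8").splitlines(), delimiter="\t"
        )
        ions = []
        for row in rows:
            ions.append(
                FragmentIon(
                    id=row["id"],
                    composition=parse_formula(row["formula"]),
                    diagnostic_of=row["diagnostic_of"],
                    covers=frozenset(
                        m for m in (row["covers"] or "").split(";") if m
                    ),
                    scaffold=Scaffold(row["scaffold"]),
                    parents=tuple(
                        p for p in (row.get("parents") or "").split(";") if p
                    ),
                    modified=row.get("modified", "0") == "1",
                )
            )
        _LIBRARY = tuple(ions)
    return _LIBRARY


def scaffold_fragments(compound: Compound) -> tuple[FragmentIon, ...]:
    """Diagnostic ions applicable to a parent: its scaffold's shared ions
    plus any chain-specific ions registered for that compound."""
    if not isinstance(compound.scaffold, Scaffold):
        raise ValueError(f"unknown scaffold {compound.scaffold!r}")
    return tuple(
        ion
        for ion in _full_library()
        if ion.scaffold == compound.scaffold
        and (not ion.parents or compound.name in ion.parents)
    )


def _step_shift_combinations(candidate: MetaboliteCandidate):
    """All sub-multisets of the candidate's steps with their summed mass shift."""
    counts = Counter(candidate.steps)
    rule_ids = sorted(counts)
    per_rule_mass = {
        rid: rule_delta_mass(rid, candidate.parent) for rid in rule_ids
    }
    for take in itertools.product(*(range(counts[r] + 1) for r in rule_ids)):
        steps: tuple[str, ...] = tuple(
            itertools.chain.from_iterable(
                (rid,) * n for rid, n in zip(rule_ids, take)
            )
        )
        yield steps, sum(per_rule_mass[rid] * n for rid, n in zip(rule_ids, take))


def explain_fragment(
    observed: float,
    candidate: MetaboliteCandidate,
    library: Sequence[FragmentIon],
    tol_ppm: float = 5.0,
    allow_losses: Sequence[str] = ("H2O",),
) -> list[FragmentEvidence]:
    """Explain one observed product-ion m/z against a candidate's library.

    Constructions tried: each library ion unmodified; shifted by any
    sub-multiset of the candidate's rule deltas; and either of those minus
    a single neutral loss from ``allow_losses`` (HF is only considered
    when the candidate or its parent carries fluorine). All matches within
    ``tol_ppm`` are returned, sorted by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    has_fluorine = (
        candidate.composition["F"] >= 1 or candidate.parent.composition["F"] >= 1
    )
    losses: list[str | None] = [None]
    for loss in allow_losses:
        if loss not in NEUTRAL_LOSS_MASS:
            raise ValueError(f"unknown neutral loss {loss!r}")
        if loss == "HF" and not has_fluorine:
            continue
        losses.append(loss)
    matches: list[FragmentEvidence] = []
    for ion in library:
        for steps, shift in _step_shift_combinations(candidate):
            base = ion.mz + shift
            for loss in losses:
                theo = base - (NEUTRAL_LOSS_MASS[loss] if loss else 0.0)
                if theo <= 0:
                    continue
                err = ppm_error(observed, theo)
                if abs(err) <= tol_ppm:
                    matches.append(
                        FragmentEvidence(
                            observed_mz=observed,
                            fragment_id=ion.id,
                            shift_steps=steps,
                            neutral_loss=loss,
                            theoretical_mz=theo,
                            ppm=err,
                        )
                    )
    matches.sort(key=lambda e: (abs(e.ppm), e.fragment_id, e.shift_steps))
    return matches


def _spectrum_evidence(
    candidate: MetaboliteCandidate,
    ms2: Sequence[tuple[float, float]],
    library: Sequence[FragmentIon],
    tol_ppm: float,
) -> list[FragmentEvidence]:
    evidence: list[FragmentEvidence] = []
    losses = ("H2O", "HF")
    for mz, _intensity in ms2:
        evidence.extend(
            explain_fragment(mz, candidate, library, tol_ppm, allow_losses=losses)
        )
    return evidence


def localize(
    candidate: MetaboliteCandidate,
    ms2: Sequence[tuple[float, float]],
    library: Sequence[FragmentIon] | None = None,
    tol_ppm: float = 5.0,
) -> dict[str, str]:
    """Assign each biotransformation step of a candidate to a moiety.

    For every rule in the candidate's path, diagnostic ions observed
    shifted by that rule's delta vote *for* the moieties they contain,
    while unmodified diagnostic ions observed at their native m/z veto
    the moieties *they* contain. A single surviving moiety is returned as
    the localization; if the survivors jointly correspond to one composite
    diagnostic ion (e.g. the N-butyl-indazole acylium), that composite
    label is returned. Anything else — no shifted evidence, or a conflict —
    yields ``"ambiguous"``. Atom positions are never asserted.

    Returns a mapping rule id -> moiety label (or ``"ambiguous"``).
    """
    if not ms2:
        raise ValueError("ms2 spectrum is empty")
    if library is None:
        library = scaffold_fragments(candidate.parent)
    by_id = {ion.id: ion for ion in library}
    evidence = _spectrum_evidence(candidate, ms2, library, tol_ppm)

    unshifted_veto: set[str] = set()
    for ev in evidence:
        ion = by_id[ev.fragment_id]
        if not ev.shift_steps and not ion.modified:
            unshifted_veto |= ion.covers

    assignment: dict[str, str] = {}
    for rule_id in sorted(set(candidate.steps)):
        shifted = [
            ev
            for ev in evidence
            if rule_id in ev.shift_steps and not by_id[ev.fragment_id].modified
        ]
        if not shifted:
            assignment[rule_id] = AMBIGUOUS
            continue
        support: set[str] = set()
        for ev in shifted:
            support |= by_id[ev.fragment_id].covers
        survivors = support - unshifted_veto
        if len(survivors) == 1:
            assignment[rule_id] = next(iter(survivors))
        elif survivors:
            composite = [
                by_id[ev.fragment_id]
                for ev in shifted
                if by_id[ev.fragment_id].covers == frozenset(survivors)
            ]
            assignment[rule_id] = (
                composite[0].diagnostic_of if composite else AMBIGUOUS
            )
        else:
            assignment[rule_id] = AMBIGUOUS
    return assignment


def resolvable_moieties(compound: Compound) -> tuple[str, ...]:
    """Atomic moieties of a parent that its fragment library can localize.

    A moiety is resolvable when some unmodified diagnostic ion contains it
    and, for every other moiety co-occurring in those ions, another ion
    not containing the target covers it (so unshifted observations can
    veto the alternatives). Used by the synthetic-run generator to plant
    only localizable hydroxylation sites.
    """
    library = [ion for ion in scaffold_fragments(compound) if not ion.modified]
    atoms: set[str] = set()
    for ion in library:
        atoms |= ion.covers
    resolvable = []
    for moiety in sorted(atoms):
        containing = [ion for ion in library if moiety in ion.covers]
        if not containing:
            continue
        co_occurring = set().union(*(ion.covers for ion in containing)) - {moiety}
        vetoable = set()
        for ion in library:
            if moiety not in ion.covers:
                vetoable |= ion.covers
        if co_occurring <= vetoable:
            resolvable.append(moiety)
    return tuple(resolvable)
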