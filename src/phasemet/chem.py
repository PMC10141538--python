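"""Elemental-composition arithmetic and accurate-mass computation.

All m/z bookkeeping in the package runs through this module: compositions
are integer element-count mappings, masses are monoisotopic (most abundant
isotope per element), and ions are singly charged positive species as
produced by electrospray in positive mode — either protonated molecules
[M+H]+ or even-electron fragment cations.
"""

from __future__ import annotations

import itertools
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC_MASS",
    "ElementalComposition",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "cation_mz",
    "ppm_error",
    "rdbe",
    "fit_composition",
]

#: Monoisotopic atomic masses in Da (CODATA/NIST). 12C defines the scale.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
}

ELECTRON_MASS: float = 0.0005485799
PROTON_MASS: float = 1.0072764665

# Valence-based ring-and-double-bond-equivalent increments: 1 + sum n_i (v_i - 2) / 2.
_RDBE_INCREMENT: Mapping[str, float] = {
    "C": 1.0,
    "H": -0.5,
    "N": 0.5,
    "O": 0.0,
    "F": -0.5,
    "S": 0.0,
    "P": 0.5,
    "Cl": -0.5,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Immutable mapping of element symbol -> non-negative integer count.

    Supports element-wise ``+`` and ``-`` (the latter raises if any count
    would go negative) and signed shifts via :meth:`shift`. Zero counts are
    normalised away so equal compositions compare and hash equal.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or isinstance(count, bool):
                raise ValueError(f"count for {element} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count:
                clean[element] = count
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def items(self):
        return self.counts.items()

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self.shift({e: -c for e, c in other.counts.items()})

    def shift(self, delta: Mapping[str, int]) -> "ElementalComposition":
        """Apply a signed element-count delta; raises on a negative result."""
        merged = dict(self.counts)
        for element, count in delta.items():
            merged[element] = merged.get(element, 0) + count
            if merged[element] < 0:
                raise ValueError(
                    f"composition underflow: {element} would be {merged[element]}"
                )
        return ElementalComposition(merged)

    def hill(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-notation molecular formula such as ``C18H26N4O2``.

    Each element symbol may be followed by an optional positive integer
    count. Raises ``ValueError`` on empty input, unknown symbols, or any
    text that is not a sequence of symbol/count tokens.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        if digits == "0":
            raise ValueError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return ElementalComposition(counts)


def format_formula(comp: ElementalComposition) -> str:
    """Hill notation: C first, then H, then remaining elements alphabetically."""
    ordered: list[str] = []
    symbols = set(comp.counts)
    if "C" in symbols:
        ordered.append("C")
        if "H" in symbols:
            ordered.append("H")
        ordered.extend(sorted(symbols - {"C", "H"}))
    else:
        ordered.extend(sorted(symbols))
    return "".join(
        f"{e}{comp[e]}" if comp[e] != 1 else e for e in ordered
    )


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral monoisotopic mass in Da; additive over composition sums."""
    return sum(count * MONOISOTOPIC_MASS[element] for element, count in comp.items())


def protonated_mz(comp: ElementalComposition) -> float:
    """m/z of the singly protonated molecule [M+H]+ for a neutral composition."""
    return monoisotopic_mass(comp) + PROTON_MASS


def cation_mz(comp: ElementalComposition) -> float:
    """m/z of an even-electron cation whose formula includes its charge proton.

    E.g. the benzoyl (benzyl oxonium) cation C7H5O+ at m/z 105.0335.
    """
    return monoisotopic_mass(comp) - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(comp: ElementalComposition) -> float:
    """Ring-and-double-bond equivalents: C - (H+F+Cl)/2 + (N+P)/2 + 1."""
    return 1.0 + sum(
        count * _RDBE_INCREMENT[element] for element, count in comp.items()
    )


def _is_half_integer(x: float) -> bool:
    return abs(x - round(x)) > 0.25


def fit_composition(
    target_mz: float,
    tol_ppm: float,
    bounds: Mapping[str, int],
    ion_mode: str = "protonated",
) -> list[ElementalComposition]:
    """Exhaustively enumerate elemental compositions matching an accurate m/z.

    Parameters
    ----------
    target_mz
        Observed m/z to explain.
    tol_ppm
        Symmetric matching window in ppm; must be positive.
    bounds
        Per-element maximum counts, e.g. ``{"C": 12, "H": 20, "N": 4, "O": 4}``.
    ion_mode
        ``"protonated"``: candidates are neutral molecules scored at
        M + proton, RDBE required to be a non-negative integer.
        ``"cation"``: candidates are fragment formulas; half-integer-RDBE
        formulas are scored as even-electron cations (sum of atoms minus an
        electron), integer-RDBE formulas as plain neutral-loss masses
        (radical-cation convention disabled). RDBE >= 0 in both cases.

    Returns all matches sorted by absolute ppm error, ties by Hill formula.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not bounds:
        raise ValueError("empty element bounds")
    if ion_mode not in ("protonated", "cation"):
        raise ValueError(f"unknown ion_mode {ion_mode!r}")
    for element in bounds:
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol in bounds: {element!r}")

    # Heaviest-first ordering lets the running-mass check prune whole subtrees.
    elements = sorted(bounds, key=lambda e: -MONOISOTOPIC_MASS[e])
    tol_da = target_mz * tol_ppm * 1e-6

    results: list[tuple[float, str, ElementalComposition]] = []

    def theoretical(comp: ElementalComposition) -> float:
        if ion_mode == "protonated":
            return protonated_mz(comp)
        return monoisotopic_mass(comp) - (
            ELECTRON_MASS if _is_half_integer(rdbe(comp)) else 0.0
        )

    def recurse(index: int, partial: dict[str, int], mass: float) -> None:
        # mass here is the bare atom-sum; the ion-mode offset (at most ~1 Da)
        # is accounted for in the pruning slack.
        if mass > target_mz + tol_da + 1.5:
            return
        if index == len(elements):
            comp = ElementalComposition(dict(partial))
            mz = theoretical(comp)
            if abs(mz - target_mz) <= tol_da:
                r = rdbe(comp)
                if r < 0:
                    return
                if ion_mode == "protonated" and _is_half_integer(r):
                    return
                err = abs(ppm_error(mz, target_mz))
                results.append((err, comp.hill(), comp))
            return
        element = elements[index]
        for count in range(bounds[element] + 1):
            new_mass = mass + count * MONOISOTOPIC_MASS[element]
            if new_mass > target_mz + tol_da + 1.5:
                break
            partial[element] = count
            recurse(index + 1, partial, new_mass)
        partial.pop(element, None)

    recurse(0, {}, 0.0)
    results.sort(key=lambda item: (item[0], item[1]))
    return [comp for _, _, comp in results]


def enumerate_compositions(
    bounds: Mapping[str, int],
) -> Iterator[ElementalComposition]:
    """Yield every composition within per-element bounds (test/oracle helper)."""
    elements = list(bounds)
    for counts in itertools.product(*(range(bounds[e] + 1) for e in elements)):
        yield ElementalComposition(dict(zip(elements, counts)))
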