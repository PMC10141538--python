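"""Ground-truthed synthetic LC-HRMS runs for end-to-end pipeline testing.

The generator emulates a positive-mode data-dependent Orbitrap acquisition:
an MS1 survey over m/z 100-1000 with product-ion spectra over m/z 50-1000.
Planted metabolite features take their theoretical [M+H]+ from the rule
engine, perturbed by Gaussian ppm error truncated at the 5 ppm acceptance
window; decoy features are placed uniformly, rejected within 20 ppm of any
candidate so false-positive behaviour is unambiguous. Peak areas are
log-normal, retention times uniform inside the observed metabolite elution
window (5.10-11.67 min). Each planted feature carries an MS2 spectrum
built from the scaffold's diagnostic ions: ions containing a step's
planted moiety appear shifted by that step's mass delta, the rest appear
at their native m/z, each included with a configurable completeness
probability.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .annotate import MS1_RANGE, MS2_RANGE, Feature
from .fragments import resolvable_moieties, scaffold_fragments
from .rules import (
    Compound,
    MetaboliteCandidate,
    enumerate_metabolites,
    get_compound,
    rule_delta_mass,
)

__all__ = ["TruthConfig", "SyntheticRun", "simulate_run"]

#: Elution window (minutes) the generator draws retention times from.
DEFAULT_RT_WINDOW = (5.10, 11.67)

#: Hard ppm cutoff for the truncated Gaussian mass error.
ERROR_TRUNCATION_PPM = 5.0

# Rules whose modification rides on the N-alkyl side chain; their planted
# site is always the chain. Conjugations/hydrolyses touch the linker, which
# no diagnostic ion covers, so they shift nothing (fragments stay native).
_CHAIN_RULES = frozenset(
    {
        "dehydrogenation",
        "hydrogenation",
        "ketone",
        "carboxylation",
        "dihydrodiol",
        "N_dealkylation",
        "oxidative_defluorination",
    }
)
_UNLOCALIZED_RULES = frozenset(
    {"amide_hydrolysis", "ester_hydrolysis", "glucuronidation", "benzoyl_hydrolysis"}
)


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for one synthetic run.

    ``planted`` is either a count (candidates sampled from the enumeration,
    with replacement once the candidate space is exhausted) or an explicit
    tuple of rule paths, each a tuple of rule ids.
    """

    parent: str
    planted: int | tuple[tuple[str, ...], ...] = 30
    mass_error_sd_ppm: float = 1.0
    n_decoys: int = 30
    decoy_min_ppm: float = 20.0
    area_median: float = 1e6
    area_sigma: float = 1.0
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW
    fragment_completeness: float = 1.0
    seed: int = 0
    max_depth: int = 4

    def __post_init__(self) -> None:
        if self.mass_error_sd_ppm < 0:
            raise ValueError("mass-error SD must be >= 0")
        lo, hi = self.rt_window
        if not (0.0 <= lo <= hi <= 18.0):
            raise ValueError("rt_window must lie within the 0-18 min gradient")
        if not 0.0 <= self.fragment_completeness <= 1.0:
            raise ValueError("fragment_completeness must be in [0, 1]")


@dataclass
class TruthRow:
    """Ground-truth record for one synthetic feature."""

    feature_id: str
    kind: str  # "planted" | "decoy"
    rule_path: str = ""
    composition: str = ""
    theoretical_mz: float = float("nan")
    observed_mz: float = float("nan")
    error_ppm: float = float("nan")
    planted_moieties: str = ""


@dataclass
class SyntheticRun:
    """Features plus the ground truth that produced them."""

    parent: Compound
    features: list[Feature]
    truth: list[TruthRow]
    config: TruthConfig = field(repr=False, default=None)

    def planted_rows(self) -> list[TruthRow]:
        return [row for row in self.truth if row.kind == "planted"]

    def decoy_rows(self) -> list[TruthRow]:
        return [row for row in self.truth if row.kind == "decoy"]


def _truncated_ppm_error(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 0.0
    while True:
        eps = rng.normal(0.0, sd)
        if abs(eps) <= ERROR_TRUNCATION_PPM:
            return eps


def _select_candidates(
    config: TruthConfig,
    candidates: Sequence[MetaboliteCandidate],
    rng: np.random.Generator,
) -> list[MetaboliteCandidate]:
    if isinstance(config.planted, int):
        n = config.planted
        if n < 0:
            raise ValueError("planted count must be >= 0")
        if n <= len(candidates):
            idx = rng.choice(len(candidates), size=n, replace=False)
        else:
            idx = rng.choice(len(candidates), size=n, replace=True)
        return [candidates[i] for i in idx]
    by_key = {
        tuple(sorted(Counter(c.steps).items())): c for c in candidates
    }
    selected = []
    for path in config.planted:
        key = tuple(sorted(Counter(path).items()))
        if key not in by_key:
            raise ValueError(
                f"planted path {path!r} not in the candidate closure at "
                f"depth {config.max_depth}"
            )
        selected.append(by_key[key])
    return selected


def _plant_moieties(
    candidate: MetaboliteCandidate,
    hydroxyl_sites: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[str, str | None]]:
    """Choose a moiety for each step occurrence of the candidate path.

    Hydroxylation sites are drawn among the moieties the fragment library
    can resolve; chain-bound transformations sit on the side chain;
    hydrolyses and conjugations shift no diagnostic ion.
    """
    placements: list[tuple[str, str | None]] = []
    for rule_id in candidate.steps:
        if rule_id == "hydroxylation":
            site = (
                str(rng.choice(list(hydroxyl_sites))) if hydroxyl_sites else None
            )
        elif rule_id in _CHAIN_RULES:
            site = "side-chain"
        elif rule_id in _UNLOCALIZED_RULES:
            site = None
        else:
            site = None
        placements.append((rule_id, site))
    return placements


def _build_ms2(
    candidate: MetaboliteCandidate,
    placements: Sequence[tuple[str, str | None]],
    precursor_mz: float,
    config: TruthConfig,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], ...]:
    library = [
        ion for ion in scaffold_fragments(candidate.parent) if not ion.modified
    ]
    peaks: list[tuple[float, float]] = []
    if MS2_RANGE[0] <= precursor_mz <= MS2_RANGE[1]:
        peaks.append((precursor_mz, float(rng.uniform(1e5, 1e6))))
    for ion in library:
        shift = sum(
            rule_delta_mass(rule_id, candidate.parent)
            for rule_id, site in placements
            if site is not None and site in ion.covers
        )
        mz = ion.mz + shift
        if not MS2_RANGE[0] <= mz <= MS2_RANGE[1]:
            continue
        eps = _truncated_ppm_error(rng, config.mass_error_sd_ppm)
        mz_obs = mz * (1.0 + eps * 1e-6)
        intensity = float(rng.uniform(1e3, 1e5))
        if rng.random() < config.fragment_completeness or (
            config.fragment_completeness == 1.0
        ):
            peaks.append((mz_obs, intensity))
    return tuple(peaks)


def simulate_run(config: TruthConfig) -> SyntheticRun:
    """Generate one deterministic synthetic run from a truth configuration."""
    rng = np.random.default_rng(config.seed)
    parent = get_compound(config.parent)
    candidates = enumerate_metabolites(parent, max_depth=config.max_depth)
    exclusion_mzs = np.array([c.mz for c in candidates] + [parent.mz])

    selected = _select_candidates(config, candidates, rng)
    hydroxyl_sites = resolvable_moieties(parent)

    features: list[Feature] = []
    truth: list[TruthRow] = []

    for index, candidate in enumerate(selected, start=1):
        fid = f"P{index:04d}"
        eps = _truncated_ppm_error(rng, config.mass_error_sd_ppm)
        mz_obs = candidate.mz * (1.0 + eps * 1e-6)
        mz_obs = float(np.clip(mz_obs, *MS1_RANGE))
        area = float(
            rng.lognormal(mean=np.log(config.area_median), sigma=config.area_sigma)
        )
        rt = float(rng.uniform(*config.rt_window))
        placements = _plant_moieties(candidate, hydroxyl_sites, rng)
        ms2 = _build_ms2(candidate, placements, mz_obs, config, rng)
        features.append(
            Feature(feature_id=fid, mz=mz_obs, rt=rt, area=area, ms2=ms2)
        )
        truth.append(
            TruthRow(
                feature_id=fid,
                kind="planted",
                rule_path=candidate.rule_path,
                composition=candidate.composition.hill(),
                theoretical_mz=candidate.mz,
                observed_mz=mz_obs,
                error_ppm=eps,
                planted_moieties=";".join(
                    f"{rule}:{site}" for rule, site in placements if site
                ),
            )
        )

    n_placed = 0
    while n_placed < config.n_decoys:
        mz = float(rng.uniform(*MS1_RANGE))
        ppm_distances = np.abs(mz - exclusion_mzs) / exclusion_mzs * 1e6
        if ppm_distances.min() < config.decoy_min_ppm:
            continue
        n_placed += 1
        fid = f"D{n_placed:04d}"
        area = float(
            rng.lognormal(mean=np.log(config.area_median), sigma=config.area_sigma)
        )
        rt = float(rng.uniform(*config.rt_window))
        features.append(Feature(feature_id=fid, mz=mz, rt=rt, area=area, ms2=None))
        truth.append(TruthRow(feature_id=fid, kind="decoy", observed_mz=mz))

    return SyntheticRun(parent=parent, features=features, truth=truth, config=config)
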