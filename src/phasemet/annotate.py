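"""MS1 feature annotation against enumerated metabolite candidates.

Matching is deterministic tolerance gating on ppm mass error (no
probabilistic scoring): every candidate within the window annotates the
feature, ranked by |ppm|, then path depth, then rule path. Retention time
is carried through for reporting but never scored — the acquisition this
emulates derives no identification rule from it. Biomarker ranking is by
peak area among annotated metabolite features, excluding the parent drug
itself, which is reported separately.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .chem import ppm_error
from .fragments import (
    AMBIGUOUS,
    FragmentEvidence,
    localize,
    scaffold_fragments,
)
from .rules import (
    Compound,
    MetaboliteCandidate,
    enumerate_metabolites,
    root_candidate,
)

__all__ = [
    "Feature",
    "Annotation",
    "AnnotationReport",
    "match_features",
    "rank_biomarkers",
    "annotate_run",
]

#: MS1 survey scan range (m/z) of the emulated acquisition.
MS1_RANGE = (100.0, 1000.0)
#: MS2 product-ion scan range (m/z).
MS2_RANGE = (50.0, 1000.0)


@dataclass(frozen=True)
class Feature:
    """One MS1 feature: centroid m/z, retention time (min), peak area,
    and optionally its data-dependent MS2 spectrum as (m/z, intensity)."""

    feature_id: str
    mz: float
    rt: float
    area: float
    ms2: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not MS1_RANGE[0] <= self.mz <= MS1_RANGE[1]:
            raise ValueError(
                f"feature {self.feature_id}: m/z {self.mz} outside survey "
                f"range {MS1_RANGE[0]}-{MS1_RANGE[1]}"
            )
        if self.ms2:
            for frag_mz, _ in self.ms2:
                if not MS2_RANGE[0] <= frag_mz <= MS2_RANGE[1]:
                    raise ValueError(
                        f"feature {self.feature_id}: fragment m/z {frag_mz} "
                        f"outside range {MS2_RANGE[0]}-{MS2_RANGE[1]}"
                    )


@dataclass
class Annotation:
    """A (feature, candidate) match within tolerance, with MS2 evidence."""

    feature: Feature
    candidate: MetaboliteCandidate
    ppm: float
    evidence: tuple[FragmentEvidence, ...] = ()
    localization: Mapping[str, str] = field(default_factory=dict)
    rank: int = 0  # 1-based rank among the feature's annotations
    biomarker_rank: int | None = None

    @property
    def sort_key(self):
        return (abs(self.ppm), self.candidate.depth, self.candidate.steps)


@dataclass
class BiomarkerShortlist:
    """Top-k largest-area metabolite annotations; ``short`` flags that fewer
    than k annotated features were available."""

    annotations: list[Annotation]
    k: int
    short: bool = False


@dataclass
class AnnotationReport:
    """Deterministic per-run annotation summary."""

    parent: Compound
    annotations: list[Annotation]
    unannotated: list[Feature]
    parent_matches: list[Annotation]
    biomarkers: BiomarkerShortlist
    tol_ppm: float

    def summary(self) -> dict[str, int]:
        annotated_ids = {a.feature.feature_id for a in self.annotations}
        return {
            "n_features": len(annotated_ids)
            + len(self.unannotated)
            + len({a.feature.feature_id for a in self.parent_matches}),
            "n_annotated": len(annotated_ids),
            "n_unannotated": len(self.unannotated),
            "n_annotations": len(self.annotations),
            "n_parent_features": len(
                {a.feature.feature_id for a in self.parent_matches}
            ),
            "n_biomarkers": len(self.biomarkers.annotations),
        }


def match_features(
    features: Sequence[Feature],
    candidates: Sequence[MetaboliteCandidate],
    tol_ppm: float = 5.0,
) -> list[Annotation]:
    """All (feature, candidate) pairs within the ppm window.

    Per feature, annotations are sorted by (|ppm|, depth, rule path) and
    given a 1-based rank; features with no candidate in range yield no
    annotation (the report stage lists them as unannotated).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    annotations: list[Annotation] = []
    for feature in features:
        hits = []
        for candidate in candidates:
            err = ppm_error(feature.mz, candidate.mz)
            if abs(err) <= tol_ppm:
                hits.append(Annotation(feature=feature, candidate=candidate, ppm=err))
        hits.sort(key=lambda a: a.sort_key)
        for rank, annotation in enumerate(hits, start=1):
            annotation.rank = rank
        annotations.extend(hits)
    return annotations


def rank_biomarkers(annotations: Sequence[Annotation], k: int = 3) -> BiomarkerShortlist:
    """Top-k annotated metabolite features by peak area.

    The parent drug itself (a zero-step candidate) is excluded. Each
    feature counts once, represented by its best (rank-1) annotation.
    Ties on area break toward smaller |ppm|, then feature id. When fewer
    than ``k`` features are annotated, all are returned and the shortlist
    is flagged ``short``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    best: dict[str, Annotation] = {}
    for annotation in annotations:
        if annotation.candidate.depth == 0:
            continue
        fid = annotation.feature.feature_id
        if fid not in best or annotation.sort_key < best[fid].sort_key:
            best[fid] = annotation
    pool = sorted(
        best.values(),
        key=lambda a: (-a.feature.area, abs(a.ppm), a.feature.feature_id),
    )
    shortlist = pool[:k]
    for i, annotation in enumerate(shortlist, start=1):
        annotation.biomarker_rank = i
    return BiomarkerShortlist(
        annotations=shortlist, k=k, short=len(shortlist) < k
    )


def annotate_run(
    features: Sequence[Feature],
    parent: Compound,
    tol_ppm: float = 5.0,
    max_depth: int = 4,
    caps: Mapping[str, int] | None = None,
    k_biomarkers: int = 3,
) -> AnnotationReport:
    """Full pipeline on one run: enumerate, match, explain, localize, rank.

    Deterministic for identical inputs. The parent's own feature(s) are
    matched and reported separately from metabolite annotations.
    """
    candidates = enumerate_metabolites(parent, max_depth=max_depth, caps=caps)
    library = scaffold_fragments(parent)

    metabolite_annotations = match_features(features, candidates, tol_ppm)

    parent_candidate = root_candidate(parent)
    parent_matches = match_features(features, [parent_candidate], tol_ppm)
    parent_feature_ids = {a.feature.feature_id for a in parent_matches}

    # Don't report the parent feature a second time as a metabolite unless
    # a metabolite candidate genuinely shares its m/z within tolerance.
    annotated_ids = {a.feature.feature_id for a in metabolite_annotations}
    unannotated = [
        f
        for f in features
        if f.feature_id not in annotated_ids
        and f.feature_id not in parent_feature_ids
    ]

    for annotation in metabolite_annotations:
        ms2 = annotation.feature.ms2
        if not ms2:
            continue
        evidence = []
        for mz, intensity in ms2:
            evidence.extend(
                ev
                for ev in _explain_peak(mz, annotation.candidate, library, tol_ppm)
            )
        annotation.evidence = tuple(evidence)
        annotation.localization = localize(
            annotation.candidate, ms2, library, tol_ppm
        )

    biomarkers = rank_biomarkers(metabolite_annotations, k=k_biomarkers)
    return AnnotationReport(
        parent=parent,
        annotations=metabolite_annotations,
        unannotated=unannotated,
        parent_matches=parent_matches,
        biomarkers=biomarkers,
        tol_ppm=tol_ppm,
    )


def _explain_peak(mz, candidate, library, tol_ppm):
    from .fragments import explain_fragment

    return explain_fragment(
        mz, candidate, library, tol_ppm, allow_losses=("H2O", "HF")
    )


def localization_label(annotation: Annotation) -> str:
    """Compact ``rule:moiety`` display for report tables."""
    if not annotation.localization:
        return ""
    return ";".join(
        f"{rule}:{moiety}"
        for rule, moiety in sorted(annotation.localization.items())
    )


AMBIGUOUS_LABEL = AMBIGUOUS
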