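"""Readers and writers for the pipeline's interchange formats.

Feature tables and annotation tables are plain UTF-8 CSV with a header
("." decimal separator); MS2 spectra travel as MGF keyed by feature id in
the TITLE field. Writers are deterministic: stable row order and fixed
decimal formatting (m/z to 4 decimals, ppm to 2), so identical runs give
byte-identical files.
"""

from __future__ import annotations

import csv
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotate import AnnotationReport, Feature
from .simulate import SyntheticRun

__all__ = [
    "PipelineConfig",
    "read_feature_table",
    "read_mgf",
    "attach_spectra",
    "write_feature_table",
    "write_mgf",
    "write_ground_truth",
    "write_annotations",
    "format_report_text",
]

_FEATURE_COLUMNS = ("feature_id", "mz", "rt_min", "area")

_ANNOTATION_COLUMNS = (
    "feature_id",
    "observed_mz",
    "theoretical_mz",
    "ppm",
    "composition",
    "rule_path",
    "depth",
    "localization",
    "area",
    "biomarker_rank",
)


@dataclass
class PipelineConfig:
    """User-tunable pipeline settings with acquisition-matched defaults."""

    tol_ppm: float = 5.0
    max_depth: int = 4
    caps: Mapping[str, int] | None = None
    ms1_range: tuple[float, float] = (100.0, 1000.0)
    ms2_range: tuple[float, float] = (50.0, 1000.0)
    neutral_losses: tuple[str, ...] = ("H2O", "HF")
    k_biomarkers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for lo, hi in (self.ms1_range, self.ms2_range):
            if lo >= hi:
                raise ValueError(f"scan range must be ordered, got ({lo}, {hi})")
        if self.k_biomarkers < 1:
            raise ValueError("k_biomarkers must be >= 1")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a key-value (YAML) config file; keyword overrides win."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain key-value pairs")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        for key in ("ms1_range", "ms2_range", "neutral_losses"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def read_feature_table(path) -> list[Feature]:
    """Read an MS1 feature table CSV (feature_id, mz, rt_min, area).

    Row order is preserved. Raises ``ValueError`` naming the offending
    column on missing columns or non-numeric values, and listing the ids
    on duplicate feature ids.
    """
    frame = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in _FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path}: missing column(s) {', '.join(missing)}")
    for column in ("mz", "rt_min", "area"):
        values = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.loc[values.isna(), "feature_id"].tolist()
        if bad:
            raise ValueError(
                f"feature table {path}: non-numeric {column} for feature(s) "
                f"{', '.join(map(str, bad))}"
            )
        frame[column] = values
    duplicated = frame.loc[frame["feature_id"].duplicated(), "feature_id"]
    if not duplicated.empty:
        raise ValueError(
            f"feature table {path}: duplicate feature_id(s) "
            f"{', '.join(duplicated.unique())}"
        )
    return [
        Feature(
            feature_id=row.feature_id, mz=row.mz, rt=row.rt_min, area=row.area
        )
        for row in frame.itertuples(index=False)
    ]


def _validate_mgf_blocks(path) -> None:
    """Cheap structural pre-scan so errors carry line numbers."""
    open_line = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped == "BEGIN IONS":
                if open_line is not None:
                    raise ValueError(
                        f"{path}: BEGIN IONS at line {lineno} inside the block "
                        f"opened at line {open_line} (missing END IONS)"
                    )
                open_line = lineno
            elif stripped == "END IONS":
                if open_line is None:
                    raise ValueError(f"{path}: stray END IONS at line {lineno}")
                open_line = None
    if open_line is not None:
        raise ValueError(
            f"{path}: block opened at line {open_line} is never terminated "
            f"(missing END IONS)"
        )


def read_mgf(path) -> dict[str, tuple[tuple[float, float], ...]]:
    """Read MS2 spectra from MGF; returns feature_id -> peak list.

    The TITLE of each block carries the feature id. Peak order is
    preserved. An empty file yields an empty mapping; unterminated blocks
    and missing titles raise ``ValueError``.
    """
    _validate_mgf_blocks(path)
    spectra: dict[str, tuple[tuple[float, float], ...]] = {}
    with _mgf.read(str(path), use_index=False) as reader:
        for spectrum in reader:
            title = spectrum.get("params", {}).get("title")
            if not title:
                raise ValueError(f"{path}: spectrum block without a TITLE")
            fid = str(title).strip()
            peaks = tuple(
                (float(mz), float(inten))
                for mz, inten in zip(
                    spectrum["m/z array"], spectrum["intensity array"]
                )
            )
            spectra[fid] = peaks
    return spectra


def attach_spectra(
    features: Sequence[Feature],
    spectra: Mapping[str, tuple[tuple[float, float], ...]],
) -> list[Feature]:
    """Return features with their MS2 spectra attached by feature id."""
    return [
        Feature(
            feature_id=f.feature_id,
            mz=f.mz,
            rt=f.rt,
            area=f.area,
            ms2=spectra.get(f.feature_id),
        )
        for f in features
    ]


def write_feature_table(features: Sequence[Feature], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FEATURE_COLUMNS)
        for f in features:
            writer.writerow(
                [f.feature_id, f"{f.mz:.4f}", f"{f.rt:.2f}", f"{f.area:.1f}"]
            )


def write_mgf(features: Sequence[Feature], path) -> None:
    """Write the MS2 spectra of features that have one, as MGF blocks."""
    spectra = []
    for f in features:
        if not f.ms2:
            continue
        mzs, intensities = zip(*f.ms2)
        spectra.append(
            {
                "m/z array": np.asarray(mzs),
                "intensity array": np.asarray(intensities),
                "params": {
                    "title": f.feature_id,
                    "pepmass": round(f.mz, 4),
                    "charge": "1+",
                },
            }
        )
    _mgf.write(spectra, output=str(path), file_mode="w")


def write_ground_truth(run: SyntheticRun, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "feature_id",
                "kind",
                "rule_path",
                "composition",
                "theoretical_mz",
                "observed_mz",
                "error_ppm",
                "planted_moieties",
            ]
        )
        for row in run.truth:
            writer.writerow(
                [
                    row.feature_id,
                    row.kind,
                    row.rule_path,
                    row.composition,
                    "" if np.isnan(row.theoretical_mz) else f"{row.theoretical_mz:.4f}",
                    f"{row.observed_mz:.4f}",
                    "" if np.isnan(row.error_ppm) else f"{row.error_ppm:.3f}",
                    row.planted_moieties,
                ]
            )


def _annotation_rows(report: AnnotationReport):
    from .annotate import localization_label

    for annotation in report.annotations:
        yield [
            annotation.feature.feature_id,
            f"{annotation.feature.mz:.4f}",
            f"{annotation.candidate.mz:.4f}",
            f"{annotation.ppm:.2f}",
            annotation.candidate.composition.hill(),
            annotation.candidate.rule_path,
            annotation.candidate.depth,
            localization_label(annotation),
            f"{annotation.feature.area:.1f}",
            annotation.biomarker_rank if annotation.biomarker_rank else "",
        ]


def write_annotations(report: AnnotationReport, path) -> None:
    """Write the annotation table CSV (feature order, then rank)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_COLUMNS)
        for row in _annotation_rows(report):
            writer.writerow(row)


def format_report_text(report: AnnotationReport) -> str:
    """Human-readable run summary (deterministic)."""
    lines = []
    summary = report.summary()
    lines.append(f"parent: {report.parent.name} [M+H]+ {report.parent.mz:.4f}")
    lines.append(f"tolerance: {report.tol_ppm:g} ppm")
    for key in sorted(summary):
        lines.append(f"{key}: {summary[key]}")
    if report.parent_matches:
        lines.append("parent features:")
        for match in report.parent_matches:
            lines.append(
                f"  {match.feature.feature_id}  m/z {match.feature.mz:.4f}  "
                f"{match.ppm:+.2f} ppm  area {match.feature.area:.1f}"
            )
    lines.append("biomarker shortlist (by peak area, parent excluded):")
    if report.biomarkers.short:
        lines.append(
            f"  [flagged: only {len(report.biomarkers.annotations)} of "
            f"{report.biomarkers.k} requested]"
        )
    for annotation in report.biomarkers.annotations:
        lines.append(
            f"  #{annotation.biomarker_rank}  {annotation.feature.feature_id}  "
            f"m/z {annotation.feature.mz:.4f}  {annotation.candidate.rule_path}  "
            f"area {annotation.feature.area:.1f}"
        )
    lines.append("unannotated features:")
    for feature in report.unannotated:
        lines.append(f"  {feature.feature_id}  m/z {feature.mz:.4f}")
    return "\n".join(lines) + "\n"
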