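"""CSV interchange for annotations, manifests and ground-truth cells.

Annotation files use the canonical header ``slide_id, annotator_id, x_px,
y_px, grade`` (UTF-8, "." decimal).  Readers validate each row and report
the offending data row and field; writers emit a deterministic row order so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scoring import CellAnnotation
from .synthetic import GroundTruthCell, SlideManifest

def _float_repr(v) -> str:
    """Shortest exact decimal representation (lossless round trip)."""
    return repr(float(v))


ANNOTATION_COLUMNS = ["slide_id", "annotator_id", "x_px", "y_px", "grade"]
GROUND_TRUTH_COLUMNS = [
    "slide_id", "cell_id", "x_px", "y_px", "content", "grade", "is_macrophage",
]
MANIFEST_COLUMNS = [
    "slide_id", "stain", "severity", "n_macrophages", "width", "height",
    "sample_id", "iron", "iron_censored", "rbc", "hemoglobin",
]


def read_annotations(path) -> list[CellAnnotation]:
    """Read and validate an annotation CSV.

    Errors name the 1-based data row and the offending field.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    out: list[CellAnnotation] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        out.append(_parse_annotation_row(row, pos))
    return out


def _parse_annotation_row(row, pos: int) -> CellAnnotation:
    raw_grade = str(row.grade).strip()
    try:
        grade = int(raw_grade)
    except ValueError:
        raise ValueError(f"row {pos}: grade {raw_grade!r} is not an integer") from None
    coords = {}
    for name in ("x_px", "y_px"):
        try:
            coords[name] = float(getattr(row, name))
        except ValueError:
            raise ValueError(
                f"row {pos}: {name} {getattr(row, name)!r} is not a number"
            ) from None
    try:
        return CellAnnotation(
            slide_id=str(row.slide_id),
            annotator_id=str(row.annotator_id),
            x=coords["x_px"],
            y=coords["y_px"],
            grade=grade,
        )
    except ValueError as exc:
        raise ValueError(f"row {pos}: {exc}") from None


def write_annotations(records: Iterable[CellAnnotation], path) -> None:
    """Write annotations in canonical column and row order."""
    records = list(records)
    # stable sort: slide, then annotator, preserving cell order within
    records.sort(key=lambda a: (a.slide_id, a.annotator_id))
    df = pd.DataFrame(
        [(a.slide_id, a.annotator_id, a.x, a.y, a.grade) for a in records],
        columns=ANNOTATION_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format=_float_repr)


def write_ground_truth(cells: Iterable[GroundTruthCell], path) -> None:
    df = pd.DataFrame(
        [
            (c.slide_id, c.cell_id, c.x, c.y, c.content, c.grade, c.is_macrophage)
            for c in cells
        ],
        columns=GROUND_TRUTH_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format=_float_repr)


def read_ground_truth(path) -> list[GroundTruthCell]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    return [
        GroundTruthCell(
            slide_id=str(r.slide_id),
            cell_id=str(r.cell_id),
            x=float(r.x_px),
            y=float(r.y_px),
            content=float(r.content),
            grade=int(r.grade),
            is_macrophage=bool(r.is_macrophage),
        )
        for r in df.itertuples(index=False)
    ]


def write_manifests(manifests: Iterable[SlideManifest], path) -> None:
    df = pd.DataFrame(
        [
            (
                m.slide_id, m.stain, m.severity, m.n_macrophages, m.width,
                m.height, m.sample_id, m.iron, m.iron_censored, m.rbc,
                m.hemoglobin,
            )
            for m in manifests
        ],
        columns=MANIFEST_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format=_float_repr)


def read_manifests(path) -> list[SlideManifest]:
    df = pd.read_csv(path, float_precision="round_trip")

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        SlideManifest(
            slide_id=str(r.slide_id),
            stain=str(r.stain),
            severity=float(r.severity),
            n_macrophages=int(r.n_macrophages),
            width=int(r.width),
            height=int(r.height),
            sample_id=str(r.sample_id),
            iron=opt(r.iron),
            iron_censored=bool(r.iron_censored),
            rbc=opt(r.rbc),
            hemoglobin=opt(r.hemoglobin),
        )
        for r in df.itertuples(index=False)
    ]


def write_ths_records(records: Sequence, path) -> None:
    """THS report CSV: slide_id, rater_id, n_cells, ths, eiph_positive."""
    df = pd.DataFrame(
        [(r.slide_id, r.rater_id, r.n_cells, r.ths, r.eiph_positive) for r in records],
        columns=["slide_id", "rater_id", "n_cells", "ths", "eiph_positive"],
    ).sort_values(["slide_id", "rater_id"], kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format=_float_repr)
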