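"""Total hemosiderin score (THS) computation and hemosiderin-grade semantics.

The THS is the standard semi-quantitative cytologic readout for
exercise-induced pulmonary hemorrhage (EIPH) in horses.  Each of at least 300
alveolar macrophages in an iron-stained bronchoalveolar-lavage preparation is
assigned a discrete hemosiderin grade from 0 (no intracytoplasmic hemosiderin)
to 4 (cell filled with hemosiderin), and the score is the grade total
normalised per 100 cells:

    THS = 100 * mean(grade)        (range 0-400)

A THS at or above 75 is the published cut-off for diagnosing EIPH.  This
module defines the annotation record, the score record, the grade-from-content
binning used by the synthetic slides and the rule-based image grader, and the
reference aggregates (mean annotators' THS).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from math import isfinite
from typing import Iterable, Sequence

import numpy as np

#: Discrete hemosiderin grades (Doucet & Viel 5-tier system).
GRADES = (0, 1, 2, 3, 4)

#: Published diagnostic cut-off: THS >= 75 is EIPH-positive.
DEFAULT_CUTOFF = 75.0

#: Minimum number of enumerated macrophages for a valid THS.
MIN_CELLS = 300

#: Canonical pigment-content fractions at which the grade steps up.  The
#: grading literature defines only a verbal continuum; these bin edges are the
#: package-wide convention shared by the slide generator and the image grader.
CANONICAL_THRESHOLDS = (0.02, 0.25, 0.50, 0.75)

#: Rater identifiers reserved for the reference annotation set and the
#: automated image grader; they are never "annotators".
RESERVED_RATER_IDS = ("ground_truth", "algorithm")


class InsufficientCellsError(ValueError):
    """Fewer enumerated macrophages than the protocol minimum."""


def _check_grade(grade: object) -> int:
    if isinstance(grade, bool) or not isinstance(grade, (int, np.integer)):
        raise ValueError(f"grade must be an integer, got {grade!r}")
    g = int(grade)
    if g not in GRADES:
        raise ValueError(f"grade must be in {GRADES}, got {g}")
    return g


@dataclass(frozen=True)
class CellAnnotation:
    """One point-labelled macrophage: centroid coordinates plus grade.

    ``annotator_id`` may be a human rater id or one of the reserved ids
    ``"ground_truth"`` / ``"algorithm"``.
    """

    slide_id: str
    annotator_id: str
    x: float
    y: float
    grade: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "grade", _check_grade(self.grade))
        for name in ("x", "y"):
            v = float(getattr(self, name))
            if not isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class ThsRecord:
    """THS of one (slide, rater) pair with its EIPH call."""

    slide_id: str
    rater_id: str
    n_cells: int
    ths: float
    eiph_positive: bool


def grade_from_content(
    p: float, thresholds: Sequence[float] = CANONICAL_THRESHOLDS
) -> int:
    """Bin a continuous pigment-content fraction into a discrete grade.

    The grade is the number of thresholds less than or equal to ``p``
    (half-open bins, lower-inclusive): content exactly at a threshold earns
    the higher grade.
    """
    p = float(p)
    if not isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"content must be in [0, 1], got {p}")
    thr = _validated_thresholds(thresholds)
    return bisect_right(thr, p)


def grades_from_content(
    p: np.ndarray, thresholds: Sequence[float] = CANONICAL_THRESHOLDS
) -> np.ndarray:
    """Vectorised :func:`grade_from_content`."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("content values must be in [0, 1]")
    thr = np.asarray(_validated_thresholds(thresholds))
    return np.searchsorted(thr, p, side="right").astype(int)


def _validated_thresholds(thresholds: Sequence[float]) -> list[float]:
    thr = [float(t) for t in thresholds]
    if len(thr) != 4:
        raise ValueError("exactly 4 grade thresholds required")
    if any(not (0.0 < t < 1.0) for t in thr) or any(
        a >= b for a, b in zip(thr, thr[1:])
    ):
        raise ValueError("thresholds must be strictly ascending within (0, 1)")
    return thr


def classify_eiph(ths: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """EIPH call from a THS: positive iff ``ths >= cutoff``.

    A score exactly at the cut-off is positive (the diagnosis is stated as
    "THS < or >= 75").
    """
    ths = float(ths)
    if not isfinite(ths):
        raise ValueError("THS must be finite")
    if ths < 0.0 or ths > 400.0:
        raise ValueError(f"THS out of range [0, 400]: {ths}")
    return ths >= float(cutoff)


def compute_ths(
    annotations: Iterable[CellAnnotation],
    min_cells: int = MIN_CELLS,
    allow_fewer: bool = False,
    cutoff: float = DEFAULT_CUTOFF,
) -> ThsRecord:
    """Compute the THS of one rater on one slide.

    All annotated cells are used (not only the first 300).  Raises
    ``ValueError("no annotations")`` on empty input and
    :class:`InsufficientCellsError` when fewer than ``min_cells`` cells were
    enumerated and ``allow_fewer`` is false — mirroring the protocol that
    excludes slides with fewer than 300 scorable macrophages.
    """
    ann = list(annotations)
    if not ann:
        raise ValueError("no annotations")
    slide_ids = {a.slide_id for a in ann}
    rater_ids = {a.annotator_id for a in ann}
    if len(slide_ids) != 1 or len(rater_ids) != 1:
        raise ValueError(
            f"annotations must share one slide and one rater, got slides "
            f"{sorted(slide_ids)} and raters {sorted(rater_ids)}"
        )
    n = len(ann)
    if n < min_cells and not allow_fewer:
        raise InsufficientCellsError(
            f"insufficient cells: {n} < {min_cells} annotated macrophages"
        )
    ths = 100.0 * float(np.mean([a.grade for a in ann]))
    return ThsRecord(
        slide_id=slide_ids.pop(),
        rater_id=rater_ids.pop(),
        n_cells=n,
        ths=ths,
        eiph_positive=classify_eiph(ths, cutoff),
    )


def mean_annotator_ths(records: Sequence[ThsRecord]) -> float:
    """Mean of the annotators' THSs for one slide (the consensus reference).

    Reserved raters ("ground_truth", "algorithm") are rejected: the mean
    annotators' THS averages out the systematic error *between humans* and
    must not be diluted by the reference sets themselves.
    """
    if not records:
        raise ValueError("no records")
    if len({r.slide_id for r in records}) != 1:
        raise ValueError("records must all belong to one slide")
    bad = [r.rater_id for r in records if r.rater_id in RESERVED_RATER_IDS]
    if bad:
        raise ValueError(f"reserved rater ids not allowed: {bad}")
    return float(np.mean([r.ths for r in records]))
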