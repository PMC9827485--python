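"""Point-annotation matching, grade standardization, and grade confusion.

Two raters' spot annotations of the same slide are compared by pairing
annotations whose centroids are at most 50 px apart (at 0.25 um/px, i.e.
12.5 um — roughly one macrophage diameter).  Pairing is a one-to-one,
maximum-cardinality assignment of minimum total Euclidean distance, so a
single reference cell can never absorb several annotations.

``standardize_grades`` rebuilds a rater's annotation set with the matched
reference grades substituted for the rater's own grades (unmatched
annotations are dropped), which isolates cell-*selection* disagreement from
hemosiderin-*grading* disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .scoring import GRADES, CellAnnotation

DEFAULT_MATCH_RADIUS = 50.0


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing between two annotation sets of a slide.

    ``pairs`` holds ``(index_a, index_b, distance)`` triples referring to the
    input lists; ``unmatched_a``/``unmatched_b`` hold leftover indices.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    max_distance: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))

    def matched_fraction_a(self) -> float:
        n = len(self.pairs) + len(self.unmatched_a)
        return len(self.pairs) / n if n else 0.0


def _coords(annotations: Sequence[CellAnnotation]) -> np.ndarray:
    return np.array([[a.x, a.y] for a in annotations], dtype=float).reshape(-1, 2)


def _check_same_slide(
    set_a: Sequence[CellAnnotation], set_b: Sequence[CellAnnotation]
) -> None:
    slides = {a.slide_id for a in set_a} | {b.slide_id for b in set_b}
    if len(slides) > 1:
        raise ValueError(f"annotation sets mix slides: {sorted(slides)}")


def match_annotations(
    set_a: Sequence[CellAnnotation],
    set_b: Sequence[CellAnnotation],
    max_distance: float = DEFAULT_MATCH_RADIUS,
) -> MatchResult:
    """Optimally pair two annotation sets within a distance threshold.

    Returns the one-to-one assignment of maximum cardinality and, among
    those, minimum total Euclidean distance, restricted to candidate pairs
    with distance <= ``max_distance``.  The radius test compares squared
    distances so behaviour at exactly 50 px is not subject to square-root
    rounding.  Exact ties between optimal assignments are broken towards
    lower input indices via an infinitesimal index-ordered perturbation.
    """
    _check_same_slide(set_a, set_b)
    na, nb = len(set_a), len(set_b)
    if na == 0 or nb == 0:
        return MatchResult((), tuple(range(na)), tuple(range(nb)), max_distance)

    xa, xb = _coords(set_a), _coords(set_b)
    r2 = float(max_distance) * float(max_distance)

    # Sparse candidate graph: only pairs within the radius can ever match.
    tree_b = cKDTree(xb)
    cand_a: list[int] = []
    cand_b: list[int] = []
    cand_d: list[float] = []
    for i, neighbours in enumerate(tree_b.query_ball_point(xa, float(max_distance))):
        for j in sorted(neighbours):
            dx = xa[i, 0] - xb[j, 0]
            dy = xa[i, 1] - xb[j, 1]
            d2 = dx * dx + dy * dy
            if d2 <= r2:  # exact squared-distance boundary test
                cand_a.append(i)
                cand_b.append(j)
                cand_d.append(float(np.sqrt(d2)))

    if not cand_a:
        return MatchResult((), tuple(range(na)), tuple(range(nb)), max_distance)

    # Independent connected components of the bipartite candidate graph can
    # be solved separately; with realistic cell spacing they are tiny.
    adj = coo_matrix(
        (np.ones(len(cand_a)), (cand_a, [j + na for j in cand_b])),
        shape=(na + nb, na + nb),
    )
    n_comp, labels = connected_components(adj, directed=False)

    edges_by_comp: dict[int, list[tuple[int, int, float]]] = {}
    for i, j, d in zip(cand_a, cand_b, cand_d):
        edges_by_comp.setdefault(labels[i], []).append((i, j, d))

    pairs: list[tuple[int, int, float]] = []
    for comp_edges in edges_by_comp.values():
        pairs.extend(_solve_component(comp_edges, max_distance))

    pairs.sort(key=lambda p: p[0])
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_a=tuple(i for i in range(na) if i not in matched_a),
        unmatched_b=tuple(j for j in range(nb) if j not in matched_b),
        max_distance=max_distance,
    )


def _solve_component(
    edges: list[tuple[int, int, float]], max_distance: float
) -> list[tuple[int, int, float]]:
    """Optimal assignment within one candidate-graph component."""
    rows = sorted({i for i, _, _ in edges})
    cols = sorted({j for _, j, _ in edges})
    ri = {i: k for k, i in enumerate(rows)}
    cj = {j: k for k, j in enumerate(cols)}
    na, nb = len(rows), len(cols)

    # Forbidden-pair cost large enough that dropping a feasible pair can
    # never pay off; the tie-break perturbation is too small to ever
    # outweigh a real distance difference within the component.
    big = float(max_distance) * min(na, nb) + 1.0
    eps = 1e-9 / (na * nb + 1)
    cost = np.full((na, nb), big)
    true_d = np.full((na, nb), np.nan)
    for i, j, d in edges:
        a, b = ri[i], cj[j]
        cost[a, b] = d + eps * (a * nb + b)
        true_d[a, b] = d
    row_ind, col_ind = linear_sum_assignment(cost)
    return [
        (rows[a], cols[b], float(true_d[a, b]))
        for a, b in zip(row_ind, col_ind)
        if np.isfinite(true_d[a, b])
    ]


def standardize_grades(
    annotator_set: Sequence[CellAnnotation],
    reference_set: Sequence[CellAnnotation],
    max_distance: float = DEFAULT_MATCH_RADIUS,
) -> list[CellAnnotation]:
    """Exchange a rater's grades for the matched reference grades.

    Output keeps the rater's coordinates and id but carries the grade of the
    matched reference cell; annotations without a reference match are
    excluded (they cannot be grade-standardized).
    """
    if not reference_set:
        raise ValueError("empty reference set")
    _check_same_slide(annotator_set, reference_set)
    match = match_annotations(annotator_set, reference_set, max_distance)
    out = []
    for ia, jb, _ in match.pairs:
        a = annotator_set[ia]
        out.append(
            CellAnnotation(
                slide_id=a.slide_id,
                annotator_id=a.annotator_id,
                x=a.x,
                y=a.y,
                grade=reference_set[jb].grade,
            )
        )
    return out


@dataclass(frozen=True)
class GradeConfusion:
    """5x5 grade agreement over matched pairs (rows = rater A, cols = B)."""

    matrix: np.ndarray = field(repr=False)
    accuracy: float
    one_off_fraction: float
    a_higher_fraction: float
    #: True when there were no divergent pairs, in which case the divergent
    #: fractions are reported as 0 but carry no information.
    no_divergent: bool

    @property
    def n_pairs(self) -> int:
        return int(self.matrix.sum())


def grade_confusion(
    match: MatchResult,
    set_a: Sequence[CellAnnotation],
    set_b: Sequence[CellAnnotation],
) -> GradeConfusion:
    """Tabulate grade agreement over the matched pairs of two raters."""
    if not match.pairs:
        raise ValueError("no matched cells")
    m = np.zeros((len(GRADES), len(GRADES)), dtype=int)
    for ia, jb, _ in match.pairs:
        m[set_a[ia].grade, set_b[jb].grade] += 1
    total = int(m.sum())
    agree = int(np.trace(m))
    divergent = total - agree
    if divergent == 0:
        return GradeConfusion(m, 1.0, 0.0, 0.0, True)
    one_off = int(sum(m[g, g + 1] + m[g + 1, g] for g in range(len(GRADES) - 1)))
    a_higher = int(np.tril(m, k=-1).sum())
    return GradeConfusion(
        matrix=m,
        accuracy=agree / total,
        one_off_fraction=one_off / divergent,
        a_higher_fraction=a_higher / divergent,
        no_divergent=False,
    )
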