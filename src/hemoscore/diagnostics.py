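"""Diagnostic accuracy, rater consensus, and chemistry correlations.

Accuracy is agreement of the EIPH call (THS above/below the cut-off) with a
reference scoring of the same slides — the ground truth THS or the mean
annotators' THS.  Consensus asks how often at least k of A raters agree on
the call per slide.  Rank correlations (Spearman, average ranks for ties)
relate THS methods to observer-independent BALF chemistry; iron values below
the detection limit enter as ties at the limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .agreement import ThsTable, UncertaintyInterval
from .scoring import DEFAULT_CUTOFF, ThsRecord


@dataclass(frozen=True)
class DiagnosticReport:
    """Aggregate diagnostic summary of a (simulated) study."""

    reference_id: str
    per_rater_accuracy: Mapping[str, float]
    pooled_accuracy: float
    consensus: Mapping[int, float]
    correlations: Mapping[tuple[str, str], float]


def diagnostic_accuracy(
    ths_records: Sequence[ThsRecord],
    reference: Sequence[ThsRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[dict[str, float], float]:
    """Per-rater and pooled EIPH-call accuracy against a reference scoring.

    Every rater must cover every reference slide.  The pooled accuracy is
    the observation-level mean over all rater x slide calls, which equals
    the mean of per-rater accuracies in a complete design.
    """
    ref_call = {r.slide_id: r.ths >= cutoff for r in reference}
    raters = sorted({r.rater_id for r in ths_records})
    per_rater: dict[str, float] = {}
    n_total = 0
    n_correct = 0
    for rater in raters:
        mine = {r.slide_id: r.ths >= cutoff for r in ths_records if r.rater_id == rater}
        missing = set(ref_call) - set(mine)
        if missing:
            raise ValueError(f"rater {rater} missing slides: {sorted(missing)[:5]}")
        hits = sum(mine[s] == ref_call[s] for s in ref_call)
        per_rater[rater] = hits / len(ref_call)
        n_correct += hits
        n_total += len(ref_call)
    pooled = n_correct / n_total if n_total else float("nan")
    return per_rater, pooled


def consensus_fraction(
    table: ThsTable, cutoff: float = DEFAULT_CUTOFF, k: int = 8
) -> float:
    """Fraction of slides where >= k of the A raters agree on the EIPH call."""
    A = len(table.annotators)
    if not (1 <= k <= A):
        raise ValueError(f"k must be in [1, {A}]")
    positive = (table.values >= cutoff).sum(axis=1)
    majority = np.maximum(positive, A - positive)
    return float(np.mean(majority >= k))


def consensus_curve(
    table: ThsTable, cutoff: float = DEFAULT_CUTOFF
) -> dict[int, float]:
    """Consensus fraction for every k = 1..A (non-increasing in k)."""
    return {
        k: consensus_fraction(table, cutoff, k)
        for k in range(1, len(table.annotators) + 1)
    }


def rank_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    y_censored: Sequence[bool] | None = None,
    detection_limit: float = 0.4,
) -> float:
    """Spearman rank correlation with average ranks for ties.

    Chemistry values flagged as censored are set to the detection limit so
    they tie at the bottom of the ranking.  Returns NaN (the undefined flag)
    when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).copy()
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if y_censored is not None:
        y[np.asarray(y_censored, dtype=bool)] = detection_limit
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def uncertainty_consensus_split(
    table: ThsTable, interval: UncertaintyInterval, k: int
) -> tuple[float, float]:
    """Consensus rate of rater THSs inside vs outside the uncertainty band.

    For every rater x slide observation, asks whether that slide reached
    >= k-of-A consensus, split by whether the observation's THS lies inside
    ``[interval.lower, interval.upper]``.  On calibrated studies, scores
    outside the band should reach consensus far more often.
    """
    A = len(table.annotators)
    positive = (table.values >= interval.cutoff).sum(axis=1)
    consensual = np.maximum(positive, A - positive) >= k
    inside = (table.values >= interval.lower) & (table.values <= interval.upper)
    consensual_obs = np.broadcast_to(consensual[:, None], table.values.shape)
    with np.errstate(invalid="ignore"):
        rate_inside = (
            float(consensual_obs[inside].mean()) if inside.any() else float("nan")
        )
        outside = ~inside
        rate_outside = (
            float(consensual_obs[outside].mean()) if outside.any() else float("nan")
        )
    return rate_inside, rate_outside


def build_report(
    reference_id: str,
    rater_records: Sequence[ThsRecord],
    reference_records: Sequence[ThsRecord],
    table: ThsTable,
    correlations: Mapping[tuple[str, str], float] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> DiagnosticReport:
    """Assemble the diagnostic summary for one reference method."""
    per_rater, pooled = diagnostic_accuracy(rater_records, reference_records, cutoff)
    return DiagnosticReport(
        reference_id=reference_id,
        per_rater_accuracy=per_rater,
        pooled_accuracy=pooled,
        consensus=consensus_curve(table, cutoff),
        correlations=dict(correlations or {}),
    )
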