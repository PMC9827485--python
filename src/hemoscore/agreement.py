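"""Interobserver agreement: variance components, ICC, and the diagnostic
uncertainty interval.

The study design is fully crossed — every annotator scores every slide once —
so the THS decomposes as

    y_sa = mu + slide_s + annotator_a + e_sa,

with independent random slide effects (true severity differences), annotator
effects (systematic grading bias: a rater who applies lower grade thresholds
is consistently high on every slide) and residual error (within-rater
inconsistency plus cell-selection noise).

Two variance-ratio summaries are reported because the literature uses "ICC"
for both: ``icc_agreement`` = sigma2_slide / total (the conventional
single-measure agreement ICC, ICC(A,1)) and ``error_partition`` =
sigma2_annotator / (sigma2_annotator + sigma2_residual), the share of the
*measurement error* that is systematic rather than random.

The 80% uncertainty interval maps the 10% and 90% quantiles of the
annotators' measurement errors around the diagnostic cut-off: a single
rater's THS inside this band does not reproducibly yield the consensus
EIPH call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .scoring import DEFAULT_CUTOFF, ThsRecord


@dataclass(frozen=True)
class ThsTable:
    """Complete slides x annotators THS matrix (fully crossed, one score per
    cell of the design)."""

    slides: tuple[str, ...]
    annotators: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.slides), len(self.annotators)):
            raise ValueError("values shape must be (n_slides, n_annotators)")
        if np.any(~np.isfinite(v)):
            raise ValueError("incomplete design: missing THS values")
        if np.any(v < 0) or np.any(v > 400):
            raise ValueError("THS values outside [0, 400]")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_records(cls, records: Sequence[ThsRecord]) -> "ThsTable":
        """Pivot (slide, rater) THS records into a complete table."""
        df = pd.DataFrame(
            [(r.slide_id, r.rater_id, r.ths) for r in records],
            columns=["slide_id", "rater_id", "ths"],
        )
        wide = df.pivot(index="slide_id", columns="rater_id", values="ths")
        if wide.isna().any().any():
            missing = int(wide.isna().sum().sum())
            raise ValueError(f"incomplete design: {missing} missing cells")
        return cls(tuple(wide.index), tuple(wide.columns), wide.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.slides), columns=list(self.annotators)
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("slide_id").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ThsTable":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index.astype(str)), tuple(df.columns), df.to_numpy())


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variances (score-points squared) and derived ratios."""

    sigma2_slide: float
    sigma2_annotator: float
    sigma2_residual: float
    icc_agreement: float
    error_partition: float
    #: Set when all components vanish (constant table); ratios are then
    #: reported as 0 but are 0/0 in substance.
    degenerate: bool = False
    method: str = "anova_mom"


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    S, A = values.shape
    grand = values.mean()
    slide_means = values.mean(axis=1)
    annot_means = values.mean(axis=0)
    mss = A * np.sum((slide_means - grand) ** 2) / (S - 1)
    msa = S * np.sum((annot_means - grand) ** 2) / (A - 1)
    resid = values - slide_means[:, None] - annot_means[None, :] + grand
    mse = np.sum(resid**2) / ((S - 1) * (A - 1))
    return float(mss), float(msa), float(mse)


def variance_components(
    table: ThsTable, method: str = "anova_mom"
) -> VarianceComponents:
    """Two-way crossed random-effects decomposition of a THS table.

    ``anova_mom`` (the reference method) solves the expected-mean-square
    equations of the balanced design: sigma2_e = MSE, sigma2_annotator =
    (MSA - MSE) / S, sigma2_slide = (MSS - MSE) / A, with negative solutions
    truncated to zero.  ``reml`` maximises the residual likelihood using the
    exact three-strata spectral form of the balanced crossed design.
    """
    S, A = table.values.shape
    if S < 2 or A < 2:
        raise ValueError(f"need >= 2 slides and >= 2 annotators, got S={S}, A={A}")
    if method == "anova_mom":
        mss, msa, mse = _mean_squares(table.values)
        s2_e = mse
        s2_a = (msa - mse) / S
        s2_s = (mss - mse) / A
        if s2_a < 0 or s2_s < 0:
            warnings.warn(
                "negative method-of-moments variance estimate truncated to 0",
                stacklevel=2,
            )
        s2_a, s2_s = max(s2_a, 0.0), max(s2_s, 0.0)
    elif method == "reml":
        s2_s, s2_a, s2_e = _reml_balanced(table.values)
    else:
        raise ValueError(f"unknown method {method!r}")

    total = s2_s + s2_a + s2_e
    err = s2_a + s2_e
    degenerate = total <= 0.0
    return VarianceComponents(
        sigma2_slide=float(s2_s),
        sigma2_annotator=float(s2_a),
        sigma2_residual=float(s2_e),
        icc_agreement=0.0 if degenerate else float(s2_s / total),
        error_partition=0.0 if err <= 0.0 else float(s2_a / err),
        degenerate=degenerate,
        method=method,
    )


def _reml_balanced(values: np.ndarray) -> tuple[float, float, float]:
    """REML for the balanced crossed design via its spectral decomposition.

    After removing the grand mean, the data split into three orthogonal
    strata with i.i.d. normal coordinates: slide contrasts (variance
    sigma2_e + A*sigma2_s), annotator contrasts (sigma2_e + S*sigma2_a) and
    interaction residuals (sigma2_e); the restricted likelihood is the
    product of the three strata likelihoods.
    """
    S, A = values.shape
    mss, msa, mse = _mean_squares(values)
    ss = np.array([mss * (S - 1), msa * (A - 1), mse * (S - 1) * (A - 1)])
    df = np.array([S - 1, A - 1, (S - 1) * (A - 1)], dtype=float)

    def neg2_reml(log_sigma2: np.ndarray) -> float:
        s2_s, s2_a, s2_e = np.exp(log_sigma2)
        lam = np.array([s2_e + A * s2_s, s2_e + S * s2_a, s2_e])
        return float(np.sum(df * np.log(lam) + ss / lam))

    scale = max(mse, 1e-8)
    x0 = np.log(
        [max((mss - mse) / A, scale * 1e-3), max((msa - mse) / S, scale * 1e-3), scale]
    )
    res = minimize(neg2_reml, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    s2 = np.exp(res.x)
    # Components pushed to the boundary come back as numerical zeros.
    s2[s2 < scale * 1e-6] = 0.0
    return float(s2[0]), float(s2[1]), float(s2[2])


@dataclass(frozen=True)
class ErrorReduction:
    """Percentage reduction in measurement-error variance after grade
    standardization (raw vs standardized THS tables)."""

    overall_pct: float | None
    between_annotator_pct: float | None
    residual_pct: float | None

    def as_dict(self) -> Mapping[str, float | None]:
        return {
            "overall_pct": self.overall_pct,
            "between_annotator_pct": self.between_annotator_pct,
            "residual_pct": self.residual_pct,
        }


def error_reduction(raw: ThsTable, standardized: ThsTable) -> ErrorReduction:
    """Error-variance reduction attributable to grade standardization.

    Fits the variance decomposition to both tables; each reduction is
    1 - (component_std / component_raw), in percent.  A reduction whose raw
    component is zero is undefined and reported as ``None``.
    """
    if raw.slides != standardized.slides or raw.annotators != standardized.annotators:
        raise ValueError("raw and standardized tables must share slides/annotators")
    vc_raw = variance_components(raw)
    vc_std = variance_components(standardized)

    def pct(num: float, den: float) -> float | None:
        if den <= 0.0:
            return None
        return 100.0 * (1.0 - num / den)

    return ErrorReduction(
        overall_pct=pct(
            vc_std.sigma2_annotator + vc_std.sigma2_residual,
            vc_raw.sigma2_annotator + vc_raw.sigma2_residual,
        ),
        between_annotator_pct=pct(vc_std.sigma2_annotator, vc_raw.sigma2_annotator),
        residual_pct=pct(vc_std.sigma2_residual, vc_raw.sigma2_residual),
    )


def measurement_errors(table: ThsTable) -> np.ndarray:
    """Signed deviations of each rater's THS from the slide's mean THS.

    Returns the flattened S x A array (slide-major order) of
    ``e_sa = y_sa - mean_a(y_s.)``; within each slide the errors sum to 0.
    """
    return (table.values - table.values.mean(axis=1, keepdims=True)).ravel()


@dataclass(frozen=True)
class UncertaintyInterval:
    """Quantile band of rater measurement errors mapped around the cut-off.

    Individual THSs inside ``[lower, upper]`` fail to reproduce the consensus
    EIPH call with at least ``coverage`` probability.
    """

    q_low: float
    q_high: float
    lower: float
    upper: float
    coverage: float
    cutoff: float


def uncertainty_interval(
    errors: Sequence[float] | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    coverage: float = 0.8,
) -> UncertaintyInterval:
    """Diagnostic uncertainty interval from rater measurement errors.

    ``q_low``/``q_high`` are the (1-coverage)/2 and 1-(1-coverage)/2
    quantiles (linear interpolation of order statistics, the numpy default
    convention); the interval is the cut-off shifted by those quantiles.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 measurement errors")
    if not (0.0 < coverage < 1.0):
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    alpha = (1.0 - coverage) / 2.0
    q_low, q_high = np.quantile(errors, [alpha, 1.0 - alpha], method="linear")
    return UncertaintyInterval(
        q_low=float(q_low),
        q_high=float(q_high),
        lower=float(cutoff + q_low),
        upper=float(cutoff + q_high),
        coverage=float(coverage),
        cutoff=float(cutoff),
    )
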