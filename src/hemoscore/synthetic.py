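"""Synthetic EIPH study generator: slides, annotators, chemistry, images.

Emulates the structure of a two-stain cytologic EIPH study so the whole
scoring/agreement pipeline can be exercised at desk scale with a known ground
truth:

* paired slides (one Prussian-blue, one Turnbull-blue preparation per BALF
  sample; 26 pairs by default) whose macrophage counts fall in the reported
  596-8954 per-slide range;
* per-cell continuous hemosiderin content drawn from a severity-indexed
  two-component Beta mixture, discretised into grades 0-4 by the canonical
  content thresholds;
* simulated annotators with *systematic* grading bias (a signed shift applied
  to their personal grade thresholds), *random* per-cell perception noise,
  distinct cell-selection patterns, coordinate jitter, and a configurable
  rate of misidentified non-macrophages (matching the reported ~23% of
  annotations without a ground-truth match);
* BALF chemistry (iron, censored below the 0.4 umol/L detection limit, plus
  RBC count and hemoglobin that are deliberately independent of the THS —
  they mark acute, not chronic, hemorrhage);
* rendered RGB images of iron-stained slides with a per-cell registry, for
  the rule-based image grader.

Cells are placed on a jittered grid whose pitch guarantees a minimum centre
spacing of 110 px (> 2x the 50 px matching radius), so annotation matching
is geometrically unambiguous at defaults.  All randomness flows from numpy
``SeedSequence`` substreams: one master seed reproduces every slide,
annotator and image byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import ellipse as _draw_ellipse

from .scoring import CANONICAL_THRESHOLDS, CellAnnotation, grades_from_content

STAINS = ("prussian_blue", "turnbull_blue")
SELECTION_PATTERNS = ("uniform_random", "clustered_fields", "meander")

#: Pixel scale of the emulated scans (documentation only; all distances in px).
MICRONS_PER_PX = 0.25


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _subseed(master: int, *key: int) -> np.random.SeedSequence:
    """Independent, order-stable substream of a master seed."""
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(key))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GroundTruthCell:
    """One generated cell: location, continuous pigment content, grade."""

    slide_id: str
    cell_id: str
    x: float
    y: float
    content: float
    grade: int
    is_macrophage: bool


@dataclass(frozen=True)
class SlideManifest:
    """Per-slide metadata: stain, severity, geometry, chemistry."""

    slide_id: str
    stain: str
    severity: float
    n_macrophages: int
    width: int
    height: int
    sample_id: str = ""
    iron: float | None = None          # umol/L; detection-limit value if censored
    iron_censored: bool = False
    rbc: float | None = None           # cells/uL BALF
    hemoglobin: float | None = None    # g/L BALF

    def __post_init__(self) -> None:
        if self.stain not in STAINS:
            raise ValueError(f"stain must be one of {STAINS}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")
        if self.n_macrophages < 1:
            raise ValueError("n_macrophages must be >= 1")
        if self.iron is not None and self.iron < 0:
            raise ValueError("iron must be >= 0")


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioural model of one simulated rater.

    ``threshold_shift`` is added to every canonical grade threshold: a
    negative shift lowers the thresholds and inflates the rater's grades
    (the dominant systematic error seen between human experts).
    ``perception_sd`` is random per-cell noise on the perceived pigment
    content; ``misid_rate`` is the probability that an annotation lands on a
    non-macrophage (which then carries a low grade and cannot be matched to
    the ground truth).
    """

    annotator_id: str
    threshold_shift: float = 0.0
    perception_sd: float = 0.05
    selection_pattern: str = "uniform_random"
    n_target: int = 300
    misid_rate: float = 0.23
    jitter_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.selection_pattern not in SELECTION_PATTERNS:
            raise ValueError(f"selection_pattern must be one of {SELECTION_PATTERNS}")
        if not (0.0 <= self.misid_rate < 1.0):
            raise ValueError("misid_rate must be in [0, 1)")
        if self.perception_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if abs(self.threshold_shift) >= 0.5:
            raise ValueError("threshold_shift magnitude must be < 0.5")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    """Stated-world parameters of the emulated study."""

    n_slide_pairs: int = 26
    cell_count_range: tuple[int, int] = (596, 8954)
    severity_range: tuple[float, float] = (0.0, 1.0)
    distractor_fraction: float = 0.35
    min_spacing: float = 110.0
    grid_jitter: float = 15.0
    margin: float = 60.0
    grid_occupancy: float = 0.7
    turnbull_content_bias: float = 0.0
    thresholds: tuple[float, float, float, float] = CANONICAL_THRESHOLDS

    def __post_init__(self) -> None:
        lo, hi = self.cell_count_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid cell_count_range")
        slo, shi = self.severity_range
        if not (0.0 <= slo <= shi <= 1.0):
            raise ValueError("invalid severity_range")
        if self.n_slide_pairs < 1:
            raise ValueError("n_slide_pairs must be >= 1")
        if not (0.0 < self.grid_occupancy <= 1.0):
            raise ValueError("grid_occupancy must be in (0, 1]")
        if self.min_spacing <= 0 or self.grid_jitter < 0 or self.margin < 0:
            raise ValueError("invalid geometry parameters")
        if not (0.0 <= self.distractor_fraction < 1.0):
            raise ValueError("distractor_fraction must be in [0, 1)")

    @property
    def grid_pitch(self) -> float:
        # pitch - 2*jitter >= min_spacing guarantees the spacing floor
        return self.min_spacing + 2.0 * self.grid_jitter


# ---------------------------------------------------------------------------
# study and slide generation


def _extent_for(config: StudyConfig, n_cells_total: int) -> tuple[int, int]:
    cols = math.ceil(math.sqrt(n_cells_total / config.grid_occupancy))
    side = math.ceil(cols * config.grid_pitch + 2 * config.margin)
    return side, side


def generate_study(
    config: StudyConfig, seed: int
) -> tuple[list[SlideManifest], list[GroundTruthCell]]:
    """Generate manifests and ground-truth cells for a full two-stain study.

    Each BALF sample yields one Prussian-blue and one Turnbull-blue slide
    sharing the sample's severity; per-slide macrophage counts are drawn
    uniformly from ``cell_count_range``.  Deterministic under ``seed``.
    """
    study_rng = _rng(_subseed(seed, 0))
    manifests: list[SlideManifest] = []
    cells: list[GroundTruthCell] = []
    slo, shi = config.severity_range
    lo, hi = config.cell_count_range
    idx = 0
    for pair in range(config.n_slide_pairs):
        sample_id = f"B{pair + 1:02d}"
        severity = float(study_rng.uniform(slo, shi))
        for stain in STAINS:
            n_macro = int(study_rng.integers(lo, hi + 1))
            n_total = n_macro + int(round(config.distractor_fraction * n_macro))
            width, height = _extent_for(config, n_total)
            suffix = "PB" if stain == "prussian_blue" else "TB"
            manifest = SlideManifest(
                slide_id=f"{sample_id}_{suffix}",
                stain=stain,
                severity=severity,
                n_macrophages=n_macro,
                width=width,
                height=height,
                sample_id=sample_id,
            )
            manifests.append(manifest)
            cells.extend(generate_slide(manifest, _subseed(seed, 1, idx), config=config))
            idx += 1
    return manifests, cells


def generate_slide(
    manifest: SlideManifest, seed, config: StudyConfig | None = None
) -> list[GroundTruthCell]:
    """Realise the ground-truth cells of one slide.

    Macrophage pigment content is drawn from the severity-indexed mixture; a
    ``distractor_fraction`` of additional non-macrophage leukocytes (low
    pigment, excluded from the ground-truth annotation set) is interleaved.
    Cell centres sit on a jittered square grid so that no two centres are
    closer than ``min_spacing``.  Raises if the declared extent cannot hold
    the requested cells at that spacing.
    """
    config = config or StudyConfig()
    rng = _rng(seed)
    n_macro = manifest.n_macrophages
    n_distract = int(round(config.distractor_fraction * n_macro))
    n_total = n_macro + n_distract

    pitch = config.grid_pitch
    cols = int((manifest.width - 2 * config.margin) // pitch) + 1
    rows = int((manifest.height - 2 * config.margin) // pitch) + 1
    if cols < 1 or rows < 1 or cols * rows < n_total:
        raise ValueError(
            f"extent too small: {cols * rows} grid sites for {n_total} cells "
            f"at spacing {config.min_spacing}"
        )

    sites = rng.choice(cols * rows, size=n_total, replace=False)
    gx = config.margin + (sites % cols) * pitch
    gy = config.margin + (sites // cols) * pitch
    jit = rng.uniform(-config.grid_jitter, config.grid_jitter, size=(n_total, 2))
    xs = np.clip(gx + jit[:, 0], 0.0, manifest.width - 1.0)
    ys = np.clip(gy + jit[:, 1], 0.0, manifest.height - 1.0)

    content = np.empty(n_total)
    content[:n_macro] = _draw_macrophage_content(rng, n_macro, manifest.severity)
    content[n_macro:] = _draw_distractor_content(rng, n_distract)
    if manifest.stain == "turnbull_blue" and config.turnbull_content_bias:
        content[:n_macro] = np.clip(
            content[:n_macro] + config.turnbull_content_bias, 0.0, 1.0
        )
    grades = grades_from_content(content, config.thresholds)

    out = []
    for i in range(n_total):
        is_macro = i < n_macro
        out.append(
            GroundTruthCell(
                slide_id=manifest.slide_id,
                cell_id=f"{manifest.slide_id}_c{i:05d}",
                x=float(xs[i]),
                y=float(ys[i]),
                content=float(content[i]),
                grade=int(grades[i]),
                is_macrophage=is_macro,
            )
        )
    return out


def _draw_macrophage_content(
    rng: np.random.Generator, n: int, severity: float
) -> np.ndarray:
    """Severity-indexed two-component Beta mixture of pigment content.

    With probability ``severity`` a cell carries pigment from a high-content
    Beta component whose mean rises with severity; otherwise it comes from a
    low component bounded below the grade-1 threshold, so a severity-0 slide
    is uniformly grade 0.
    """
    high = rng.random(n) < severity
    content = 0.0199 * rng.beta(1.0, 3.0, size=n)  # strictly below 0.02
    n_high = int(high.sum())
    if n_high:
        a = 1.0 + 4.0 * severity
        b = 5.0 - 3.0 * severity
        content[high] = rng.beta(a, b, size=n_high)
    return content


def _draw_distractor_content(rng: np.random.Generator, n: int) -> np.ndarray:
    # other leukocytes: essentially pigment-free (grade 0, rarely 1)
    return 0.04 * rng.beta(1.0, 3.0, size=n)


def ground_truth_annotations(
    cells: Iterable[GroundTruthCell],
) -> list[CellAnnotation]:
    """Reference annotation set: every macrophage, labelled "ground_truth"."""
    return [
        CellAnnotation(c.slide_id, "ground_truth", c.x, c.y, c.grade)
        for c in cells
        if c.is_macrophage
    ]


# ---------------------------------------------------------------------------
# simulated annotators


def shift_thresholds(
    thresholds: Sequence[float], shift: float
) -> tuple[float, ...]:
    """Apply a rater's signed threshold shift, keeping bins valid."""
    shifted = np.clip(np.asarray(thresholds, dtype=float) + shift, 1e-6, 1.0 - 1e-6)
    # re-impose strict ascent if clipping collapsed the extreme bins
    for i in range(1, len(shifted)):
        if shifted[i] <= shifted[i - 1]:
            shifted[i] = shifted[i - 1] + 1e-9
    return tuple(float(t) for t in shifted)


def simulate_annotator(
    cells: Sequence[GroundTruthCell],
    profile: AnnotatorProfile,
    seed,
    match_radius: float = 50.0,
    thresholds: Sequence[float] = CANONICAL_THRESHOLDS,
) -> list[CellAnnotation]:
    """Simulate one rater's annotation set on one slide.

    Selects ``n_target`` cells following the rater's selection pattern; a
    binomial ``misid_rate`` share of them are misidentified non-macrophages
    (placed at distractor cells, hence >= ``match_radius`` from every true
    macrophage at default spacing).  Perceived content = true content plus
    Gaussian noise; the grade comes from the rater's shifted thresholds.
    Coordinates are jittered, truncated just inside the matching radius so
    genuinely annotated macrophages always remain matchable.
    """
    rng = _rng(seed)
    macros = [c for c in cells if c.is_macrophage]
    distractors = [c for c in cells if not c.is_macrophage]
    if len({c.slide_id for c in cells}) != 1:
        raise ValueError("cells must belong to a single slide")
    if profile.n_target > len(macros):
        raise ValueError(
            f"n_target {profile.n_target} exceeds {len(macros)} available macrophages"
        )

    n_misid = int(rng.binomial(profile.n_target, profile.misid_rate))
    if n_misid > len(distractors):
        raise ValueError(
            f"{n_misid} misidentified annotations requested but only "
            f"{len(distractors)} non-macrophage cells are available"
        )
    n_real = profile.n_target - n_misid

    selected = _select_cells(rng, macros, n_real, profile.selection_pattern)
    if n_misid:
        picks = rng.choice(len(distractors), size=n_misid, replace=False)
        selected = selected + [distractors[int(i)] for i in picks]

    own_thresholds = shift_thresholds(thresholds, profile.threshold_shift)
    jitter_cap = 0.98 * match_radius
    out = []
    for cell in selected:
        perceived = float(
            np.clip(cell.content + rng.normal(0.0, profile.perception_sd), 0.0, 1.0)
        )
        grade = int(np.searchsorted(own_thresholds, perceived, side="right"))
        dx, dy = rng.normal(0.0, profile.jitter_sd, size=2)
        norm = math.hypot(dx, dy)
        if norm > jitter_cap:
            dx, dy = dx * jitter_cap / norm, dy * jitter_cap / norm
        out.append(
            CellAnnotation(
                slide_id=cell.slide_id,
                annotator_id=profile.annotator_id,
                x=max(0.0, cell.x + dx),
                y=max(0.0, cell.y + dy),
                grade=grade,
            )
        )
    return out


def _select_cells(
    rng: np.random.Generator,
    macros: Sequence[GroundTruthCell],
    n: int,
    pattern: str,
    field_radius: float = 400.0,
    band_height: float = 300.0,
) -> list[GroundTruthCell]:
    if n == 0:
        return []
    if pattern == "uniform_random":
        idx = rng.choice(len(macros), size=n, replace=False)
        return [macros[int(i)] for i in idx]
    if pattern == "clustered_fields":
        coords = np.array([[c.x, c.y] for c in macros])
        tree = cKDTree(coords)
        chosen: list[int] = []
        taken = np.zeros(len(macros), dtype=bool)
        while len(chosen) < n:
            centre = int(rng.integers(len(macros)))
            for i in tree.query_ball_point(coords[centre], field_radius):
                if not taken[i]:
                    taken[i] = True
                    chosen.append(i)
        return [macros[i] for i in chosen[:n]]
    # meander: snake through horizontal bands, start at a random offset
    def band_key(c: GroundTruthCell) -> tuple[int, float]:
        band = int(c.y // band_height)
        return (band, c.x if band % 2 == 0 else -c.x)

    ordered = sorted(macros, key=band_key)
    start = int(rng.integers(len(ordered)))
    return [ordered[(start + k) % len(ordered)] for k in range(n)]


def make_default_profiles(
    n_annotators: int = 10,
    n_target: int = 300,
    misid_rate: float = 0.23,
    jitter_sd: float = 10.0,
) -> list[AnnotatorProfile]:
    """The default ten-rater cohort.

    Threshold shifts are evenly spaced from -0.09 to +0.01 (mean -0.04):
    mostly negative, reproducing the experts' tendency to apply lower grade
    thresholds — and hence score higher — than the ground truth.  Selection
    patterns cycle through the three observed styles.
    """
    shifts = np.linspace(-0.09, 0.01, n_annotators)
    return [
        AnnotatorProfile(
            annotator_id=f"A{k + 1:02d}",
            threshold_shift=float(shifts[k]),
            perception_sd=0.05,
            selection_pattern=SELECTION_PATTERNS[k % len(SELECTION_PATTERNS)],
            n_target=n_target,
            misid_rate=misid_rate,
            jitter_sd=jitter_sd,
        )
        for k in range(n_annotators)
    ]


# ---------------------------------------------------------------------------
# chemistry


@dataclass(frozen=True)
class ChemistryParams:
    """BALF laboratory-value model.

    Iron tracks chronic hemorrhage: baseline + slope * (THS/400) scaled by a
    mild cell-density factor, with multiplicative lognormal noise, censored
    below the 0.4 umol/L detection limit (a censored slide reports the limit
    itself plus a flag).  RBC count and hemoglobin mark *acute* bleeding and
    are simulated independently of the THS.
    """

    iron_baseline: float = 0.05     # umol/L
    iron_slope: float = 4.5         # umol/L at THS 400, reference density
    iron_noise_sigma: float = 0.6   # lognormal sigma on the THS term
    detection_limit: float = 0.4    # umol/L
    density_ref: int = 4137         # reference macrophage count (median-like)
    density_exponent: float = 0.25
    rbc_log_mean: float = math.log(200.0)   # cells/uL
    rbc_log_sigma: float = 1.0
    hgb_log_mean: float = math.log(0.15)    # g/L
    hgb_log_sigma: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "iron_baseline",
            "iron_slope",
            "iron_noise_sigma",
            "detection_limit",
            "rbc_log_sigma",
            "hgb_log_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_chemistry(
    manifest: SlideManifest,
    ground_truth_ths: float,
    params: ChemistryParams = ChemistryParams(),
    seed=0,
) -> SlideManifest:
    """Attach simulated laboratory values to a slide manifest."""
    if not (0.0 <= ground_truth_ths <= 400.0):
        raise ValueError("ground_truth_ths must be in [0, 400]")
    rng = _rng(seed)
    density = (manifest.n_macrophages / params.density_ref) ** params.density_exponent
    signal = (
        params.iron_slope
        * (ground_truth_ths / 400.0)
        * density
        * rng.lognormal(0.0, params.iron_noise_sigma)
    )
    iron = params.iron_baseline + signal
    censored = iron < params.detection_limit
    return replace(
        manifest,
        iron=params.detection_limit if censored else float(iron),
        iron_censored=bool(censored),
        rbc=float(rng.lognormal(params.rbc_log_mean, params.rbc_log_sigma)),
        hemoglobin=float(rng.lognormal(params.hgb_log_mean, params.hgb_log_sigma)),
    )


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class RenderParams:
    """Appearance of rendered iron-stained cytology images.

    Macrophages are ellipses of pale cytoplasm with a Nuclear-Fast-Red-hued
    nucleus; hemosiderin is painted as blue pixels covering a fraction of the
    cell area equal to the cell's pigment content (a small nucleus core is
    always preserved so even grade-4 cells keep a detectable nucleus).
    Non-macrophage distractors render smaller and anucleate.  The Turnbull
    variant only shifts the pigment hue.
    """

    major_axis_range: tuple[float, float] = (30.0, 38.0)
    minor_axis_range: tuple[float, float] = (24.0, 32.0)
    nucleus_axis_frac: float = 0.36
    nucleus_core_frac: float = 0.20      # core radius as a fraction of cell axes
    distractor_scale: float = 0.55
    noise_sigma: float = 2.5             # additive Gaussian, 8-bit counts
    background: tuple[int, int, int] = (246, 246, 244)
    cytoplasm: tuple[int, int, int] = (226, 216, 219)
    nucleus: tuple[int, int, int] = (202, 84, 122)
    pigment_prussian: tuple[int, int, int] = (45, 65, 150)
    pigment_turnbull: tuple[int, int, int] = (40, 92, 150)
    margin: float = 55.0

    def pigment_color(self, stain: str) -> tuple[int, int, int]:
        return self.pigment_prussian if stain == "prussian_blue" else self.pigment_turnbull


def render_slide_image(
    cells: Sequence[GroundTruthCell],
    stain: str = "prussian_blue",
    params: RenderParams = RenderParams(),
    seed=0,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Render an RGB image of a slide plus a per-cell registry.

    Returns ``(image, registry)`` where the registry records each cell's
    rendered centroid, its requested content and the pigment pixel fraction
    actually painted.  If ``shape`` (height, width) is given, cells that do
    not fit inside it raise; otherwise the extent is computed from the cells.
    """
    if stain not in STAINS:
        raise ValueError(f"stain must be one of {STAINS}")
    rng = _rng(seed)
    margin = params.margin
    if shape is None:
        if cells:
            h = int(math.ceil(max(c.y for c in cells) + margin))
            w = int(math.ceil(max(c.x for c in cells) + margin))
        else:
            h = w = int(2 * margin)
        shape = (h, w)
    else:
        h, w = shape
        req = max(params.major_axis_range)  # room for the largest ellipse
        for c in cells:
            if c.x + req > w or c.y + req > h or c.x < req or c.y < req:
                raise ValueError(f"cell {c.cell_id} overflows the {shape} extent")

    img = np.empty((h, w, 3), dtype=float)
    img[:] = params.background
    pigment_rgb = params.pigment_color(stain)

    registry: list[dict] = []
    for cell in cells:
        entry = _render_cell(img, cell, params, pigment_rgb, rng)
        registry.append(entry)

    img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), registry


def _render_cell(
    img: np.ndarray,
    cell: GroundTruthCell,
    params: RenderParams,
    pigment_rgb: tuple[int, int, int],
    rng: np.random.Generator,
) -> dict:
    scale = 1.0 if cell.is_macrophage else params.distractor_scale
    a = rng.uniform(*params.major_axis_range) * scale
    b = rng.uniform(*params.minor_axis_range) * scale
    rot = rng.uniform(0, math.pi)
    h, w = img.shape[:2]
    flat = img.reshape(-1, 3)

    rr, cc = _draw_ellipse(cell.y, cell.x, b, a, rotation=rot, shape=(h, w))
    cell_px = rr.astype(np.int64) * w + cc  # unique flat indices
    flat[cell_px] = params.cytoplasm
    n_cell = cell_px.size

    if cell.is_macrophage:
        # nucleus offset from the cell centre, core concentric with nucleus
        off = 0.25 * b
        ang = rng.uniform(0, 2 * math.pi)
        ny, nx = cell.y + off * math.sin(ang), cell.x + off * math.cos(ang)
        nrr, ncc = _draw_ellipse(
            ny, nx, b * params.nucleus_axis_frac, a * params.nucleus_axis_frac,
            rotation=rot, shape=(h, w),
        )
        nucleus_px = np.intersect1d(nrr.astype(np.int64) * w + ncc, cell_px)
        flat[nucleus_px] = params.nucleus
        crr, ccc = _draw_ellipse(
            ny, nx, b * params.nucleus_core_frac, a * params.nucleus_core_frac,
            rotation=rot, shape=(h, w),
        )
        core_px = np.intersect1d(crr.astype(np.int64) * w + ccc, nucleus_px)
    else:
        nucleus_px = np.empty(0, dtype=np.int64)
        core_px = np.empty(0, dtype=np.int64)

    # paint pigment: exact pixel count, cytoplasm first, nucleus core spared
    target = int(round(cell.content * n_cell))
    cyto = np.setdiff1d(cell_px, nucleus_px)
    nuc_paintable = np.setdiff1d(nucleus_px, core_px)
    order = np.concatenate(
        [cyto[rng.permutation(cyto.size)], nuc_paintable[rng.permutation(nuc_paintable.size)]]
    )
    k = min(target, order.size)
    flat[order[:k]] = pigment_rgb

    return {
        "cell_id": cell.cell_id,
        "x": float(cell.x),
        "y": float(cell.y),
        "content": float(cell.content),
        "pigment_fraction": k / n_cell if n_cell else 0.0,
        "grade": int(cell.grade),
        "is_macrophage": bool(cell.is_macrophage),
        "cell_area_px": n_cell,
    }
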