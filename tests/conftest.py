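"""Shared fixtures: small synthetic slides and annotation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from hemoscore import (
    AnnotatorProfile,
    CellAnnotation,
    StudyConfig,
    generate_study,
    ground_truth_annotations,
)


def make_annotations(grades, slide="s1", rater="a1", spacing=120.0):
    """Well-spaced annotations on one row, one per grade entry."""
    return [
        CellAnnotation(slide, rater, i * spacing, 0.0, int(g))
        for i, g in enumerate(grades)
    ]


@pytest.fixture(scope="session")
def small_study():
    """One slide pair, ~350 macrophages each, mid severity."""
    config = StudyConfig(
        n_slide_pairs=1, cell_count_range=(340, 360), severity_range=(0.5, 0.7)
    )
    manifests, cells = generate_study(config, seed=2024)
    by_slide = {m.slide_id: [c for c in cells if c.slide_id == m.slide_id] for m in manifests}
    return manifests, by_slide


@pytest.fixture()
def slide_cells(small_study):
    manifests, by_slide = small_study
    return by_slide[manifests[0].slide_id]


@pytest.fixture()
def identity_profile():
    """A rater with no bias, no noise, no jitter, no misidentification."""
    return AnnotatorProfile(
        annotator_id="ident",
        threshold_shift=0.0,
        perception_sd=0.0,
        misid_rate=0.0,
        jitter_sd=0.0,
        n_target=300,
    )


@pytest.fixture()
def gt_annotations(slide_cells):
    return ground_truth_annotations(slide_cells)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
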