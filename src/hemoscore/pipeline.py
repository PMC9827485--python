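"""End-to-end simulated-study driver.

``run_pipeline`` executes the full analogue of the study workflow on
synthetic data: generate slides -> simulate annotators (and optionally
render/score images) -> match and grade-standardize against the ground
truth -> variance-component agreement analysis -> diagnostics — and writes
manifests, annotation files, THS tables and one JSON report.  Every output
is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from collections import defaultdict
from pathlib import Path

import numpy as np

from . import io as hio
from .agreement import (
    ThsTable,
    error_reduction,
    measurement_errors,
    uncertainty_interval,
    variance_components,
)
from .config import RunConfig
from .diagnostics import (
    consensus_curve,
    diagnostic_accuracy,
    rank_correlation,
    uncertainty_consensus_split,
)
from .matching import match_annotations, standardize_grades
from .scoring import ThsRecord, compute_ths, mean_annotator_ths
from .synthetic import (
    _subseed,
    generate_study,
    ground_truth_annotations,
    render_slide_image,
    simulate_annotator,
    simulate_chemistry,
)

log = logging.getLogger("hemoscore")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and config hash."""

    def __init__(self, stage: str, config_hash: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed (config {config_hash}): {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full simulated study and write its report bundle.

    Returns the report dictionary; files written to ``out_dir``:
    ``config.yaml``, ``manifests.csv``, ``ground_truth.csv``,
    ``annotations.csv``, ``ths_records.csv``, ``ths_raw.csv``,
    ``ths_standardized.csv`` and ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("annotate", _stage_annotate),
        ("score_images", _stage_score_images),
        ("standardize", _stage_standardize),
        ("agreement", _stage_agreement),
        ("diagnostics", _stage_diagnostics),
        ("write", _stage_write),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config, seed, state, out)
        except Exception as exc:  # abort with stage name + config hash
            raise PipelineError(name, chash, exc) from exc
        log.info("stage %s done in %.2fs (seed=%d)", name, time.perf_counter() - t0, seed)

    report = _sanitize(_build_report(config, state, chash))
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    config.to_yaml(out / "config.yaml")
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    manifests, cells = generate_study(config.study_config(), seed)
    by_slide = defaultdict(list)
    for c in cells:
        by_slide[c.slide_id].append(c)
    gt_sets = {sid: ground_truth_annotations(cs) for sid, cs in by_slide.items()}
    gt_records = {
        sid: compute_ths(anns, allow_fewer=True, cutoff=config.cutoff)
        for sid, anns in gt_sets.items()
    }
    chem = config.chemistry_params()
    manifests = [
        simulate_chemistry(m, gt_records[m.slide_id].ths, chem, _subseed(seed, 2, i))
        for i, m in enumerate(manifests)
    ]
    state.update(
        manifests=manifests, cells_by_slide=dict(by_slide), gt_sets=gt_sets,
        gt_records=gt_records,
    )


def _stage_annotate(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    profiles = config.profiles()
    annotations = {}   # (slide_id, annotator_id) -> list[CellAnnotation]
    records = []
    for i, m in enumerate(state["manifests"]):
        cells = state["cells_by_slide"][m.slide_id]
        for k, prof in enumerate(profiles):
            anns = simulate_annotator(
                cells, prof, _subseed(seed, 3, i, k), match_radius=config.match_radius
            )
            annotations[(m.slide_id, prof.annotator_id)] = anns
            records.append(
                compute_ths(
                    anns,
                    min_cells=config.min_cells,
                    allow_fewer=config.allow_fewer,
                    cutoff=config.cutoff,
                )
            )
    state.update(profiles=profiles, annotations=annotations, rater_records=records)


def _stage_score_images(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    from .imaging import score_image  # local import: heavy skimage machinery

    if not config.render_images:
        state.update(algo_records=None, algo_annotations=None)
        return
    algo_records = {}
    algo_annotations = {}
    for i, m in enumerate(state["manifests"]):
        img, _ = render_slide_image(
            state["cells_by_slide"][m.slide_id],
            stain=m.stain,
            params=config.render_params(),
            seed=_subseed(seed, 4, i),
            shape=(m.height, m.width),
        )
        anns, rec = score_image(
            img, m.slide_id, stain=m.stain, allow_fewer=True, cutoff=config.cutoff
        )
        algo_records[m.slide_id] = rec
        algo_annotations[m.slide_id] = anns
    state.update(algo_records=algo_records, algo_annotations=algo_annotations)


def _stage_standardize(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    std_records = []
    matched_fractions = []
    for (slide_id, annot_id), anns in state["annotations"].items():
        ref = state["gt_sets"][slide_id]
        match = match_annotations(anns, ref, config.match_radius)
        matched_fractions.append(match.matched_fraction_a())
        std = standardize_grades(anns, ref, config.match_radius)
        std_records.append(
            compute_ths(std, allow_fewer=True, cutoff=config.cutoff)
        )
    state.update(std_records=std_records, matched_fractions=matched_fractions)


def _stage_agreement(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    raw = ThsTable.from_records(state["rater_records"])
    std = ThsTable.from_records(state["std_records"])
    vc_raw = variance_components(raw)
    vc_std = variance_components(std)
    red = error_reduction(raw, std)
    errors = measurement_errors(raw)
    interval = uncertainty_interval(errors, cutoff=config.cutoff, coverage=config.coverage)
    state.update(
        raw_table=raw, std_table=std, vc_raw=vc_raw, vc_std=vc_std,
        reduction=red, errors=errors, interval=interval,
    )


def _stage_diagnostics(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    raw: ThsTable = state["raw_table"]
    gt_records = [state["gt_records"][sid] for sid in raw.slides]
    per_rater_gt, pooled_gt = diagnostic_accuracy(
        state["rater_records"], gt_records, config.cutoff
    )
    mean_records = [
        ThsRecord(
            slide_id=sid,
            rater_id="mean_annotators",
            n_cells=0,
            ths=mean_annotator_ths(
                [r for r in state["rater_records"] if r.slide_id == sid]
            ),
            eiph_positive=False,
        )
        for sid in raw.slides
    ]
    per_rater_mean, pooled_mean = diagnostic_accuracy(
        state["rater_records"], mean_records, config.cutoff
    )

    manifests = {m.slide_id: m for m in state["manifests"]}
    iron = [manifests[s].iron for s in raw.slides]
    censored = [manifests[s].iron_censored for s in raw.slides]
    rbc = [manifests[s].rbc for s in raw.slides]
    hgb = [manifests[s].hemoglobin for s in raw.slides]
    gt_ths = [state["gt_records"][s].ths for s in raw.slides]
    mean_ths = [r.ths for r in mean_records]
    detection_limit = config.chemistry.detection_limit

    def corr(x, y, cens=None):
        # Spearman needs >= 3 slides; smaller runs report the undefined flag
        if len(x) < 3:
            return float("nan")
        return rank_correlation(x, y, cens, detection_limit)

    correlations = {
        "mean_annotators_vs_ground_truth": corr(mean_ths, gt_ths),
        "mean_annotators_vs_iron": corr(mean_ths, iron, censored),
        "ground_truth_vs_iron": corr(gt_ths, iron, censored),
        "mean_annotators_vs_rbc": corr(mean_ths, rbc),
        "mean_annotators_vs_hemoglobin": corr(mean_ths, hgb),
    }
    algo = state.get("algo_records")
    if algo:
        algo_ths = [algo[s].ths for s in raw.slides]
        correlations["algorithm_vs_ground_truth"] = corr(algo_ths, gt_ths)
        correlations["algorithm_vs_iron"] = corr(algo_ths, iron, censored)
        per_algo_gt, _ = diagnostic_accuracy(
            [algo[s] for s in raw.slides], gt_records, config.cutoff
        )
        state["algo_accuracy_vs_gt"] = per_algo_gt["algorithm"]

    k = min(config.consensus_k, len(raw.annotators))
    inside, outside = uncertainty_consensus_split(raw, state["interval"], k)
    state.update(
        accuracy_gt=(per_rater_gt, pooled_gt),
        accuracy_mean=(per_rater_mean, pooled_mean),
        consensus=consensus_curve(raw, config.cutoff),
        correlations=correlations,
        consensus_split=(inside, outside),
        mean_records=mean_records,
    )


def _stage_write(config: RunConfig, seed: int, state: dict, out: Path) -> None:
    hio.write_manifests(state["manifests"], out / "manifests.csv")
    all_cells = [c for cs in state["cells_by_slide"].values() for c in cs]
    hio.write_ground_truth(all_cells, out / "ground_truth.csv")
    all_annotations = [a for anns in state["annotations"].values() for a in anns]
    if state.get("algo_annotations"):
        for anns in state["algo_annotations"].values():
            all_annotations.extend(anns)
    hio.write_annotations(all_annotations, out / "annotations.csv")
    hio.write_ths_records(state["rater_records"], out / "ths_records.csv")
    state["raw_table"].to_csv(out / "ths_raw.csv")
    state["std_table"].to_csv(out / "ths_standardized.csv")


# ---------------------------------------------------------------------------
# report


def _sanitize(obj):
    """Replace NaN with None so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def _vc_dict(vc) -> dict:
    return {
        "sigma2_slide": vc.sigma2_slide,
        "sigma2_annotator": vc.sigma2_annotator,
        "sigma2_residual": vc.sigma2_residual,
        "icc_agreement": vc.icc_agreement,
        "error_partition": vc.error_partition,
        "degenerate": vc.degenerate,
    }


def _build_report(config: RunConfig, state: dict, chash: str) -> dict:
    interval = state["interval"]
    per_gt, pooled_gt = state["accuracy_gt"]
    per_mean, pooled_mean = state["accuracy_mean"]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": chash,
        "seed": config.seed,
        "n_slides": len(state["manifests"]),
        "n_annotators": len(state["profiles"]),
        "ths": {
            "ground_truth": {
                s: state["gt_records"][s].ths for s in state["raw_table"].slides
            },
            "mean_annotators": {r.slide_id: r.ths for r in state["mean_records"]},
            "algorithm": (
                {s: r.ths for s, r in state["algo_records"].items()}
                if state.get("algo_records")
                else None
            ),
        },
        "matched_fraction_mean": float(np.mean(state["matched_fractions"])),
        "agreement": {
            "raw": _vc_dict(state["vc_raw"]),
            "standardized": _vc_dict(state["vc_std"]),
            "error_reduction": state["reduction"].as_dict(),
            "uncertainty_interval": {
                "q_low": interval.q_low,
                "q_high": interval.q_high,
                "lower": interval.lower,
                "upper": interval.upper,
                "coverage": interval.coverage,
                "cutoff": interval.cutoff,
            },
        },
        "diagnostics": {
            "accuracy_vs_ground_truth": {
                "per_rater": per_gt,
                "pooled": pooled_gt,
            },
            "accuracy_vs_mean_annotators": {
                "per_rater": per_mean,
                "pooled": pooled_mean,
            },
            "algorithm_accuracy_vs_ground_truth": state.get("algo_accuracy_vs_gt"),
            "consensus": {str(k): v for k, v in state["consensus"].items()},
            "consensus_split_inside_outside": list(state["consensus_split"]),
            "correlations": state["correlations"],
        },
    }
    return report
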