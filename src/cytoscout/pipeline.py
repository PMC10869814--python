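"""End-to-end orchestration: simulate -> detect -> classify -> enumerate ->
stats -> embed, with a manifest that makes every run reproducible.

Two run modes:

* ``feature-table`` — skips rendering and segmentation; ground-truth events
  get synthetic feature vectors and flow straight into classification.
  This is the fast mode for cohort-level statistics.
* ``image`` — frames are rendered to pixels and re-detected, exercising the
  full segmentation stack.

All randomness derives from one root seed via deterministically spawned
child generators, so a config plus seed reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categories import ONCOSOME_CATEGORIES, RARE_CATEGORIES
from .classify import (
    Gates,
    call_positivity_ml,
    call_positivity_threshold,
    classify_events,
    train_positivity_models,
)
from .config import CohortDesign, SimulationConfig, config_to_dict
from .detect import DetectionParams, detect_frame, filter_artifacts, select_rare_candidates
from .embedding import build_morphometric_matrix, embed_tsne
from .enumeration import TOTAL_COLUMNS, enumerate_cohort
from .io import write_frame, write_table
from .simulate import FEATURE_COLUMNS, Cohort, generate_cohort, render_slide, synthesize_features
from .stats import (
    PN_STAGE_CODES,
    PT_STAGE_CODES,
    correlate_clinical,
    default_comparison_specs,
    run_comparisons,
)

logger = logging.getLogger("cytoscout")


@dataclass
class RunConfig:
    """One pipeline run: simulation block, mode and module knobs."""

    out_dir: str
    seed: int = 0
    mode: str = "feature-table"  # feature-table | image
    classifier: str = "threshold"  # threshold | ml | truth
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: CohortDesign = field(default_factory=CohortDesign)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tumor_volume_effect: float = 0.0
    n_common_per_slide: int = 300
    write_frames: bool = False
    run_stats: bool = True
    run_embedding: bool = True
    embed_perplexity: float = 30.0

    def validate(self) -> None:
        if self.mode not in ("feature-table", "image"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.classifier not in ("threshold", "ml", "truth"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        self.simulation.validate()


def _stage(name: str):
    logger.info("stage: %s", name)


def classify_feature_table(
    features: pd.DataFrame,
    config: SimulationConfig,
    classifier: str = "threshold",
    seed: int = 0,
    truth_positivity: pd.DataFrame | None = None,
    flagged: pd.Series | None = None,
) -> pd.DataFrame:
    """Attach positivity calls, channel type and proximity to a feature table."""
    gates = Gates.from_background(config.background_level, config.background_sd,
                                  k=getattr(config, "gate_k", 5.0))
    if classifier == "truth":
        out = features.copy()
        # category column already holds planted truth
        out["proximity"] = out["proximity"].fillna("n/a")
        return out
    if classifier == "ml":
        if truth_positivity is None:
            raise ValueError("ml classifier needs training labels")
        models = train_positivity_models(features, truth_positivity,
                                         list(FEATURE_COLUMNS), seed=seed)
        positivity = call_positivity_ml(models, features, gates, list(FEATURE_COLUMNS))
    else:
        positivity = call_positivity_threshold(features, gates)
    out = features.copy()
    for ch in ("dapi", "ck", "vim", "cd"):
        out[f"pos_{ch}"] = positivity[f"pos_{ch}"]
    out["category"] = classify_events(features, positivity, flagged)
    d_um = config.adjacency_distance_um
    if "nearest_cell_gap_um" in out.columns:
        is_onco = out["category"].isin([c.value for c in ONCOSOME_CATEGORIES])
        out["proximity"] = np.where(
            is_onco, np.where(out["nearest_cell_gap_um"] <= d_um, "proximal", "distal"),
            "n/a")
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seed_cohort, seed_render, seed_features, seed_embed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4))

    _stage("simulate")
    mode = "render" if config.mode == "image" else "table"
    cohort = generate_cohort(config.design, config.simulation, seed_cohort,
                             mode=mode, tumor_volume_effect=config.tumor_volume_effect,
                             n_common_per_slide=(config.n_common_per_slide
                                                 if mode == "table" else 0))
    write_table(cohort.sample_table, out / "samples.tsv")
    write_table(cohort.slide_table, out / "slides.tsv")
    write_table(cohort.ground_truth, out / "ground_truth.tsv")
    write_table(cohort.clinical, out / "clinical.tsv")

    gates = Gates.from_background(config.simulation.background_level,
                                  config.simulation.background_sd,
                                  k=config.detection.gate_k)

    if config.mode == "image":
        _stage("detect")
        rng_render = np.random.default_rng(seed_render)
        tables = []
        for slide_id in cohort.slides:
            truth = cohort.ground_truth[cohort.ground_truth["slide_id"] == slide_id]
            for frame in render_slide(truth, config.simulation, rng_render, slide_id):
                if config.write_frames:
                    write_frame(frame, out / "frames")
                tables.append(detect_frame(frame, config.detection, gates))
        detected = pd.concat([t for t in tables if len(t)], ignore_index=True)
        detected, removed = filter_artifacts(detected, config.detection)
        detected = detected.reset_index(drop=True)
        write_table(removed, out / "removed_events.tsv")
        flagged_parts = []
        for slide_id, grp in detected.groupby("slide_id"):
            flagged_parts.append(select_rare_candidates(
                grp, config.detection, gates, random_state=config.seed))
        flagged = pd.concat(flagged_parts).reindex(detected.index)
        features = detected
        truth_positivity = None
    else:
        _stage("features")
        rng_feat = np.random.default_rng(seed_features)
        features = synthesize_features(cohort.ground_truth, config.simulation, rng_feat)
        gap = _synthetic_gaps(cohort.ground_truth, config.simulation, rng_feat)
        features["nearest_cell_gap_um"] = gap
        truth_positivity = cohort.ground_truth[["ck", "vim", "cd"]]
        if config.n_common_per_slide > 0:
            flagged_parts = []
            for slide_id, grp in features.groupby("slide_id"):
                flagged_parts.append(select_rare_candidates(
                    grp, config.detection, gates, random_state=config.seed))
            flagged = pd.concat(flagged_parts).reindex(features.index)
        else:  # no background sample: every event is a rare candidate
            flagged = None

    _stage("classify")
    classified = classify_feature_table(
        features, config.simulation, config.classifier, config.seed,
        truth_positivity=truth_positivity, flagged=flagged)
    write_table(classified, out / "events.tsv")

    _stage("enumerate")
    rare = classified[classified["category"].isin([c.value for c in RARE_CATEGORIES])]
    long, wide = enumerate_cohort(rare, cohort.slides, cohort.samples)
    write_table(long, out / "enum_long.tsv")
    write_table(wide.reset_index(), out / "enum_wide.tsv")

    if config.run_stats:
        _stage("stats")
        analytes = [c.value for c in RARE_CATEGORIES] + list(TOTAL_COLUMNS)
        specs = default_comparison_specs(cohort.sample_table, analytes)
        comparisons = run_comparisons(wide, cohort.sample_table, specs, add_bh=True)
        write_table(comparisons, out / "comparisons.tsv")
        pre = cohort.sample_table.query("cohort == 'PDAC' and site == 'PB' and timepoint == 'Pre'")
        if len(pre) >= 4:
            by_patient = (wide.reindex(pre["sample_id"])
                          .set_axis(pre["patient_id"].tolist(), axis=0))
            kinds = {"age": "continuous", "tumor_volume": "continuous",
                     "sex": "categorical", "smoker": "categorical",
                     "pT": "ordinal", "pN": "ordinal"}
            clin = cohort.clinical[cohort.clinical["pN"] != "pNX"]
            corr = correlate_clinical(
                by_patient, clin, kinds,
                analytes=["total_events", "total_cells", "total_oncosomes"],
                ordinal_codes={"pT": PT_STAGE_CODES, "pN": PN_STAGE_CODES})
            write_table(corr, out / "correlations.tsv")

    if config.run_embedding and len(rare) >= 12:
        _stage("embed")
        matrix, cols, means, sds = build_morphometric_matrix(rare)
        emb = embed_tsne(matrix, rare["event_id"].tolist(),
                         perplexity=config.embed_perplexity, seed=seed_embed,
                         columns=cols, means=means, sds=sds)
        coords = pd.DataFrame({"event_id": emb.event_ids,
                               "tsne1": emb.coordinates[:, 0],
                               "tsne2": emb.coordinates[:, 1]})
        write_table(coords, out / "embedding.tsv")

    _stage("manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "classifier": config.classifier,
        "config_hash": hashlib.sha256(
            json.dumps(config_to_dict(config.simulation), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(cohort.samples),
        "n_slides": len(cohort.slides),
        "n_events": int(len(classified)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _synthetic_gaps(truth: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Nearest-cell gaps (µm) consistent with planted proximity labels."""
    d = config.adjacency_distance_um
    prox = truth["proximity"].to_numpy()
    gaps = np.full(len(truth), np.inf)
    is_prox = prox == "proximal"
    is_dist = prox == "distal"
    gaps[is_prox] = rng.uniform(0.0, 0.8 * d, is_prox.sum())
    gaps[is_dist] = rng.uniform(2.5 * d, 10.0 * d, is_dist.sum())
    return gaps
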