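"""Segmentation, feature extraction, outlier selection and artifact removal."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cytoscout.categories import ChannelType
from cytoscout.classify import Gates
from cytoscout.config import DistributionSpec, SimulationConfig
from cytoscout.detect import (
    DetectionParams,
    SegmentedEvent,
    detect_frame,
    extract_features,
    filter_artifacts,
    segment_acellular_ck,
    segment_nuclei,
    select_rare_candidates,
)
from cytoscout.records import FrameImage, SlideRecord
from cytoscout.simulate import plant_events, render_frame, sample_common_events, synthesize_features

PARAMS = DetectionParams()


def _blank_frame(level=100.0, sd=10.0, shape=(256, 256), seed=0):
    rng = np.random.default_rng(seed)
    planes = np.clip(rng.normal(level, sd, (4, *shape)), 0, None)
    return FrameImage("s0", 0, planes, 0.2)


def _gates():
    return Gates.from_background((100.0,) * 4, (10.0,) * 4, k=5.0)


def _disc_mask(shape, r0, c0, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


class TestSegmentNuclei:
    def test_blank_frame_yields_no_masks(self):
        labels = segment_nuclei(_blank_frame(), PARAMS, _gates())
        assert labels.max() == 0

    def test_single_nucleus_centroid_recovered(self):
        frame = _blank_frame()
        frame.planes[0][_disc_mask(frame.shape, 120, 140, 25)] += 200.0
        labels = segment_nuclei(frame, PARAMS, _gates())
        assert labels.max() == 1
        r, c = np.argwhere(labels == 1).mean(axis=0)
        assert abs(r - 120) <= 2 and abs(c - 140) <= 2

    def test_two_distant_nuclei_separated(self):
        frame = _blank_frame()
        frame.planes[0][_disc_mask(frame.shape, 60, 60, 20)] += 200.0
        frame.planes[0][_disc_mask(frame.shape, 190, 190, 20)] += 200.0
        labels = segment_nuclei(frame, PARAMS, _gates())
        assert labels.max() == 2


class TestSegmentAcellularCk:
    def test_distal_oncosome_found(self):
        frame = _blank_frame()
        frame.planes[1][_disc_mask(frame.shape, 100, 100, 10)] += 150.0
        nuclei = np.zeros(frame.shape, dtype=np.int32)
        events = segment_acellular_ck(frame, nuclei, PARAMS, _gates())
        assert len(events) == 1
        assert not events[0].is_nucleated
        assert np.hypot(events[0].centroid[0] - 100, events[0].centroid[1] - 100) <= 2

    def test_ck_over_nucleus_is_cytoplasm_not_acellular(self):
        frame = _blank_frame()
        mask = _disc_mask(frame.shape, 100, 100, 12)
        frame.planes[1][mask] += 150.0
        frame.planes[0][mask] += 150.0
        nuclei = mask.astype(np.int32)
        events = segment_acellular_ck(frame, nuclei, PARAMS, _gates())
        assert events == []

    def test_elongated_ck_streak_excluded(self):
        frame = _blank_frame()
        frame.planes[1][100:104, 40:220] += 150.0  # 4 x 180 px streak
        nuclei = np.zeros(frame.shape, dtype=np.int32)
        events = segment_acellular_ck(frame, nuclei, PARAMS, _gates())
        assert events == []


class TestExtractFeatures:
    def _event(self, frame, mask, nucleated=False, nuc_mask=None):
        nm = nuc_mask if nuc_mask is not None else np.zeros(frame.shape, dtype=bool)
        cm = mask | nm
        centroid = tuple(np.argwhere(cm).mean(axis=0))
        return SegmentedEvent("e", "s0", 0, nm, cm, centroid, nucleated)

    def test_uniform_intensity_median(self):
        frame = _blank_frame()
        mask = _disc_mask(frame.shape, 100, 100, 10)
        frame.planes[1][mask] = 777.0
        feats = extract_features(self._event(frame, mask), frame)
        assert feats["ck_median"] == 777.0

    def test_disc_area_matches_analytic(self):
        frame = _blank_frame()
        mask = _disc_mask(frame.shape, 100, 100, 10)  # r = 10 px = 2 µm
        feats = extract_features(self._event(frame, mask), frame)
        assert feats["cell_area_um2"] == pytest.approx(np.pi * 2.0**2, rel=0.05)

    def test_ellipse_eccentricity_matches_analytic(self):
        frame = _blank_frame()
        rr, cc = np.mgrid[: frame.shape[0], : frame.shape[1]]
        mask = ((rr - 100) / 40.0) ** 2 + ((cc - 100) / 20.0) ** 2 <= 1.0
        feats = extract_features(self._event(frame, mask), frame)
        assert feats["cell_eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_empty_mask_rejected(self):
        frame = _blank_frame()
        with pytest.raises(ValueError, match="empty"):
            extract_features(self._event(frame, np.zeros(frame.shape, bool)), frame)

    def test_mask_locality(self):
        frame = _blank_frame()
        mask = _disc_mask(frame.shape, 100, 100, 10)
        ev = self._event(frame, mask)
        feats1 = extract_features(ev, frame)
        frame.planes[:, 0:40, 0:40] = 9999.0  # edit far outside the mask
        feats2 = extract_features(ev, frame)
        assert feats1 == feats2


def _background_features(n, seed=0):
    cfg = SimulationConfig(wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
    rng = np.random.default_rng(seed)
    slide = SlideRecord("s0", "t0", 6.0e6, 3_000_000)
    truth = sample_common_events(cfg, slide, rng, n)
    return synthesize_features(truth, cfg, rng), cfg


class TestSelectRareCandidates:
    def test_too_few_events_instructs_pooling(self):
        feats, _ = _background_features(5)
        with pytest.raises(ValueError, match="pool"):
            select_rare_candidates(feats, PARAMS, _gates())

    def test_pure_background_false_flag_rate_bounded(self):
        # binomial tolerance around the configured 1e-3 false-flag quantile
        feats, _ = _background_features(2000, seed=3)
        flagged = select_rare_candidates(feats, PARAMS, _gates(), random_state=0)
        n, q = len(feats), 1.0 - PARAMS.outlier_quantile
        upper = q + 1.96 * np.sqrt(q * (1 - q) / n) + 3.0 / n
        assert flagged.mean() <= upper

    def test_ck_positive_event_always_flagged(self):
        feats, _ = _background_features(100, seed=1)
        feats.loc[feats.index[0], "ck_median"] = 500.0
        flagged = select_rare_candidates(feats, PARAMS, _gates(), random_state=0)
        assert bool(flagged.iloc[0])

    def test_planted_marker_negative_rare_cell_flagged_by_distance(self):
        # a D|CD phenotype cell is only separable through its larger morphology
        feats, cfg = _background_features(1000, seed=2)
        rng = np.random.default_rng(7)
        slide = SlideRecord("s0", "t0", 6.0e6, 3_000_000)
        rare_cfg = dataclasses.replace(cfg, rare_rates={ChannelType.D_CD: 150.0})
        truth = plant_events(rare_cfg, slide, rng)
        rare_feats = synthesize_features(truth, cfg, rng)
        allf = pd.concat([feats, rare_feats], ignore_index=True)
        flagged = select_rare_candidates(allf, PARAMS, _gates(), random_state=0)
        assert flagged.iloc[len(feats):].mean() >= 0.9


class TestFilterArtifacts:
    def _table(self, **overrides):
        row = {"event_id": "e", "slide_id": "s", "frame_index": 0,
               "row": 50.0, "col": 50.0, "is_nucleated": True, "cluster_size": 1,
               "touches_border": False, "saturation_fraction": 0.0,
               "cell_area_um2": 100.0, "nucleus_area_um2": 60.0,
               "cell_eccentricity": 0.5, "nucleus_eccentricity": 0.5}
        row.update(overrides)
        return pd.DataFrame([row])

    def test_border_event_removed(self):
        kept, removed = filter_artifacts(self._table(touches_border=True), PARAMS)
        assert len(kept) == 0 and removed["removal_rule"].iloc[0] == "border"

    def test_tiny_ck_speck_removed_as_debris(self):
        kept, removed = filter_artifacts(
            self._table(cell_area_um2=0.04, nucleus_area_um2=0.0,
                        is_nucleated=False), PARAMS)
        assert len(kept) == 0 and removed["removal_rule"].iloc[0] == "area"

    def test_saturated_event_removed(self):
        kept, removed = filter_artifacts(self._table(saturation_fraction=0.5), PARAMS)
        assert removed["removal_rule"].iloc[0] == "saturation"

    def test_nonround_acellular_removed(self):
        kept, removed = filter_artifacts(
            self._table(is_nucleated=False, nucleus_area_um2=0.0,
                        cell_eccentricity=0.95), PARAMS)
        assert removed["removal_rule"].iloc[0] == "roundness"

    def test_clean_event_retained(self):
        kept, removed = filter_artifacts(self._table(), PARAMS)
        assert len(kept) == 1 and len(removed) == 0


class TestDetectFrameEndToEnd:
    def test_rendered_cell_detected_in_bounds(self, render_config):
        rng = np.random.default_rng(5)
        slide = SlideRecord("s0", "t0", 6.0e6, 48)
        cfg = dataclasses.replace(render_config, frames_per_slide=1,
                                  common_cells_per_frame=4)
        truth = plant_events(cfg, slide, rng, mode="render")
        frame = render_frame(truth, cfg, rng)
        gates = _gates()
        det = detect_frame(frame, PARAMS, gates)
        det, _ = filter_artifacts(det, PARAMS)
        # every planted in-bounds event matched within 5 px
        for _, ev in truth.iterrows():
            dist = np.hypot(det["row"] - ev["row"], det["col"] - ev["col"])
            assert dist.min() <= 5.0
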