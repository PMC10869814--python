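"""Synthetic slide generator: metadata laws, event planting, rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cytoscout.categories import ONCOSOME_CATEGORIES, RARE_CATEGORIES, ChannelType
from cytoscout.config import CohortDesign, DistributionSpec, SimulationConfig
from cytoscout.records import SlideRecord
from cytoscout.simulate import (
    event_masks,
    generate_cohort,
    plant_events,
    render_frame,
    sample_slide_metadata,
    synthesize_features,
)


class TestSlideMetadata:
    def test_point_mass_law_gives_constant_wbc(self, desk_config, rng):
        slides = sample_slide_metadata(desk_config, 5, rng)
        assert all(s.wbc_per_ml == 6.0e6 for s in slides)
        assert all(s.cells_plated == desk_config.cells_plated_per_slide for s in slides)

    def test_same_seed_reproduces_metadata(self):
        cfg = SimulationConfig()
        a = sample_slide_metadata(cfg, 10, np.random.default_rng(42))
        b = sample_slide_metadata(cfg, 10, np.random.default_rng(42))
        assert [(s.wbc_per_ml, s.cells_plated) for s in a] == \
               [(s.wbc_per_ml, s.cells_plated) for s in b]

    def test_lognormal_law_recovers_configured_mean(self):
        # the default law is parameterised by its arithmetic mean
        cfg = SimulationConfig()
        slides = sample_slide_metadata(cfg, 5000, np.random.default_rng(1))
        mean = np.mean([s.wbc_per_ml for s in slides])
        assert mean == pytest.approx(7.49e6, rel=0.02)

    def test_all_wbc_draws_positive(self):
        cfg = SimulationConfig(
            wbc_per_ml_law=DistributionSpec("normal", {"mean": 1e5, "sd": 3e5, "min": 1.0}))
        slides = sample_slide_metadata(cfg, 200, np.random.default_rng(2))
        assert all(s.wbc_per_ml > 0 for s in slides)

    def test_rejects_nonpositive_slide_count(self, desk_config, rng):
        with pytest.raises(ValueError):
            sample_slide_metadata(desk_config, 0, rng)


class TestPlantEvents:
    def _slide(self, wbc=6.0e6, plated=6_000_000):
        return SlideRecord("s0", "t0", wbc, plated)

    def test_zero_rates_plant_only_commons(self, rng):
        cfg = SimulationConfig(frames_per_slide=2, common_cells_per_frame=5,
                               rare_rates={c: 0.0 for c in RARE_CATEGORIES})
        events = plant_events(cfg, self._slide(), rng, mode="render")
        assert set(events["category"]) == {"common"}

    def test_poisson_rate_oracle_for_epi_ctc(self):
        # rate 50/mL on 1.0 mL analysed: mean planted count within 3 SE of 50
        cfg = SimulationConfig(
            rare_rates={ChannelType.EPI_CTC: 50.0},
            wbc_per_ml_law=DistributionSpec("point", {"value": 3.0e6}))
        slide = SlideRecord("s0", "t0", 3.0e6, 3_000_000)  # exactly 1.0 mL
        rng = np.random.default_rng(123)
        counts = [len(plant_events(cfg, slide, rng)) for _ in range(200)]
        se = np.sqrt(50.0 / 200)
        assert abs(np.mean(counts) - 50.0) <= 3 * se

    def test_proximal_fraction_one_labels_every_oncosome_proximal(self, rng):
        cfg = SimulationConfig(
            oncosome_proximal_fraction=1.0,
            rare_rates={ChannelType.ONC_CK: 100.0},
            wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        events = plant_events(cfg, self._slide(), rng)
        onc = events[events["category"] == "Onc.CK"]
        assert len(onc) > 10
        assert (onc["proximity"] == "proximal").all()

    def test_truth_invariants(self, rng):
        cfg = SimulationConfig(wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        events = plant_events(cfg, self._slide(), rng)
        onc = events[events["category"].isin([c.value for c in ONCOSOME_CATEGORIES])]
        cells = events[~events["category"].isin([c.value for c in ONCOSOME_CATEGORIES])]
        assert (~onc["dapi"]).all() and onc["ck"].all()
        assert (onc["proximity"] != "n/a").all()
        assert cells["dapi"].all()
        assert (cells["proximity"] == "n/a").all()

    def test_overcrowded_frame_raises_with_frame_name(self, rng):
        # more rare cells than a single frame can hold without overlap
        cfg = SimulationConfig(frames_per_slide=1, common_cells_per_frame=0,
                               rare_rates={ChannelType.EPI_CTC: 100.0},
                               wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        with pytest.raises(RuntimeError, match="frame 0"):
            plant_events(cfg, self._slide(), rng, mode="render")


class TestRenderFrame:
    def test_background_only_frame(self, render_config, rng):
        empty = pd.DataFrame(columns=["row", "col", "nuc_a"])
        frame = render_frame(empty, render_config, rng)
        for i in range(4):
            med = np.median(frame.planes[i])
            assert abs(med - render_config.background_level[i]) \
                <= 3 * render_config.background_sd[i]

    def _one_event_frame(self, config, category, rng):
        slide = SlideRecord("s0", "t0", 6.0e6, 96)  # 1.6e-5 mL analysed
        cfg = dataclasses.replace(
            config, frames_per_slide=1,
            common_cells_per_frame=0,
            oncosome_proximal_fraction=0.0,
            rare_rates={category: 3.0e5})  # ~5 expected events
        for seed in range(20):  # deterministic scan for a non-empty draw
            events = plant_events(cfg, slide, np.random.default_rng(seed), mode="render")
            if len(events):
                break
        events = events.iloc[:1]
        return events, render_frame(events, cfg, rng)

    def test_oncosome_has_no_nuclear_signal(self, render_config, rng):
        events, frame = self._one_event_frame(render_config, ChannelType.ONC_CK, rng)
        _, mask = event_masks(events.iloc[0], frame.shape)
        med_dapi = np.median(frame.plane("dapi")[mask])
        assert abs(med_dapi - render_config.background_level[0]) \
            <= 3 * render_config.background_sd[0]

    def test_epi_ctc_ck_signal_reaches_half_amplitude(self, render_config, rng):
        events, frame = self._one_event_frame(render_config, ChannelType.EPI_CTC, rng)
        ev = events.iloc[0]
        _, cell = event_masks(ev, frame.shape)
        med_ck = np.median(frame.plane("ck")[cell])
        assert med_ck >= render_config.background_level[1] + 0.5 * ev["amp_ck"]

    def test_intensities_nonnegative(self, render_config, rng):
        events, frame = self._one_event_frame(render_config, ChannelType.MES_CTC, rng)
        assert (frame.planes >= 0).all()


class TestGenerateCohort:
    def test_bookkeeping_two_patients_one_arm(self):
        design = CohortDesign(n_patients=2, arms=[("PDAC", "PB", "Pre")], slides_per_test=2)
        cohort = generate_cohort(design, SimulationConfig(), seed=0)
        assert len(cohort.samples) == 2
        assert len(cohort.slides) == 4
        for sample in cohort.samples:
            assert all(cohort.slides[sid].sample_id == sample.sample_id
                       for sid in sample.slide_ids)

    def test_determinism_byte_identical_ground_truth(self):
        design = CohortDesign(n_patients=3, arms=[("PDAC", "PB", "Pre"), ("ND", "PB", "Pre")])
        a = generate_cohort(design, SimulationConfig(), seed=9)
        b = generate_cohort(design, SimulationConfig(), seed=9)
        assert a.ground_truth.to_csv() == b.ground_truth.to_csv()
        assert a.clinical.to_csv() == b.clinical.to_csv()

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_patients=1, arms=[])

    def test_post_arm_multiplier_scales_oncosome_rate(self):
        base = SimulationConfig(
            rare_rates={ChannelType.ONC_CK: 20.0},
            wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        mult = {(("PDAC", "PB", "Post"), "*"): 5.0}
        design = CohortDesign(
            n_patients=4, arms=[("PDAC", "PB", "Pre"), ("PDAC", "PB", "Post")],
            effect_multipliers=mult)
        pre_total = post_total = 0
        for seed in range(25):
            cohort = generate_cohort(design, base, seed=seed)
            truth = cohort.ground_truth
            slide_tp = {s: ("Post" if "-Post-" in s else "Pre") for s in cohort.slides}
            tp = truth["slide_id"].map(slide_tp)
            pre_total += (tp == "Pre").sum()
            post_total += (tp == "Post").sum()
        assert 4.0 <= post_total / pre_total <= 6.0

    def test_clinical_table_shape_and_ranges(self):
        cohort = generate_cohort(CohortDesign(n_patients=20), SimulationConfig(), seed=4)
        clin = cohort.clinical
        assert len(clin) == 20
        assert clin["tumor_volume"].between(4.86, 184.9).all()
        assert set(clin["pT"]).issubset({"pT0", "pT1", "pT2", "pT3", "pT4"})

    def test_rate_calibration_across_slides(self):
        # pooled planted count / pooled mL within 3 SE of the configured rate
        cfg = SimulationConfig(
            rare_rates={ChannelType.ONC_CK: 30.0},
            wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        design = CohortDesign(n_patients=10, arms=[("PDAC", "PB", "Pre")])
        cohort = generate_cohort(design, cfg, seed=21)
        total_ml = sum(s.ml_analyzed for s in cohort.slides.values())
        count = len(cohort.ground_truth)
        se = np.sqrt(30.0 * total_ml)
        assert abs(count - 30.0 * total_ml) <= 3 * se


class TestSynthesizeFeatures:
    def test_feature_columns_complete_and_consistent(self, rng):
        cfg = SimulationConfig(wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}))
        slide = SlideRecord("s0", "t0", 6.0e6, 6_000_000)
        truth = plant_events(cfg, slide, rng)
        feats = synthesize_features(truth, cfg, rng)
        from cytoscout.simulate import FEATURE_COLUMNS

        assert set(FEATURE_COLUMNS) <= set(feats.columns)
        onc = feats[truth["category"].isin([c.value for c in ONCOSOME_CATEGORIES]).to_numpy()]
        assert (onc["nucleus_area_um2"] == 0).all()
        cells = feats[(~truth["category"].isin(
            [c.value for c in ONCOSOME_CATEGORIES])).to_numpy()]
        assert (cells["nucleus_area_um2"] > 0).all()
        assert (cells["cell_area_um2"] > cells["nucleus_area_um2"] * 0).all()
        assert feats["cell_eccentricity"].between(0, 1, inclusive="left").all()
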