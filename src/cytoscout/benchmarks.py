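"""Self-contained benchmark harnesses for the pipeline's key guarantees.

Each function builds its own synthetic inputs from a seed, runs the relevant
part of the pipeline and returns plain numbers: gating truth-table
agreement, exact-test error against brute-force enumeration, enumeration
recovery under Poisson sampling, rendered-frame detection performance,
type-I error and power of the comparison battery, and channel-positivity
model quality.  The brute-force rank-test oracles here enumerate every
group assignment / sign pattern directly and share no code with the
dynamic-programming implementations they check.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.stats import poisson, rankdata

from .categories import (
    CELLULAR_CATEGORIES,
    ONCOSOME_CATEGORIES,
    RARE_CATEGORIES,
    ChannelType,
    PositivityVector,
)
from .classify import (
    Gates,
    call_positivity_ml,
    call_positivity_threshold,
    classify_channel_type,
    train_positivity_models,
)
from .config import CohortDesign, DistributionSpec, SimulationConfig
from .detect import DetectionParams, detect_frame, filter_artifacts
from .enumeration import enumerate_cohort
from .pipeline import classify_feature_table
from .simulate import (
    FEATURE_COLUMNS,
    generate_cohort,
    render_slide,
    synthesize_features,
)
from .stats import (
    ComparisonSpec,
    mann_whitney_u,
    run_comparisons,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# gating truth table
# ---------------------------------------------------------------------------

def _expected_channel_type(pv: tuple[bool, bool, bool, bool], nucleated: bool):
    """Independent statement of the 12-category gating rules."""
    dapi, ck, vim, cd = pv
    if dapi != nucleated:
        return "error"
    if nucleated:
        table = {
            (True, False, False): ChannelType.EPI_CTC,
            (True, True, False): ChannelType.MES_CTC,
            (True, True, True): ChannelType.D_CK_V_CD,
            (True, False, True): ChannelType.D_CK_CD,
            (False, True, True): ChannelType.D_V_CD,
            (False, True, False): ChannelType.D_V,
            (False, False, True): ChannelType.D_CD,
            (False, False, False): ChannelType.DAPI_ONLY,
        }
        return table[(ck, vim, cd)]
    if not ck:
        return ChannelType.UNCLASSIFIED
    return {
        (False, False): ChannelType.ONC_CK,
        (True, False): ChannelType.ONC_CK_V,
        (False, True): ChannelType.ONC_CK_CD,
        (True, True): ChannelType.ONC_CK_V_CD,
    }[(vim, cd)]


def truth_table_agreement() -> dict[str, float]:
    """Check the classifier against all 16 positivity patterns x nucleation."""
    agree = total = 0
    for bits in itertools.product((True, False), repeat=4):
        for nucleated in (True, False):
            total += 1
            expected = _expected_channel_type(bits, nucleated)
            try:
                got = classify_channel_type(PositivityVector(*bits), nucleated,
                                            is_rare_flagged=True, roundness_ok=True)
            except ValueError:
                got = "error"
            agree += got == expected
    return {"agreement": agree, "total": total}


# ---------------------------------------------------------------------------
# exact rank tests vs brute force
# ---------------------------------------------------------------------------

def _brute_force_mwu(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x = len(x)
    observed = ranks[:n_x].sum()
    sums = [ranks[list(idx)].sum()
            for idx in itertools.combinations(range(len(pooled)), n_x)]
    eps = 1e-9
    p_le = np.mean([s <= observed + eps for s in sums])
    p_ge = np.mean([s >= observed - eps for s in sums])
    return min(1.0, 2.0 * min(p_le, p_ge))


def _brute_force_wilcoxon(diffs: np.ndarray) -> float:
    d = diffs[diffs != 0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    w_all = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product((0, 1), repeat=d.size)]
    eps = 1e-9
    p_le = np.mean([w <= observed + eps for w in w_all])
    p_ge = np.mean([w >= observed - eps for w in w_all])
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_test_oracle(seed: int, n_datasets: int = 100) -> dict[str, float]:
    """Max |p - p_oracle| over random small integer datasets with ties/zeros."""
    rng = np.random.default_rng(seed)
    err_mwu = err_wsr = 0.0
    for _ in range(n_datasets):
        n_x = int(rng.integers(2, 7))
        n_y = int(rng.integers(2, 9 - n_x)) if n_x < 7 else 2
        x = rng.integers(0, 5, size=n_x).astype(float)
        y = rng.integers(0, 5, size=n_y).astype(float)
        _, p = mann_whitney_u(x, y, mode="exact")
        err_mwu = max(err_mwu, abs(p - _brute_force_mwu(x, y)))

        n_d = int(rng.integers(1, 9))
        d = rng.integers(-3, 4, size=n_d).astype(float)
        if (d != 0).any():
            _, p, _ = wilcoxon_signed_rank(d, mode="exact")
            err_wsr = max(err_wsr, abs(p - _brute_force_wilcoxon(d)))
    return {"max_error_mann_whitney": err_mwu,
            "max_error_wilcoxon": err_wsr,
            "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# enumeration recovery
# ---------------------------------------------------------------------------

def _flat_rate_config(rate: float = 10.0) -> SimulationConfig:
    return SimulationConfig(
        rare_rates={cat: rate for cat in RARE_CATEGORIES},
        wbc_per_ml_law=DistributionSpec("point", {"value": 6.383e6}))


def enumeration_recovery(seed: int, n_samples: int = 20,
                         rate: float = 10.0) -> dict[str, float]:
    """Recover planted per-category rates through the feature-table pipeline.

    Each of ``n_samples`` two-slide tests (~0.94 mL) carries every category
    at ``rate`` events/mL; a sample counts as covered when its estimated
    total-events rate lies inside the Poisson 95% interval of the planted
    total.
    """
    config = _flat_rate_config(rate)
    n_patients = (n_samples + 1) // 2
    design = CohortDesign(n_patients=n_patients,
                          arms=[("PDAC", "PB", "Pre"), ("PDAC", "PB", "Post")])
    cohort = generate_cohort(design, config, seed)
    rng = np.random.default_rng(seed + 1)
    feats = synthesize_features(cohort.ground_truth, config, rng)
    classified = classify_feature_table(feats, config, classifier="threshold")
    rare = classified[classified["category"].isin([c.value for c in RARE_CATEGORIES])]
    _, wide = enumerate_cohort(rare, cohort.slides, cohort.samples)
    wide = wide.iloc[:n_samples]
    total_rate = rate * len(RARE_CATEGORIES)
    covered = 0
    for _, row in wide.iterrows():
        mu = total_rate * row["ml_analyzed"]
        lo, hi = poisson.interval(0.95, mu)
        count = row["total_events"] * row["ml_analyzed"]
        covered += lo <= round(count) <= hi
    return {"samples_covered": covered, "n_samples": len(wide),
            "mean_ml_per_test": float(wide["ml_analyzed"].mean())}


# ---------------------------------------------------------------------------
# rendered-frame detection
# ---------------------------------------------------------------------------

def detection_performance(seed: int, n_frames: int = 50) -> dict[str, float]:
    """Segmentation recall/precision and proximity accuracy on rendered frames.

    Frames hold a sparse leukocyte background plus rare events at the
    default signal-to-noise configuration (amplitudes at least 5 background
    sd above background).  Matching is by centroid within 5 px.
    """
    base = SimulationConfig()
    ml_factor = 6 * n_frames / 6.0e6  # mL analysed by the rendered slide
    scale = 1.8 * n_frames / (sum(base.rare_rates.values()) * ml_factor)
    config = SimulationConfig(
        frames_per_slide=n_frames, common_cells_per_frame=6,
        wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}),
        rare_rates={c: r * scale for c, r in base.rare_rates.items()})
    design = CohortDesign(n_patients=1, arms=[("PDAC", "PB", "Pre")], slides_per_test=1)
    cohort = generate_cohort(design, config, seed, mode="render")
    truth = cohort.ground_truth
    params = DetectionParams()
    gates = Gates.from_background(config.background_level, config.background_sd,
                                  params.gate_k)
    rng = np.random.default_rng(seed + 1)
    slide_id = next(iter(cohort.slides))
    tables = [detect_frame(f, params, gates)
              for f in render_slide(truth, config, rng, slide_id)]
    det = pd.concat([t for t in tables if len(t)], ignore_index=True)
    det, _ = filter_artifacts(det, params)

    onc_names = {c.value for c in ONCOSOME_CATEGORIES}
    cell_names = {c.value for c in CELLULAR_CATEGORIES}
    d_um = config.adjacency_distance_um

    tp_cell = tp_onc = 0
    prox_ok = prox_n = 0
    matched_det: set[int] = set()
    for _, ev in truth.iterrows():
        sub = det[det["frame_index"] == ev["frame_index"]]
        if not len(sub):
            continue
        dist = np.hypot(sub["row"] - ev["row"], sub["col"] - ev["col"])
        idx = dist.idxmin()
        if dist.loc[idx] > 5.0:
            continue
        matched_det.add(idx)
        if ev["category"] in cell_names and sub.loc[idx, "is_nucleated"]:
            tp_cell += 1
        elif ev["category"] in onc_names and not sub.loc[idx, "is_nucleated"]:
            tp_onc += 1
            prox_n += 1
            pred = "proximal" if sub.loc[idx, "nearest_cell_gap_um"] <= d_um else "distal"
            prox_ok += pred == ev["proximity"]

    n_truth_cell = int(truth["category"].isin(cell_names).sum())
    n_truth_onc = int(truth["category"].isin(onc_names).sum())
    det_cellular = det[det["is_nucleated"]]
    det_acellular = det[~det["is_nucleated"]]
    # precision: a detected object is correct when a planted object of the
    # same compartment lies within 5 px
    def _precision(sub: pd.DataFrame, names: set[str], want_nucleated: bool) -> float:
        if not len(sub):
            return 1.0
        ok = 0
        pool = truth if want_nucleated else truth[truth["category"].isin(names)]
        for _, d_ev in sub.iterrows():
            cand = pool[pool["frame_index"] == d_ev["frame_index"]]
            if len(cand):
                dd = np.hypot(cand["row"] - d_ev["row"], cand["col"] - d_ev["col"])
                ok += float(dd.min()) <= 5.0
        return ok / len(sub)

    return {
        "recall_cells": tp_cell / max(n_truth_cell, 1),
        "recall_oncosomes": tp_onc / max(n_truth_onc, 1),
        "precision_cells": _precision(det_cellular, cell_names, True),
        "precision_oncosomes": _precision(det_acellular, onc_names, False),
        "proximity_accuracy": prox_ok / max(prox_n, 1),
        "n_frames": n_frames,
        "n_truth_cells": n_truth_cell,
        "n_truth_oncosomes": n_truth_onc,
    }


# ---------------------------------------------------------------------------
# cohort statistics: type-I error and power
# ---------------------------------------------------------------------------

def type1_error(seed: int, n_reps: int = 500,
                analytes: tuple[str, ...] = ("total_events", "total_cells",
                                              "total_oncosomes")) -> dict[str, float]:
    """Null rejection fraction at alpha 0.05 for cancer-vs-donor contrasts.

    Both cohorts are generated from identical laws (same WBC law, same
    rates), so every rejection is a false positive.
    """
    config = _flat_rate_config(10.0)
    design = CohortDesign(n_patients=10,
                          arms=[("PDAC", "PB", "Pre"), ("ND", "PB", "Pre")])
    specs = [ComparisonSpec(a, "unpaired", "cohort", ("ND", "PDAC"),
                            {"site": "PB", "timepoint": "Pre"}) for a in analytes]
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    reject = {a: 0 for a in analytes}
    for rep_seed in child_seeds:
        cohort = generate_cohort(design, config, rep_seed,
                                 nd_wbc_law=config.wbc_per_ml_law)
        _, wide = enumerate_cohort(cohort.ground_truth, cohort.slides, cohort.samples)
        res = run_comparisons(wide, cohort.sample_table, specs)
        for _, row in res.iterrows():
            if row["p_two_sided"] < 0.05:
                reject[row["analyte"]] += 1
    out = {f"rejection_{a}": reject[a] / n_reps for a in analytes}
    out["n_replicates"] = n_reps
    return out


def power_direction(seed: int, n_reps: int = 100, n_pairs: int = 16,
                    fold: float = 5.0) -> dict[str, float]:
    """Power of the paired Post-vs-Pre contrast with one planted increase.

    The total-oncosome rate rises ``fold``-x after resection in the Post
    arm; every other analyte stays at its Pre level.  Reports how often the
    planted analyte is significant with direction 'increase', and the null
    rejection rate on the untouched analytes.
    """
    config = _flat_rate_config(10.0)
    mult = {(("PDAC", "PB", "Post"), cat.value): fold for cat in ONCOSOME_CATEGORIES}
    design = CohortDesign(n_patients=n_pairs,
                          arms=[("PDAC", "PB", "Pre"), ("PDAC", "PB", "Post")],
                          effect_multipliers=mult)
    target = "total_oncosomes"
    null_analytes = ("total_cells", "Epi.CTC", "D|V")
    specs = [ComparisonSpec(a, "paired", "timepoint", ("Pre", "Post"),
                            {"cohort": "PDAC", "site": "PB"})
             for a in (target,) + null_analytes]
    root = np.random.SeedSequence(seed + 1)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    hits = 0
    null_rejects = 0
    for rep_seed in child_seeds:
        cohort = generate_cohort(design, config, rep_seed)
        _, wide = enumerate_cohort(cohort.ground_truth, cohort.slides, cohort.samples)
        res = run_comparisons(wide, cohort.sample_table, specs).set_index("analyte")
        row = res.loc[target]
        hits += (row["p_two_sided"] < 0.05) and (row["direction"] == "increase")
        for a in null_analytes:
            null_rejects += res.loc[a, "p_two_sided"] < 0.05
    return {"power_with_increase": hits / n_reps,
            "null_analyte_rejection": null_rejects / (n_reps * len(null_analytes)),
            "n_replicates": n_reps, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# channel-positivity models
# ---------------------------------------------------------------------------

def ml_positivity(seed: int, n_events: int = 5000) -> dict[str, float]:
    """Train the three channel models and score them against gating.

    Returns the minimum held-out accuracy over CK/Vim/CD and the agreement
    with threshold gating on high-SNR events (all channel medians at least
    3 background sd away from their gates).
    """
    base = SimulationConfig()
    config = SimulationConfig(
        rare_rates={c: r * 40 for c, r in base.rare_rates.items()})
    n_common = max(200, int(n_events * 0.55))
    design = CohortDesign(n_patients=2, arms=[("PDAC", "PB", "Pre")])
    cohort = generate_cohort(design, config, seed, n_common_per_slide=n_common // 4)
    rng = np.random.default_rng(seed + 2)
    feats = synthesize_features(cohort.ground_truth, config, rng)
    labels = cohort.ground_truth[["ck", "vim", "cd"]]
    models = train_positivity_models(feats, labels, list(FEATURE_COLUMNS), seed=seed)
    gates = Gates.from_background(config.background_level, config.background_sd)
    pos_ml = call_positivity_ml(models, feats, gates, list(FEATURE_COLUMNS))
    pos_thr = call_positivity_threshold(feats, gates)
    # high-SNR: every channel median >= 3 sd away from its gate
    clear = np.ones(len(feats), dtype=bool)
    for i, ch in enumerate(("dapi", "ck", "vim", "cd")):
        sd = config.background_sd[i]
        clear &= (feats[f"{ch}_median"] - gates[ch]).abs().to_numpy() >= 3 * sd
    agree = (pos_ml.loc[clear, ["pos_ck", "pos_vim", "pos_cd"]].to_numpy()
             == pos_thr.loc[clear, ["pos_ck", "pos_vim", "pos_cd"]].to_numpy()).mean()
    accs = {ch: m.holdout_accuracy for ch, m in models.items()}
    return {"min_holdout_accuracy": min(accs.values()),
            "accuracy_ck": accs["ck"], "accuracy_vim": accs["vim"],
            "accuracy_cd": accs["cd"],
            "threshold_concordance_high_snr": float(agree),
            "n_events": len(feats)}


# ---------------------------------------------------------------------------
# normalisation identities
# ---------------------------------------------------------------------------

def normalization_identities(seed: int) -> dict[str, float]:
    """Exact conservation / equivariance / pooling checks on a generated cohort."""
    config = _flat_rate_config(10.0)
    design = CohortDesign(n_patients=6,
                          arms=[("PDAC", "PB", "Pre"), ("PDAC", "PoVB", "Pre")])
    cohort = generate_cohort(design, config, seed)
    _, wide = enumerate_cohort(cohort.ground_truth, cohort.slides, cohort.samples)
    conservation = float(np.max(np.abs(
        wide["total_events"] - (wide["total_cells"] + wide["total_oncosomes"]))))
    onc_split = float(np.max(np.abs(
        wide["total_oncosomes"]
        - (wide["oncosomes_distal"] + wide["oncosomes_proximal"]))))

    # scale equivariance: doubling WBC (halving mL) doubles every events/mL
    slides2 = {
        sid: dataclasses.replace(s, wbc_per_ml=2 * s.wbc_per_ml)
        for sid, s in cohort.slides.items()}
    _, wide2 = enumerate_cohort(cohort.ground_truth, slides2, cohort.samples)
    analyte_cols = [c.value for c in RARE_CATEGORIES] + ["total_events"]
    equivariance = float(np.max(np.abs(
        wide2[analyte_cols].to_numpy() - 2 * wide[analyte_cols].to_numpy())))

    # pooling associativity: per-slide counts pooled then normalised equals
    # the enumerated per-category rate
    associativity = 0.0
    truth = cohort.ground_truth
    for sample in cohort.samples:
        ml = sum(cohort.slides[sid].ml_analyzed for sid in sample.slide_ids)
        on_sample = truth[truth["slide_id"].isin(sample.slide_ids)]
        for cat in RARE_CATEGORIES:
            count = int((on_sample["category"] == cat.value).sum())
            associativity = max(associativity, abs(
                wide.loc[sample.sample_id, cat.value] - count / ml))
    return {"conservation_max_error": conservation,
            "oncosome_split_max_error": onc_split,
            "scale_equivariance_max_error": equivariance,
            "pooling_max_error": float(associativity)}
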