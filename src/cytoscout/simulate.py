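"""Ground-truthed synthetic cohorts of 4-channel immunofluorescence slides.

Two modes:

* **feature-table mode** — only ground-truth event records and their
  morphometric feature vectors are synthesised; no pixels are rendered.
  The full-scale plating target (3e6 cells/slide) is used for events/mL
  normalisation, so cohort-level statistics run at realistic blood volumes.
* **render mode** — frames are rasterised: elliptical nuclei in DAPI with
  cytoplasmic profiles in the positive marker channels, round DAPI-negative
  CK discs for oncosomes, plus additive Gaussian background noise (clipped
  at zero).  Normalisation then uses the common cells actually planted, so
  the events/mL arithmetic stays exact at desk scale.

Proximal oncosomes are planted adjacent (mask gap below the adjacency
distance D) to a nucleated cell; every other pair of objects is kept more
than 2.5 D apart so planted proximity labels are unambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .categories import (
    CATEGORY_POSITIVITY,
    CELLULAR_CATEGORIES,
    CHANNELS,
    ONCOSOME_CATEGORIES,
    RARE_CATEGORIES,
    ChannelType,
)
from .config import FULL_SCALE_FRAMES, CohortDesign, DistributionSpec, SimulationConfig
from .records import FrameImage, SampleRecord, SlideRecord

#: columns of the ground-truth event table
EVENT_COLUMNS = [
    "event_id", "slide_id", "frame_index", "row", "col",
    "category", "dapi", "ck", "vim", "cd", "cluster_size", "proximity",
    "nuc_a", "nuc_b", "cell_a", "cell_b", "angle",
    "amp_dapi", "amp_ck", "amp_vim", "amp_cd", "nuclei_offsets",
]


# ---------------------------------------------------------------------------
# slide metadata
# ---------------------------------------------------------------------------

def sample_slide_metadata(
    config: SimulationConfig,
    n_slides: int,
    rng: np.random.Generator,
    sample_id: str = "unassigned",
    mode: str = "table",
) -> list[SlideRecord]:
    """Draw per-slide WBC concentrations and plating counts.

    WBC draws come from ``config.wbc_per_ml_law`` truncated to positive
    values (non-positive draws are redrawn).  In render mode the plated-cell
    count equals the common cells that will actually be planted
    (frames x common_cells_per_frame); in feature-table mode it is the
    full-scale plating target.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    if mode == "render":
        cells = config.common_cells_per_frame * config.frames_per_slide
    else:
        cells = config.cells_plated_per_slide
    records = []
    for i in range(n_slides):
        wbc = float(config.wbc_per_ml_law.sample(rng))
        for _ in range(100):
            if wbc > 0:
                break
            wbc = float(config.wbc_per_ml_law.sample(rng))
        if wbc <= 0:
            raise RuntimeError("wbc_per_ml_law keeps producing non-positive draws")
        records.append(SlideRecord(f"{sample_id}-S{i}", sample_id, wbc, cells))
    return records


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------

def _ellipse_axes(diameter_um: float, pixel_size: float,
                  rng: np.random.Generator) -> tuple[float, float, float]:
    """Semi-axes (px) and orientation for a mildly elongated ellipse."""
    r_px = 0.5 * diameter_um / pixel_size
    ratio = rng.uniform(0.75, 1.0)  # minor/major axis ratio
    a = r_px / np.sqrt(ratio)
    b = r_px * np.sqrt(ratio)
    angle = rng.uniform(0.0, np.pi)
    return a, b, angle


@dataclass
class _Placed:
    row: float
    col: float
    radius: float  # bounding radius in px
    nucleated: bool
    a: float = 0.0  # cell ellipse semi-axes and orientation
    b: float = 0.0
    angle: float = 0.0


def _try_place(
    placed: list[_Placed],
    shape: tuple[int, int],
    radius: float,
    rng: np.random.Generator,
    cell_gap: float,
    onco_gap: float,
    new_is_onco: bool = False,
    max_tries: int = 200,
) -> tuple[float, float] | None:
    """Random sequential placement.

    Cells may sit close together (``cell_gap``); any pair involving an
    oncosome keeps at least ``onco_gap`` so that planted distal labels stay
    unambiguous.
    """
    h, w = shape
    margin = radius + 2.0
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        return None
    for _ in range(max_tries):
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        ok = True
        for p in placed:
            gap = onco_gap if (new_is_onco or not p.nucleated) else cell_gap
            if np.hypot(r - p.row, c - p.col) < radius + p.radius + gap:
                ok = False
                break
        if ok:
            return r, c
    return None


def _ellipse_radius_towards(a: float, b: float, angle: float, theta: float) -> float:
    """Distance from centre to the ellipse boundary in direction theta."""
    phi = theta - angle
    return a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))


def plant_events(
    config: SimulationConfig,
    slide: SlideRecord,
    rng: np.random.Generator,
    rate_multiplier: float = 1.0,
    mode: str = "table",
) -> pd.DataFrame:
    """Plant ground-truth events on one slide.

    Per rare category the event count is Poisson(rate x mL analysed x
    multiplier).  In render mode, common leukocytes fill each frame to
    ``common_cells_per_frame`` and all objects get explicit pixel geometry;
    in feature-table mode positions are drawn but packing is not enforced
    (nothing is rasterised) and no common background rows are emitted —
    commons are represented separately (see :func:`sample_common_events`).
    """
    ml = slide.ml_analyzed
    px = config.pixel_size
    d_px = config.adjacency_distance_um / px
    shape = config.frame_shape
    n_frames = config.frames_per_slide
    rows: list[dict] = []
    placed_per_frame: dict[int, list[_Placed]] = {f: [] for f in range(n_frames)}
    eid = 0

    def new_id() -> str:
        nonlocal eid
        eid += 1
        return f"{slide.slide_id}-E{eid:05d}"

    # rare nucleated events first: they are the largest objects and would not
    # fit into the gaps left by an already-planted background
    for cat in CELLULAR_CATEGORIES:
        rate = config.rare_rates.get(cat, 0.0) * rate_multiplier
        n_cat = int(rng.poisson(rate * ml)) if rate > 0 else 0
        for _ in range(n_cat):
            f = int(rng.integers(n_frames))
            d_um = float(config.rare_cell_nucleus_diameter.sample(rng))
            a, b, ang = _ellipse_axes(d_um, px, rng)
            k = 1
            if cat is ChannelType.MES_CTC:
                sizes = sorted(config.cluster_size_law)
                probs = np.array([config.cluster_size_law[s] for s in sizes])
                k = int(rng.choice(sizes, p=probs / probs.sum()))
            if k == 1:
                # independent per-axis cytoplasm jitter keeps cell and nucleus
                # shape features from being exactly collinear
                ca = a * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
                cb = b * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
            else:
                # compact rosette of k nuclei at offset 1.05 a from the
                # centre, wrapped in a round shared cytoplasm
                ca = cb = 2.05 * a * rng.uniform(1.05, 1.2)
            rad = max(ca, cb)
            if mode == "render":
                pos = _try_place(placed_per_frame[f], shape, rad, rng,
                                 5.0, 2.5 * d_px)
                if pos is None:
                    raise RuntimeError(
                        f"frame {f} of {slide.slide_id} too crowded to place a cell")
                r, c = pos
            else:
                r = rng.uniform(rad + 2, shape[0] - rad - 3)
                c = rng.uniform(rad + 2, shape[1] - rad - 3)
            placed_per_frame[f].append(_Placed(r, c, rad, True, ca, cb, ang))
            offsets = ""
            if k > 1:
                offs = []
                for j in range(k):
                    theta = 2 * np.pi * j / k
                    ro = 1.05 * a  # nuclei packed side by side
                    offs.append(f"{ro * np.sin(theta):.2f},{ro * np.cos(theta):.2f}")
                offsets = ";".join(offs)
            amps = _draw_amplitudes(cat, config, rng)
            rows.append(_event_row(new_id(), slide, f, r, c, cat, k, "n/a",
                                   a, b, ca, cb, ang, amps, offsets))

    # common leukocyte background (render mode only); also provides hosts
    # for proximal oncosomes
    if mode == "render":
        for f in range(n_frames):
            for _ in range(config.common_cells_per_frame):
                d_um = float(config.nucleus_diameter.sample(rng))
                a, b, ang = _ellipse_axes(d_um, px, rng)
                ca = a * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
                cb = b * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
                rad = max(ca, cb)
                pos = _try_place(placed_per_frame[f], shape, rad, rng,
                                 5.0, 2.5 * d_px)
                if pos is None:
                    continue  # background density is a target, not a contract
                r, c = pos
                placed_per_frame[f].append(_Placed(r, c, rad, True, ca, cb, ang))
                amps = _draw_amplitudes(ChannelType.COMMON, config, rng)
                rows.append(_event_row(new_id(), slide, f, r, c, ChannelType.COMMON,
                                       1, "n/a", a, b, ca, cb, ang, amps, ""))

    # oncosomes last so proximal ones can attach to any planted cell
    for cat in ONCOSOME_CATEGORIES:
        rate = config.rare_rates.get(cat, 0.0) * rate_multiplier
        n_cat = int(rng.poisson(rate * ml)) if rate > 0 else 0
        for _ in range(n_cat):
            f = int(rng.integers(n_frames))
            d_um = float(config.oncosome_diameter.sample(rng))
            a, b, ang = _ellipse_axes(d_um, px, rng)
            b = a * rng.uniform(0.9, 1.0)  # oncosomes are round
            proximal = rng.random() < config.oncosome_proximal_fraction
            hosts = [p for p in placed_per_frame[f] if p.nucleated]
            if mode == "render" and proximal and hosts:
                host = hosts[int(rng.integers(len(hosts)))]
                gap = rng.uniform(0.1 * d_px, 0.8 * d_px)
                theta = rng.uniform(0, 2 * np.pi)
                # distance from the host boundary along theta, not from
                # its bounding circle, so the mask-to-mask gap is <= D
                host_r = _ellipse_radius_towards(host.a, host.b, host.angle, theta)
                dist = host_r + a + gap
                r = float(np.clip(host.row + dist * np.sin(theta), a + 2, shape[0] - a - 3))
                c = float(np.clip(host.col + dist * np.cos(theta), a + 2, shape[1] - a - 3))
                prox = "proximal"
            elif mode == "render":
                pos = _try_place(placed_per_frame[f], shape, a, rng,
                                 2.5 * d_px, 2.5 * d_px, new_is_onco=True)
                if pos is None:
                    raise RuntimeError(
                        f"frame {f} of {slide.slide_id} too crowded to place an oncosome")
                r, c = pos
                prox = "distal"
            else:
                r = rng.uniform(a + 2, shape[0] - a - 3)
                c = rng.uniform(a + 2, shape[1] - a - 3)
                prox = "proximal" if proximal else "distal"
            placed_per_frame[f].append(_Placed(r, c, a, False, a, b, ang))
            amps = _draw_amplitudes(cat, config, rng)
            rows.append(_event_row(new_id(), slide, f, r, c, cat, 1, prox,
                                   0.0, 0.0, a, b, ang, amps, ""))

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df


def _draw_amplitudes(cat: ChannelType, config: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, float]:
    pv = CATEGORY_POSITIVITY[cat]
    amps = {}
    for ch, positive in zip(CHANNELS, pv.as_tuple()):
        amps[ch] = float(config.amplitude_law(cat, ch).sample(rng)) if positive else 0.0
    return amps


def _event_row(event_id, slide, frame, r, c, cat, k, prox,
               nuc_a, nuc_b, cell_a, cell_b, angle, amps, offsets) -> dict:
    return {
        "event_id": event_id, "slide_id": slide.slide_id, "frame_index": frame,
        "row": float(r), "col": float(c), "category": cat.value,
        "dapi": CATEGORY_POSITIVITY[cat].dapi, "ck": CATEGORY_POSITIVITY[cat].ck,
        "vim": CATEGORY_POSITIVITY[cat].vim, "cd": CATEGORY_POSITIVITY[cat].cd,
        "cluster_size": int(k), "proximity": prox,
        "nuc_a": float(nuc_a), "nuc_b": float(nuc_b),
        "cell_a": float(cell_a), "cell_b": float(cell_b), "angle": float(angle),
        "amp_dapi": amps["dapi"], "amp_ck": amps["ck"],
        "amp_vim": amps["vim"], "amp_cd": amps["cd"],
        "nuclei_offsets": offsets,
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], r: float, c: float,
                  a: float, b: float, angle: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse (semi-axes a, b in px)."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - r, cc - c
    cos, sin = np.cos(angle), np.sin(angle)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def event_masks(ev: pd.Series, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(nucleus_mask, cell_mask) of a ground-truth event row (render geometry)."""
    cell = _ellipse_mask(shape, ev["row"], ev["col"], ev["cell_a"], ev["cell_b"], ev["angle"])
    if ev["nuc_a"] <= 0:
        return np.zeros(shape, dtype=bool), cell
    if ev["nuclei_offsets"]:
        nuc = np.zeros(shape, dtype=bool)
        for pair in str(ev["nuclei_offsets"]).split(";"):
            dr, dc = (float(t) for t in pair.split(","))
            nuc |= _ellipse_mask(shape, ev["row"] + dr, ev["col"] + dc,
                                 ev["nuc_a"], ev["nuc_b"], ev["angle"])
    else:
        nuc = _ellipse_mask(shape, ev["row"], ev["col"], ev["nuc_a"], ev["nuc_b"], ev["angle"])
    return nuc & cell, cell | nuc


def render_frame(
    events: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    slide_id: str = "unassigned-S0",
    frame_index: int = 0,
) -> FrameImage:
    """Rasterise one frame from its planted events.

    Nucleated events paint their amplitude over the nucleus mask in DAPI and
    over the cell mask in each positive marker channel; oncosomes paint round
    CK (plus Vim/CD as per their positivity) profiles with no DAPI signal.
    A light Gaussian blur softens edges, then Gaussian background noise is
    added and the result clipped at zero.
    """
    from scipy.ndimage import gaussian_filter

    shape = config.frame_shape
    signal = np.zeros((len(CHANNELS), *shape), dtype=float)
    for _, ev in events.iterrows():
        nuc, cell = event_masks(ev, shape)
        if ev["nuc_a"] > 0:  # cellular event
            signal[0][nuc] += ev["amp_dapi"]
            for i, ch in enumerate(CHANNELS[1:], start=1):
                amp = ev[f"amp_{ch}"]
                if amp > 0:
                    signal[i][cell] += amp
        else:  # oncosome: no nuclear structure
            for i, ch in enumerate(CHANNELS[1:], start=1):
                amp = ev[f"amp_{ch}"]
                if amp > 0:
                    signal[i][cell] += amp
    planes = np.empty_like(signal)
    for i in range(len(CHANNELS)):
        blurred = gaussian_filter(signal[i], sigma=1.0)
        noise = rng.normal(config.background_level[i], config.background_sd[i], shape)
        planes[i] = np.clip(blurred + noise, 0.0, None)
    return FrameImage(slide_id, frame_index, planes, config.pixel_size)


def render_slide(
    events: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator,
    slide_id: str,
) -> Iterator[FrameImage]:
    """Yield every frame of a slide in index order."""
    for f in range(config.frames_per_slide):
        sub = events[(events["slide_id"] == slide_id) & (events["frame_index"] == f)]
        yield render_frame(sub, config, rng, slide_id, f)


# ---------------------------------------------------------------------------
# feature-table synthesis (no pixels)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = (
    ["cell_area_um2", "nucleus_area_um2", "cell_eccentricity", "nucleus_eccentricity",
     "cell_perimeter_um", "nucleus_perimeter_um", "cell_solidity", "nucleus_solidity"]
    + [f"{ch}_{stat}" for ch in CHANNELS for stat in ("median", "mean", "sd", "max")]
)


def synthesize_features(
    events: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Morphometric feature vectors drawn directly from the generative laws.

    Emulates what segmentation + feature extraction would measure on a
    rendered frame, without rasterising: channel medians are background plus
    the event's amplitude (positive channels only) with sampling noise,
    areas/eccentricities follow from the planted ellipse geometry.
    """
    n = len(events)
    px = config.pixel_size
    out = events[["event_id", "slide_id", "frame_index", "row", "col",
                  "category", "cluster_size", "proximity"]].copy()
    a_cell = events["cell_a"].to_numpy() * px
    b_cell = events["cell_b"].to_numpy() * px
    a_nuc = events["nuc_a"].to_numpy() * px
    b_nuc = events["nuc_b"].to_numpy() * px
    out["cell_area_um2"] = np.pi * a_cell * b_cell
    out["nucleus_area_um2"] = np.pi * a_nuc * b_nuc * events["cluster_size"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc_c = np.sqrt(np.clip(1.0 - (b_cell / np.where(a_cell > 0, a_cell, 1.0)) ** 2, 0, 1))
        ecc_n = np.sqrt(np.clip(1.0 - (b_nuc / np.where(a_nuc > 0, a_nuc, 1.0)) ** 2, 0, 1))
    out["cell_eccentricity"] = ecc_c
    out["nucleus_eccentricity"] = np.where(a_nuc > 0, ecc_n, 0.0)
    # Ramanujan perimeter of the ellipse
    out["cell_perimeter_um"] = np.pi * (3 * (a_cell + b_cell)
                                        - np.sqrt((3 * a_cell + b_cell) * (a_cell + 3 * b_cell)))
    out["nucleus_perimeter_um"] = np.where(
        a_nuc > 0,
        np.pi * (3 * (a_nuc + b_nuc) - np.sqrt((3 * a_nuc + b_nuc) * (a_nuc + 3 * b_nuc))),
        0.0)
    out["cell_solidity"] = rng.uniform(0.95, 1.0, n)
    out["nucleus_solidity"] = np.where(a_nuc > 0, rng.uniform(0.95, 1.0, n), 0.0)
    for i, ch in enumerate(CHANNELS):
        bg = config.background_level[i]
        sd = config.background_sd[i]
        amp = events[f"amp_{ch}"].to_numpy()
        med = np.clip(bg + amp + rng.normal(0, sd / 3.0, n), 0, None)
        out[f"{ch}_median"] = med
        out[f"{ch}_mean"] = np.clip(med + rng.normal(0, sd / 3.0, n), 0, None)
        out[f"{ch}_sd"] = np.abs(sd * (1.0 + 0.2 * rng.normal(0, 1, n)))
        out[f"{ch}_max"] = med + np.abs(rng.normal(2.5 * sd, sd, n))
    return out


def sample_common_events(
    config: SimulationConfig,
    slide: SlideRecord,
    rng: np.random.Generator,
    n_common: int = 2000,
) -> pd.DataFrame:
    """Ground-truth rows for a representative sample of common leukocytes.

    Feature-table mode does not materialise every plated cell (3e6 at full
    scale); this draws ``n_common`` representative background cells for
    outlier-model fitting and classifier training.
    """
    rows = []
    shape = config.frame_shape
    for i in range(n_common):
        d_um = float(config.nucleus_diameter.sample(rng))
        a, b, ang = _ellipse_axes(d_um, config.pixel_size, rng)
        ca = a * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
        cb = b * config.cytoplasm_scale * rng.uniform(0.85, 1.15)
        rad = max(ca, cb)
        r = rng.uniform(rad + 2, shape[0] - rad - 3)
        c = rng.uniform(rad + 2, shape[1] - rad - 3)
        f = int(rng.integers(config.frames_per_slide))
        amps = _draw_amplitudes(ChannelType.COMMON, config, rng)
        rows.append(_event_row(f"{slide.slide_id}-C{i:05d}", slide, f, r, c,
                               ChannelType.COMMON, 1, "n/a", a, b, ca, cb, ang, amps, ""))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: metadata, ground truth and the clinical table."""

    samples: list[SampleRecord]
    slides: dict[str, SlideRecord]
    ground_truth: pd.DataFrame
    clinical: pd.DataFrame
    config: SimulationConfig
    design: CohortDesign
    seed: int

    @property
    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.samples])

    @property
    def slide_table(self) -> pd.DataFrame:
        rows = []
        for s in self.slides.values():
            rows.append({"slide_id": s.slide_id, "sample_id": s.sample_id,
                         "wbc_per_ml": s.wbc_per_ml, "cells_plated": s.cells_plated,
                         "ml_analyzed": s.ml_analyzed})
        return pd.DataFrame(rows)


#: ND donors have slightly lower WBC counts than PDAC patients
ND_WBC_LAW = DistributionSpec("lognormal", {"mean": 6.3e6, "sigma": 0.45})


def _clinical_row(patient_id: str, rng: np.random.Generator) -> dict:
    pt_levels = ["pT0", "pT1", "pT2", "pT3", "pT4"]
    pn_levels = ["pNX", "pN0", "pN1"]
    vol = float(np.clip(rng.lognormal(np.log(35.0), 0.8), 4.86, 184.9))
    return {
        "patient_id": patient_id,
        "age": float(np.clip(rng.normal(66.5, 6.0), 45, 90)),
        "sex": rng.choice(["M", "F"], p=[0.45, 0.55]),
        "race": rng.choice(["White", "Black", "Other"], p=[0.70, 0.15, 0.15]),
        "smoker": rng.choice(["Yes", "No"], p=[0.40, 0.60]),
        "alcohol": rng.choice(["Yes", "No"], p=[0.25, 0.75]),
        "familial_history": rng.choice(["Yes", "No"], p=[0.65, 0.35]),
        "tumor_grade": rng.choice(["Poor", "Moderate"], p=[0.3, 0.7]),
        "tumor_volume": vol,
        "pT": rng.choice(pt_levels, p=[0.05, 0.42, 0.42, 0.06, 0.05]),
        "pN": rng.choice(pn_levels, p=[0.25, 0.4, 0.35]),
        "therapy": rng.choice(["none", "neoadjuvant", "adjuvant"], p=[0.25, 0.15, 0.60]),
    }


def generate_cohort(
    design: CohortDesign,
    config: SimulationConfig,
    seed: int,
    mode: str = "table",
    tumor_volume_effect: float = 0.0,
    n_common_per_slide: int = 0,
    nd_wbc_law: DistributionSpec | None = None,
) -> Cohort:
    """Generate a full cohort: samples, slides, ground truth, clinical table.

    One test of ``design.slides_per_test`` slides is generated per
    (patient, arm).  PDAC arms share the PDAC WBC law from ``config``; ND
    draws use a slightly lower-mean law.  ``tumor_volume_effect`` couples a
    patient's rare rates to tumour volume as (volume / 35 mm^2)^effect,
    giving a planted monotone association for correlation tests.
    Fully reproducible from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    rng_clin, rng_events = (np.random.default_rng(s) for s in root.spawn(2))

    samples: list[SampleRecord] = []
    slides: dict[str, SlideRecord] = {}
    truth_parts: list[pd.DataFrame] = []
    clinical_rows = []

    pdac_ids = [f"P{i + 1:02d}" for i in range(design.n_patients)]
    for pid in pdac_ids:
        clinical_rows.append(_clinical_row(pid, rng_clin))
    clinical = pd.DataFrame(clinical_rows)
    vol_mult = {
        row["patient_id"]: (row["tumor_volume"] / 35.0) ** tumor_volume_effect
        for row in clinical_rows
    }

    pdac_arms = [a for a in design.arms if a[0] == "PDAC"]
    nd_arms = [a for a in design.arms if a[0] == "ND"]

    for pid in pdac_ids:
        for arm in pdac_arms:
            cohort_name, site, tp = arm
            sample_id = f"{pid}-{site}-{tp}"
            recs = sample_slide_metadata(config, design.slides_per_test,
                                         rng_events, sample_id, mode)
            for rec in recs:
                slides[rec.slide_id] = rec
                per_cat_cfg = _scaled_config(config, design, arm, vol_mult.get(pid, 1.0))
                truth_parts.append(plant_events(per_cat_cfg, rec, rng_events, 1.0, mode))
                if n_common_per_slide > 0 and mode != "render":
                    truth_parts.append(
                        sample_common_events(config, rec, rng_events, n_common_per_slide))
            samples.append(SampleRecord(sample_id, pid, cohort_name, site, tp,
                                        [r.slide_id for r in recs]))

    if nd_arms:
        nd_config = dataclasses.replace(config, wbc_per_ml_law=nd_wbc_law or ND_WBC_LAW)
        for i in range(design.n_patients):
            pid = f"N{i + 1:02d}"
            for arm in nd_arms:
                sample_id = f"{pid}-PB-Pre"
                recs = sample_slide_metadata(nd_config, design.slides_per_test,
                                             rng_events, sample_id, mode)
                for rec in recs:
                    slides[rec.slide_id] = rec
                    per_cat_cfg = _scaled_config(nd_config, design, arm, 1.0)
                    truth_parts.append(plant_events(per_cat_cfg, rec, rng_events, 1.0, mode))
                    if n_common_per_slide > 0 and mode != "render":
                        truth_parts.append(
                            sample_common_events(nd_config, rec, rng_events, n_common_per_slide))
                samples.append(SampleRecord(sample_id, pid, "ND", "PB", "Pre",
                                            [r.slide_id for r in recs]))

    truth = (pd.concat(truth_parts, ignore_index=True)
             if truth_parts else pd.DataFrame(columns=EVENT_COLUMNS))
    if mode == "render" and len(truth):
        # normalisation uses the commons actually planted (crowded frames may
        # fall short of the target density), keeping events/mL exact
        commons = truth[truth["category"] == ChannelType.COMMON.value] \
            .groupby("slide_id").size()
        for sid, rec in slides.items():
            planted = int(commons.get(sid, 0))
            if planted > 0:
                rec.cells_plated = planted
    return Cohort(samples, slides, truth, clinical, config, design, seed)


def _scaled_config(config: SimulationConfig, design: CohortDesign,
                   arm: tuple[str, str, str], patient_mult: float) -> SimulationConfig:
    rates = {
        cat: rate * design.multiplier(arm, cat) * patient_mult
        for cat, rate in config.rare_rates.items()
    }
    return dataclasses.replace(config, rare_rates=rates)


def full_scale_equivalent_frames(config: SimulationConfig) -> float:
    """Fraction of a full acquisition the configured frame count represents."""
    return config.frames_per_slide / FULL_SCALE_FRAMES
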