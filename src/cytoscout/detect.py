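"""Event detection in 4-channel frames.

Pipeline per frame: segment nuclei from DAPI (adaptive gate + watershed
separation of touching nuclei), grow cell masks over the marker channels,
segment acellular round CK-positive components (oncosome candidates),
extract morphometric features, and — per slide — select rare candidates as
robust-distance outliers from the dominant DAPI+/CD45-CD31+ leukocyte
background.  A final artifact filter removes border events, saturated
events, out-of-range areas and non-round acellular debris, logging the rule
behind each removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import chi2, f as f_dist
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from sklearn.covariance import MinCovDet

from .categories import CHANNELS
from .classify import Gates, gates_from_frame
from .records import FrameImage


@dataclass
class DetectionParams:
    """Tunable detection knobs (areas in µm², distances in µm)."""

    gate_k: float = 5.0                      # gate = background + k·sd
    min_nucleus_area_um2: float = 15.0
    min_ck_area_um2: float = 2.0
    min_event_area_um2: float = 2.0
    max_event_area_um2: float = 3000.0
    nucleus_split_min_distance_um: float = 3.0   # watershed peak separation
    roundness_max_eccentricity: float = 0.8
    saturation_level: float | None = None
    saturation_max_fraction: float = 0.2
    outlier_quantile: float = 0.999
    min_events_for_background: int = 20
    outlier_features: tuple[str, ...] = (
        "dapi_median", "ck_median", "vim_median", "cd_median",
        "cell_area_um2", "nucleus_area_um2",
        "cell_eccentricity", "nucleus_eccentricity",
    )


@dataclass
class SegmentedEvent:
    """One segmented object: masks, centroid and nucleation state."""

    event_id: str
    slide_id: str
    frame_index: int
    nucleus_mask: np.ndarray  # boolean, empty for acellular events
    cell_mask: np.ndarray
    centroid: tuple[float, float]  # 0-based (row, col)
    is_nucleated: bool
    cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.is_nucleated != bool(self.nucleus_mask.any()):
            raise ValueError("is_nucleated inconsistent with nucleus_mask")
        if self.is_nucleated and not (self.cell_mask | self.nucleus_mask).sum() == self.cell_mask.sum():
            raise ValueError("nucleus_mask must be a subset of cell_mask")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(frame: FrameImage, params: DetectionParams,
                   gates: Gates | None = None) -> np.ndarray:
    """Label image of nuclei from the DAPI plane.

    Adaptive gate (robust background + k·sd), small objects removed,
    touching nuclei split by a distance-transform watershed.
    """
    dapi = frame.plane("dapi")
    gates = gates or gates_from_frame(frame.planes, params.gate_k)
    binary = dapi >= gates["dapi"]
    min_px = max(1, int(params.min_nucleus_area_um2 / frame.pixel_size**2))
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    binary = ndimage.binary_fill_holes(binary)
    if not binary.any():
        return np.zeros(frame.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(binary)
    min_dist_px = max(3, int(params.nucleus_split_min_distance_um / frame.pixel_size))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=binary,
                           exclude_border=False)
    markers = np.zeros(frame.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(binary).astype(np.int32)
    labels = segmentation.watershed(-distance, markers, mask=binary)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_px)
    labels[np.isin(labels, small)] = 0
    return labels.astype(np.int32)


def segment_cells(frame: FrameImage, nuclei: np.ndarray,
                  params: DetectionParams, gates: Gates | None = None
                  ) -> list[SegmentedEvent]:
    """Group nuclei with their surrounding marker-positive cytoplasm.

    The cell foreground is the union of gated CK/Vim/CD signal and dilated
    nuclei; each connected component containing k >= 1 nuclei becomes one
    event with cluster_size k (clusters share one contiguous cell mask).
    """
    gates = gates or gates_from_frame(frame.planes, params.gate_k)
    marker_fg = np.zeros(frame.shape, dtype=bool)
    for ch in CHANNELS[1:]:
        marker_fg |= frame.plane(ch) >= gates[ch]
    nuc_binary = nuclei > 0
    fg = marker_fg | morphology.dilation(nuc_binary, morphology.disk(3))
    components = measure.label(fg, connectivity=2)
    events: list[SegmentedEvent] = []
    for region in measure.regionprops(components):
        comp_mask = components == region.label
        nuc_labels = np.unique(nuclei[comp_mask])
        nuc_labels = nuc_labels[nuc_labels > 0]
        if nuc_labels.size == 0:
            continue  # acellular candidate, handled separately
        nuc_mask = np.isin(nuclei, nuc_labels) & comp_mask
        if not nuc_mask.any():
            continue
        centroid = ndimage.center_of_mass(nuc_mask)
        events.append(SegmentedEvent(
            event_id=f"{frame.slide_id}-F{frame.frame_index}-N{region.label}",
            slide_id=frame.slide_id, frame_index=frame.frame_index,
            nucleus_mask=nuc_mask, cell_mask=comp_mask | nuc_mask,
            centroid=(float(centroid[0]), float(centroid[1])),
            is_nucleated=True, cluster_size=int(nuc_labels.size)))
    return events


def segment_acellular_ck(frame: FrameImage, nuclei: np.ndarray,
                         params: DetectionParams, gates: Gates | None = None
                         ) -> list[SegmentedEvent]:
    """Candidate oncosome masks: round CK components with no nuclear structure.

    CK-gated components are kept when they contain no nucleus pixels, their
    median DAPI stays below the DAPI gate, and they pass the roundness
    criterion (eccentricity <= cutoff).
    """
    gates = gates or gates_from_frame(frame.planes, params.gate_k)
    ck_fg = frame.plane("ck") >= gates["ck"]
    min_px = max(1, int(params.min_ck_area_um2 / frame.pixel_size**2))
    ck_fg = morphology.remove_small_objects(ck_fg, max_size=min_px - 1)
    components = measure.label(ck_fg, connectivity=2)
    dapi = frame.plane("dapi")
    events: list[SegmentedEvent] = []
    for region in measure.regionprops(components):
        mask = components == region.label
        if (nuclei[mask] > 0).any():
            continue  # overlaps a nucleus: cytoplasm, not acellular
        if float(np.median(dapi[mask])) >= gates["dapi"]:
            continue  # DAPI-positive: not an oncosome
        if region.eccentricity > params.roundness_max_eccentricity:
            continue  # fails the 'round' criterion
        events.append(SegmentedEvent(
            event_id=f"{frame.slide_id}-F{frame.frame_index}-A{region.label}",
            slide_id=frame.slide_id, frame_index=frame.frame_index,
            nucleus_mask=np.zeros(frame.shape, dtype=bool), cell_mask=mask,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            is_nucleated=False))
    return events


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features(event: SegmentedEvent, frame: FrameImage) -> dict[str, float]:
    """Morphometric feature vector of one segmented event.

    Areas in µm² (pixel count x pixel_size²), eccentricity from the
    best-fit-ellipse second moments, channel statistics over the cell mask
    (or the acellular mask).  Deterministic and mask-local.
    """
    if not event.cell_mask.any():
        raise ValueError(f"event {event.event_id}: empty mask")
    px2 = frame.pixel_size**2
    out: dict[str, float] = {}

    def _shape_stats(mask: np.ndarray, prefix: str) -> None:
        if not mask.any():
            out[f"{prefix}_area_um2"] = 0.0
            out[f"{prefix}_eccentricity"] = 0.0
            out[f"{prefix}_perimeter_um"] = 0.0
            out[f"{prefix}_solidity"] = 0.0
            return
        props = measure.regionprops(mask.astype(np.uint8))[0]
        out[f"{prefix}_area_um2"] = float(props.area) * px2
        out[f"{prefix}_eccentricity"] = float(props.eccentricity)
        out[f"{prefix}_perimeter_um"] = float(props.perimeter) * frame.pixel_size
        out[f"{prefix}_solidity"] = float(props.solidity)

    _shape_stats(event.cell_mask, "cell")
    _shape_stats(event.nucleus_mask, "nucleus")
    for ch in CHANNELS:
        vals = frame.plane(ch)[event.cell_mask]
        out[f"{ch}_median"] = float(np.median(vals))
        out[f"{ch}_mean"] = float(vals.mean())
        out[f"{ch}_sd"] = float(vals.std())
        out[f"{ch}_max"] = float(vals.max())
    return out


def detect_frame(frame: FrameImage, params: DetectionParams,
                 gates: Gates | None = None) -> pd.DataFrame:
    """Segment one frame and return its event/feature table (no filtering)."""
    gates = gates or gates_from_frame(frame.planes, params.gate_k)
    nuclei = segment_nuclei(frame, params, gates)
    cells = segment_cells(frame, nuclei, params, gates)
    acellular = segment_acellular_ck(frame, nuclei, params, gates)
    # mask-to-mask gap from each acellular candidate to the nearest cell,
    # in µm, for downstream oncosome proximity labelling
    gap_um: dict[str, float] = {}
    if acellular:
        cells_union = np.zeros(frame.shape, dtype=bool)
        for ev in cells:
            cells_union |= ev.cell_mask
        if cells_union.any():
            dist = ndimage.distance_transform_edt(~cells_union) * frame.pixel_size
            for ev in acellular:
                gap_um[ev.event_id] = float(dist[ev.cell_mask].min())
        else:
            gap_um = {ev.event_id: np.inf for ev in acellular}
    rows = []
    h, w = frame.shape
    for ev in cells + acellular:
        feats = extract_features(ev, frame)
        rr, cc = np.nonzero(ev.cell_mask)
        touches = bool(rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1)
        sat_frac = 0.0
        if params.saturation_level is not None:
            sat_frac = float(
                (frame.planes[:, ev.cell_mask] >= params.saturation_level).mean())
        rows.append({
            "event_id": ev.event_id, "slide_id": ev.slide_id,
            "frame_index": ev.frame_index,
            "row": ev.centroid[0], "col": ev.centroid[1],
            "is_nucleated": ev.is_nucleated, "cluster_size": ev.cluster_size,
            "touches_border": touches, "saturation_fraction": sat_frac,
            "nearest_cell_gap_um": gap_um.get(ev.event_id, np.nan),
            **feats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rare-candidate selection (outliers from the leukocyte background)
# ---------------------------------------------------------------------------

def select_rare_candidates(
    features: pd.DataFrame,
    params: DetectionParams,
    gates: Gates,
    random_state: int = 0,
) -> pd.Series:
    """Flag rare-event candidates per slide.

    Fits a robust location/scatter model (minimum covariance determinant)
    of the dominant leukocyte background — nucleated, CD45/CD31-positive,
    CK/Vim-negative events — in a small morphometric feature space, and
    flags any event whose robust Mahalanobis distance exceeds the
    configured quantile.  CK- or Vim-gate-positive events and acellular
    candidates are always flagged (the flag rule is a disjunction), so the
    flagged set is a superset of threshold-positive events.
    """
    if len(features) < params.min_events_for_background:
        raise ValueError(
            f"only {len(features)} events; need >= {params.min_events_for_background} "
            "to fit the background model — pool more frames")
    nucleated = features["nucleus_area_um2"].astype(float) > 0
    ck_pos = features["ck_median"].astype(float) >= gates["ck"]
    vim_pos = features["vim_median"].astype(float) >= gates["vim"]
    cd_pos = features["cd_median"].astype(float) >= gates["cd"]
    background = nucleated & cd_pos & ~ck_pos & ~vim_pos

    flagged = ck_pos | vim_pos | ~nucleated
    cols = [c for c in params.outlier_features if c in features.columns]
    if background.sum() >= params.min_events_for_background:
        x_bg = features.loc[background, cols].to_numpy(dtype=float)
        keep = [j for j in range(x_bg.shape[1]) if np.std(x_bg[:, j]) > 0]
        if keep:
            x_bg = x_bg[:, keep]
            mcd = MinCovDet(random_state=random_state).fit(x_bg)
            x_all = features[cols].to_numpy(dtype=float)[:, keep]
            d2 = mcd.mahalanobis(x_all)
            # Hotelling-style F cutoff on the robust distance: the asymptotic
            # chi-square quantile under-covers when the background sample is
            # small, and an empirical quantile of the gate-selected background
            # would be contaminated by marker-negative rare cells
            n_bg, p_dim = x_bg.shape
            if n_bg > p_dim + 1:
                cutoff = float(
                    p_dim * (n_bg - 1) / (n_bg - p_dim)
                    * f_dist.ppf(params.outlier_quantile, p_dim, n_bg - p_dim))
            else:  # pragma: no cover - background barely above the minimum
                cutoff = float(chi2.ppf(params.outlier_quantile, df=p_dim))
            flagged = flagged | pd.Series(d2 > cutoff, index=features.index)
    return flagged.rename("rare_flagged")


# ---------------------------------------------------------------------------
# artifact filtering
# ---------------------------------------------------------------------------

def filter_artifacts(features: pd.DataFrame, params: DetectionParams
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove artifact-like events; returns (retained, removed-with-rule).

    Rules: frame-border contact, saturated pixels above the allowed
    fraction, area outside the configured bounds, and acellular candidates
    failing the roundness criterion (debris, streaks).
    """
    rules = pd.Series("", index=features.index, dtype=object)
    border = features["touches_border"].astype(bool)
    rules[border] = "border"
    sat = features["saturation_fraction"].astype(float) > params.saturation_max_fraction
    rules[sat & (rules == "")] = "saturation"
    area = features["cell_area_um2"].astype(float)
    bad_area = (area < params.min_event_area_um2) | (area > params.max_event_area_um2)
    rules[bad_area & (rules == "")] = "area"
    acellular = features["nucleus_area_um2"].astype(float) <= 0
    not_round = acellular & (features["cell_eccentricity"].astype(float)
                             > params.roundness_max_eccentricity)
    rules[not_round & (rules == "")] = "roundness"
    removed = features[rules != ""].copy()
    removed["removal_rule"] = rules[rules != ""]
    return features[rules == ""].copy(), removed
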