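"""Channel positivity calls and channel-type classification.

Positivity is decided per channel either by an intensity gate (median over
the event mask at or above background + k x background sd) or by one of
three trained binary models (CK, Vim, CD45/CD31 — DAPI positivity is always
the threshold gate).  The positivity vector, together with whether the event
is nucleated, maps deterministically onto the twelve rare-event categories:
eight nucleated phenotypes and four round, DAPI-negative, CK-positive
oncosome phenotypes.  Oncosomes additionally get a proximity label: proximal
when their mask lies within an adjacency distance D of a nucleated cell,
distal otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .categories import CHANNELS, ChannelType, PositivityVector

ML_CHANNELS = ("ck", "vim", "cd")  # DAPI stays threshold-gated


@dataclass(frozen=True)
class Gates:
    """Per-channel positivity thresholds: background_level + k x background_sd."""

    thresholds: dict[str, float]
    k: float = 5.0

    def __getitem__(self, channel: str) -> float:
        if channel not in self.thresholds:
            raise KeyError(f"no gate calibrated for channel {channel!r}")
        return self.thresholds[channel]

    @classmethod
    def from_background(cls, level: tuple[float, ...], sd: tuple[float, ...],
                        k: float = 5.0) -> "Gates":
        return cls({ch: level[i] + k * sd[i] for i, ch in enumerate(CHANNELS)}, k)


def estimate_background(plane: np.ndarray) -> tuple[float, float]:
    """Robust (level, sd) of a frame's background: median and scaled MAD.

    Valid while foreground covers well under half the frame, which holds at
    the plating densities this pipeline targets.
    """
    level = float(np.median(plane))
    mad = float(np.median(np.abs(plane - level)))
    return level, 1.4826 * mad


def gates_from_frame(planes: np.ndarray, k: float = 5.0) -> Gates:
    """Calibrate per-channel gates from one frame's background statistics."""
    thresholds = {}
    for i, ch in enumerate(CHANNELS):
        level, sd = estimate_background(planes[i])
        thresholds[ch] = level + k * sd
    return Gates(thresholds, k)


def call_positivity_threshold(features: pd.DataFrame | pd.Series, gates: Gates) -> pd.DataFrame:
    """Threshold positivity: channel positive iff median intensity >= gate.

    Accepts one event (Series) or a feature table; returns a DataFrame with
    boolean columns ``pos_dapi``..``pos_cd``.  The at-the-gate case counts
    as positive (>= convention).
    """
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    out = pd.DataFrame(index=features.index)
    for ch in CHANNELS:
        col = f"{ch}_median"
        if col not in features.columns:
            raise KeyError(f"feature table lacks {col}")
        out[f"pos_{ch}"] = features[col].astype(float) >= gates[ch]
    return out


# ---------------------------------------------------------------------------
# channel-type truth table
# ---------------------------------------------------------------------------

def classify_channel_type(
    pv: PositivityVector,
    is_nucleated: bool,
    is_rare_flagged: bool = True,
    roundness_ok: bool = True,
) -> ChannelType:
    """Map a positivity vector to one of the twelve rare categories.

    Nucleated events (DAPI+) split on their (CK, Vim, CD45/CD31) pattern:
    CK+Vim-CD- is an epithelial-like CTC, CK+Vim+CD- mesenchymal-like, and
    so on down to DAPI-only.  The DAPI|CD45/CD31 pattern is the common
    leukocyte phenotype and is reported as rare only when the event was
    outlier-flagged.  Acellular events are oncosomes only when CK-positive
    and round; their subtype follows the (Vim, CD) pattern.
    """
    if pv.dapi != is_nucleated:
        raise ValueError(
            f"inconsistent event: dapi positivity {pv.dapi} but is_nucleated={is_nucleated}")
    ck, vim, cd = pv.ck, pv.vim, pv.cd
    if is_nucleated:
        if ck and not vim and not cd:
            return ChannelType.EPI_CTC
        if ck and vim and not cd:
            return ChannelType.MES_CTC
        if ck and vim and cd:
            return ChannelType.D_CK_V_CD
        if ck and not vim and cd:
            return ChannelType.D_CK_CD
        if not ck and vim and cd:
            return ChannelType.D_V_CD
        if not ck and vim and not cd:
            return ChannelType.D_V
        if not ck and not vim and cd:
            return ChannelType.D_CD if is_rare_flagged else ChannelType.COMMON
        return ChannelType.DAPI_ONLY
    # acellular: oncosome requires cytokeratin and roundness
    if not ck or not roundness_ok:
        return ChannelType.UNCLASSIFIED
    if vim and cd:
        return ChannelType.ONC_CK_V_CD
    if vim:
        return ChannelType.ONC_CK_V
    if cd:
        return ChannelType.ONC_CK_CD
    return ChannelType.ONC_CK


def classify_events(
    features: pd.DataFrame,
    positivity: pd.DataFrame,
    flagged: pd.Series | None = None,
    roundness_max_eccentricity: float = 0.8,
) -> pd.Series:
    """Vectorised channel-type call for an event table.

    ``features`` must carry ``nucleus_area_um2`` (> 0 marks nucleated
    events) and ``cell_eccentricity``; ``positivity`` the ``pos_*`` columns.
    For nucleated events the DAPI gate decides is_nucleated consistency:
    rows whose DAPI call disagrees with their nucleation are returned
    UNCLASSIFIED rather than raising, since real tables mix both kinds.
    """
    if flagged is None:
        flagged = pd.Series(True, index=features.index)
    labels = []
    for idx, row in features.iterrows():
        nucleated = bool(row["nucleus_area_um2"] > 0)
        pv = PositivityVector(
            bool(positivity.loc[idx, "pos_dapi"]),
            bool(positivity.loc[idx, "pos_ck"]),
            bool(positivity.loc[idx, "pos_vim"]),
            bool(positivity.loc[idx, "pos_cd"]),
        )
        if pv.dapi != nucleated:
            labels.append(ChannelType.UNCLASSIFIED.value)
            continue
        round_ok = bool(row["cell_eccentricity"] <= roundness_max_eccentricity)
        labels.append(
            classify_channel_type(pv, nucleated, bool(flagged.loc[idx]), round_ok).value)
    return pd.Series(labels, index=features.index, name="category")


# ---------------------------------------------------------------------------
# machine-learning positivity
# ---------------------------------------------------------------------------

@dataclass
class PositivityModel:
    """One trained binary channel-positivity classifier plus its metadata."""

    channel: str
    model: RandomForestClassifier
    feature_names: list[str]
    n_train: int
    seed: int
    holdout_accuracy: float


def augment_context(features: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Append frame-level and slide-level mean/sd of every feature column.

    Mirrors training on cell-level parameters plus their frame and slide
    context so the models can absorb frame- and slide-wise staining
    variability.  Zero-variance groups yield sd 0 (not NaN).
    """
    out = features[feature_cols].copy()
    frame_grp = features.groupby(["slide_id", "frame_index"])[feature_cols]
    slide_grp = features.groupby("slide_id")[feature_cols]
    f_mean = frame_grp.transform("mean")
    f_sd = frame_grp.transform("std").fillna(0.0)
    s_mean = slide_grp.transform("mean")
    s_sd = slide_grp.transform("std").fillna(0.0)
    for col in feature_cols:
        out[f"frame_mean_{col}"] = f_mean[col]
        out[f"frame_sd_{col}"] = f_sd[col]
        out[f"slide_mean_{col}"] = s_mean[col]
        out[f"slide_sd_{col}"] = s_sd[col]
    return out


def train_positivity_models(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    feature_cols: list[str],
    seed: int = 0,
    test_size: float = 0.25,
    n_estimators: int = 100,
) -> dict[str, PositivityModel]:
    """Train one random-forest positivity model per non-DAPI channel.

    ``labels`` holds boolean truth columns named like the channels
    (ck, vim, cd).  A stratified held-out split reports each model's
    accuracy.  Raises if any channel's labels are single-class.
    """
    x = augment_context(features, feature_cols)
    models: dict[str, PositivityModel] = {}
    for i, ch in enumerate(ML_CHANNELS):
        y = labels[ch].astype(bool).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError(f"channel {ch}: training labels are single-class")
        x_tr, x_te, y_tr, y_te = train_test_split(
            x.to_numpy(), y, test_size=test_size, stratify=y, random_state=seed + i)
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed + i,
                                    n_jobs=1)
        rf.fit(x_tr, y_tr)
        acc = float(rf.score(x_te, y_te))
        models[ch] = PositivityModel(ch, rf, list(x.columns), len(y_tr), seed, acc)
    return models


def call_positivity_ml(
    models: dict[str, PositivityModel],
    features: pd.DataFrame,
    gates: Gates,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Model-based positivity: CK/Vim/CD from the forests, DAPI from the gate."""
    feature_cols = feature_cols or [
        c for c in models[ML_CHANNELS[0]].feature_names if not c.startswith(
            ("frame_mean_", "frame_sd_", "slide_mean_", "slide_sd_"))]
    x = augment_context(features, feature_cols)
    out = pd.DataFrame(index=features.index)
    out["pos_dapi"] = features["dapi_median"].astype(float) >= gates["dapi"]
    for ch in ML_CHANNELS:
        model = models[ch]
        if list(x.columns) != model.feature_names:
            raise ValueError(f"feature columns do not match channel {ch} model")
        out[f"pos_{ch}"] = model.model.predict(x.to_numpy()).astype(bool)
    return out


# ---------------------------------------------------------------------------
# oncosome proximity
# ---------------------------------------------------------------------------

def assign_oncosome_proximity(
    oncosome_mask: np.ndarray,
    cell_masks: list[np.ndarray] | np.ndarray,
    adjacency_distance_um: float,
    pixel_size: float,
) -> str:
    """'proximal' iff the mask-to-mask gap to any nucleated cell is <= D."""
    if isinstance(cell_masks, list):
        if not cell_masks:
            return "distal"
        cells = np.zeros_like(oncosome_mask, dtype=bool)
        for m in cell_masks:
            cells |= m
    else:
        cells = cell_masks.astype(bool)
    if not cells.any():
        return "distal"
    dist_to_cells = ndimage.distance_transform_edt(~cells)
    gap_px = float(dist_to_cells[oncosome_mask].min())
    return "proximal" if gap_px * pixel_size <= adjacency_distance_um else "distal"
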