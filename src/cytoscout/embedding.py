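"""Morphometric heterogeneity analysis: tSNE embedding and density profiles.

The feature space is the eight-column morphometric summary — the median
intensity of the four channels plus cell/nucleus area and eccentricity —
standardised column-wise before embedding.  Plots are artifacts; the numeric
coordinates and density curves are the analysis surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

MORPHOMETRIC_COLUMNS = (
    "dapi_median", "ck_median", "vim_median", "cd_median",
    "cell_area_um2", "nucleus_area_um2",
    "cell_eccentricity", "nucleus_eccentricity",
)


@dataclass
class EmbeddingResult:
    """2-D embedding plus the exact standardisation constants used."""

    event_ids: list[str]
    coordinates: np.ndarray  # (n, 2)
    perplexity: float
    n_iter: int
    seed: int
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray


def build_morphometric_matrix(
    events: pd.DataFrame,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Standardised morphometric matrix: (matrix, kept columns, means, sds).

    Each column is scaled to zero mean / unit variance; zero-variance
    columns are dropped with a warning and recorded by their absence from
    the returned labels.
    """
    for col in MORPHOMETRIC_COLUMNS:
        if col not in events.columns:
            raise KeyError(f"missing morphometric column {col!r}")
        bad = events[col].isna()
        if bad.any():
            eid = events.loc[bad].iloc[0].get("event_id", events.index[bad][0])
            raise ValueError(f"missing feature {col!r} for event {eid}")
    raw = events[list(MORPHOMETRIC_COLUMNS)].to_numpy(dtype=float)
    means = raw.mean(axis=0)
    if raw.shape[0] == 1:  # a single event centres to zero; no scale defined
        return np.zeros_like(raw), list(MORPHOMETRIC_COLUMNS), means, np.ones(raw.shape[1])
    sds = raw.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(MORPHOMETRIC_COLUMNS, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    cols = [c for c, k in zip(MORPHOMETRIC_COLUMNS, keep) if k]
    matrix = (raw[:, keep] - means[keep]) / sds[keep]
    return matrix, cols, means[keep], sds[keep]


def embed_tsne(
    matrix: np.ndarray,
    event_ids: list[str] | None = None,
    perplexity: float = 30.0,
    n_iter: int = 500,
    seed: int = 0,
    columns: list[str] | None = None,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> EmbeddingResult:
    """Deterministic 2-D tSNE of a standardised feature matrix.

    Requires at least 3·perplexity rows; for smaller inputs the perplexity
    is reduced automatically with a warning (it must stay >= 2).
    """
    n = matrix.shape[0]
    if n < 6:
        raise ValueError("too few rows to embed; need at least 6 (reduce perplexity)")
    eff_perplexity = perplexity
    if n < 3 * perplexity:
        eff_perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; using {eff_perplexity:.1f}",
            stacklevel=2)
    tsne = TSNE(n_components=2, perplexity=eff_perplexity, max_iter=max(n_iter, 250),
                random_state=seed, init="pca")
    coords = tsne.fit_transform(matrix)
    if not np.isfinite(coords).all():  # pragma: no cover - defensive
        raise RuntimeError("embedding produced non-finite coordinates")
    ids = list(event_ids) if event_ids is not None else [str(i) for i in range(n)]
    return EmbeddingResult(ids, coords, eff_perplexity, n_iter, seed,
                           columns or [], means if means is not None else np.array([]),
                           sds if sds is not None else np.array([]))


def density_profiles(
    events: pd.DataFrame,
    parameter: str,
    category_col: str = "category",
    n_grid: int = 256,
) -> tuple[np.ndarray, dict[str, np.ndarray], list[str]]:
    """Per-category probability densities of one morphometric parameter.

    Returns (grid, {category: density}, flagged categories).  Densities are
    Gaussian KDEs normalised to unit area on a shared grid; categories with
    fewer than two events, or with zero variance (a degenerate spike), are
    flagged and omitted.
    """
    if parameter not in MORPHOMETRIC_COLUMNS:
        raise ValueError(f"parameter must be one of {MORPHOMETRIC_COLUMNS}")
    values = events[parameter].astype(float)
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo if hi > lo else max(abs(hi), 1.0))
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    curves: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    for cat, grp in events.groupby(category_col):
        v = grp[parameter].astype(float).to_numpy()
        if v.size < 2 or np.std(v) == 0:
            flagged.append(str(cat))
            continue
        kde = gaussian_kde(v)
        dens = kde(grid)
        dens = dens / np.trapezoid(dens, grid)  # renormalise on the finite grid
        curves[str(cat)] = dens
    return grid, curves, flagged


def plot_embedding(result: EmbeddingResult, categories: pd.Series, path: str) -> None:
    """Scatter of the embedding colour-coded by channel type (artifact only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    cats = categories.reindex(result.event_ids)
    for cat in sorted(cats.dropna().unique()):
        sel = (cats == cat).to_numpy()
        ax.scatter(result.coordinates[sel, 0], result.coordinates[sel, 1],
                   s=8, label=str(cat), alpha=0.7)
    ax.set_xlabel("tSNE-1")
    ax.set_ylabel("tSNE-2")
    ax.legend(fontsize=7, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
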