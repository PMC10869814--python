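"""Configuration objects for synthetic slide generation and pipeline runs.

The simulation emulates an enrichment-free slide-based liquid-biopsy assay:
the nucleated fraction of a blood draw is plated on glass slides (~3 million
cells per slide at full scale), stained in four channels and scanned as 2304
frames per slide.  The blood volume analysed by a slide is
``cells_plated / wbc_per_ml``, which converts event counts into events/mL.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .categories import ChannelType

#: frames acquired per slide by the full-scale scanning protocol
FULL_SCALE_FRAMES = 2304
#: full-scale plating target, nucleated cells per slide
FULL_SCALE_CELLS_PLATED = 3_000_000


@dataclass(frozen=True)
class DistributionSpec:
    """A small declarative spec for a 1-D sampling law.

    kinds:
      ``point``     — point mass at ``params['value']``
      ``lognormal`` — ``params['mean']`` and ``params['sigma']`` (log-scale sd);
                      the mean is the *arithmetic* mean of the law
      ``normal``    — ``params['mean']``, ``params['sd']``, optional
                      ``params['min']`` truncation (resampled)
      ``uniform``   — ``params['low']``, ``params['high']``
    """

    kind: str
    params: Mapping[str, float]

    def sample(self, rng: np.random.Generator, size: int | None = None) -> Any:
        p = self.params
        if self.kind == "point":
            value = float(p["value"])
            return value if size is None else np.full(size, value)
        if self.kind == "lognormal":
            sigma = float(p["sigma"])
            mu = np.log(float(p["mean"])) - 0.5 * sigma**2
            return rng.lognormal(mu, sigma, size=size)
        if self.kind == "normal":
            draw = rng.normal(float(p["mean"]), float(p["sd"]), size=size)
            lo = p.get("min")
            if lo is not None:
                lo = float(lo)
                # truncate by resampling; bounded retries then clip
                for _ in range(100):
                    bad = np.atleast_1d(draw) < lo
                    if not bad.any():
                        break
                    resampled = rng.normal(float(p["mean"]), float(p["sd"]), size=int(bad.sum()))
                    if size is None:
                        draw = float(resampled[0])
                    else:
                        draw = np.asarray(draw)
                        draw[bad] = resampled
                draw = np.maximum(draw, lo) if size is not None else max(float(draw), lo)
            return draw
        if self.kind == "uniform":
            return rng.uniform(float(p["low"]), float(p["high"]), size=size)
        raise ValueError(f"unknown distribution kind: {self.kind!r}")

    def mean(self) -> float:
        p = self.params
        if self.kind == "point":
            return float(p["value"])
        if self.kind == "lognormal":
            return float(p["mean"])
        if self.kind == "normal":
            return float(p["mean"])
        if self.kind == "uniform":
            return 0.5 * (float(p["low"]) + float(p["high"]))
        raise ValueError(f"unknown distribution kind: {self.kind!r}")


def _default_rare_rates() -> dict[ChannelType, float]:
    # Illustrative defaults (events/mL).  The relative pattern follows the
    # qualitative picture of pancreatic-cancer blood draws — oncosomes are the
    # most frequent rare events, classical Epi/Mes CTCs the least — but the
    # magnitudes are configuration, not biology.
    return {
        ChannelType.EPI_CTC: 2.0,
        ChannelType.MES_CTC: 1.0,
        ChannelType.D_CK_V_CD: 1.0,
        ChannelType.D_CK_CD: 1.0,
        ChannelType.D_V_CD: 5.0,
        ChannelType.D_V: 5.0,
        ChannelType.D_CD: 8.0,
        ChannelType.DAPI_ONLY: 8.0,
        ChannelType.ONC_CK: 20.0,
        ChannelType.ONC_CK_V: 6.0,
        ChannelType.ONC_CK_CD: 6.0,
        ChannelType.ONC_CK_V_CD: 2.0,
    }


def _default_wbc_law() -> DistributionSpec:
    # Arithmetic mean 7.49e6 with log-sd 0.472 puts the median near 6.7e6 and
    # the central 95% range near 2.6-17e6 cells/mL, matching adult blood counts.
    return DistributionSpec("lognormal", {"mean": 7.49e6, "sigma": 0.472})


def _default_cluster_law() -> dict[int, float]:
    return {1: 0.85, 2: 0.10, 3: 0.03, 4: 0.02}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic slide generator.

    Geometry defaults are desk-scale: 64 frames of 512x512 px at 0.2 µm/px
    (full-scale acquisition is 2304 frames).  ``cells_plated_per_slide`` is the
    full-scale plating target used for events/mL normalisation in
    feature-table mode; in rendered mode the normalisation uses the number of
    common cells actually planted so the events/mL arithmetic stays exact at
    any scale.
    """

    frames_per_slide: int = 64
    frame_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.2  # µm per pixel
    cells_plated_per_slide: int = FULL_SCALE_CELLS_PLATED
    common_cells_per_frame: int = 12  # rendered-mode planting density
    wbc_per_ml_law: DistributionSpec = field(default_factory=_default_wbc_law)
    rare_rates: dict[ChannelType, float] = field(default_factory=_default_rare_rates)
    oncosome_proximal_fraction: float = 0.3
    cluster_size_law: dict[int, float] = field(default_factory=_default_cluster_law)
    # intensity model: additive amplitudes over a Gaussian background
    background_level: tuple[float, float, float, float] = (100.0, 100.0, 100.0, 100.0)
    background_sd: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 10.0)
    intensity_laws: dict[tuple[str, str], DistributionSpec] = field(default_factory=dict)
    default_amplitude: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "normal", {"mean": 100.0, "sd": 15.0, "min": 50.0}
        )
    )
    # morphology (µm); rare nucleated events are larger than leukocytes,
    # which is what makes marker-negative rare phenotypes separable at all
    nucleus_diameter: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("uniform", {"low": 8.0, "high": 12.0})
    )
    rare_cell_nucleus_diameter: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("uniform", {"low": 15.0, "high": 22.0})
    )
    oncosome_diameter: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("uniform", {"low": 2.0, "high": 8.0})
    )
    cytoplasm_scale: float = 1.6  # cell ellipse axes / nucleus axes
    adjacency_distance_um: float = 2.0  # oncosome-to-cell gap defining "proximal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frames_per_slide < 1:
            raise ValueError("frames_per_slide must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 <= self.oncosome_proximal_fraction <= 1.0:
            raise ValueError("oncosome_proximal_fraction must be in [0, 1]")
        for cat, rate in self.rare_rates.items():
            if rate < 0:
                raise ValueError(f"rare rate for {cat} must be >= 0")
        if self.cells_plated_per_slide < 1:
            raise ValueError("cells_plated_per_slide must be >= 1")
        total = sum(self.cluster_size_law.values())
        if not np.isclose(total, 1.0):
            raise ValueError("cluster_size_law probabilities must sum to 1")

    def amplitude_law(self, category: ChannelType, channel: str) -> DistributionSpec:
        """Amplitude law for a (category, channel) pair, falling back to the default."""
        return self.intensity_laws.get((category.value, channel), self.default_amplitude)


@dataclass
class CohortDesign:
    """Cohort layout: which (cohort, site, timepoint) arms each patient contributes.

    ``arms`` entries are (cohort, site, timepoint) with cohort in {PDAC, ND},
    site in {PB, PoVB} (peripheral vs portal-vein blood) and timepoint in
    {Pre, During, Post} relative to surgical manipulation.  ND donors
    contribute a single PB/Pre draw.  ``effect_multipliers`` scales the rare
    rates of one arm, keyed by ((cohort, site, timepoint), category);
    a key of ((...), "*") applies to every category.
    """

    n_patients: int = 8
    arms: Sequence[tuple[str, str, str]] = (
        ("PDAC", "PB", "Pre"),
        ("PDAC", "PB", "Post"),
    )
    effect_multipliers: dict[tuple[tuple[str, str, str], str], float] = field(
        default_factory=dict
    )
    slides_per_test: int = 2

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.arms:
            raise ValueError("design must contain at least one arm")
        for arm in self.arms:
            cohort, site, timepoint = arm
            if cohort not in ("PDAC", "ND"):
                raise ValueError(f"unknown cohort {cohort!r}")
            if site not in ("PB", "PoVB"):
                raise ValueError(f"unknown site {site!r}")
            if timepoint not in ("Pre", "During", "Post"):
                raise ValueError(f"unknown timepoint {timepoint!r}")
            if cohort == "ND" and (site, timepoint) != ("PB", "Pre"):
                raise ValueError("ND arms are PB/Pre only")
        for key, mult in self.effect_multipliers.items():
            if mult <= 0:
                raise ValueError(f"effect multiplier for {key} must be > 0")
        if self.slides_per_test < 1:
            raise ValueError("slides_per_test must be >= 1")

    def multiplier(self, arm: tuple[str, str, str], category: ChannelType) -> float:
        m = self.effect_multipliers.get((tuple(arm), category.value), 1.0)
        m *= self.effect_multipliers.get((tuple(arm), "*"), 1.0)
        return m


def _spec_to_dict(spec: DistributionSpec) -> dict[str, Any]:
    return {"kind": spec.kind, "params": dict(spec.params)}


def _spec_from_dict(d: Mapping[str, Any]) -> DistributionSpec:
    return DistributionSpec(d["kind"], dict(d["params"]))


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Serialise a SimulationConfig to plain YAML/JSON-safe types."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, DistributionSpec):
            out[f.name] = _spec_to_dict(value)
        elif f.name == "rare_rates":
            out[f.name] = {cat.value: rate for cat, rate in value.items()}
        elif f.name == "intensity_laws":
            out[f.name] = {
                f"{cat}:{chan}": _spec_to_dict(spec) for (cat, chan), spec in value.items()
            }
        elif f.name == "cluster_size_law":
            out[f.name] = {int(k): float(v) for k, v in value.items()}
        elif isinstance(value, tuple):
            out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


def config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    kwargs: dict[str, Any] = dict(d)
    for key in ("wbc_per_ml_law", "default_amplitude", "nucleus_diameter",
                "rare_cell_nucleus_diameter", "oncosome_diameter"):
        if key in kwargs and isinstance(kwargs[key], Mapping):
            kwargs[key] = _spec_from_dict(kwargs[key])
    if "rare_rates" in kwargs:
        kwargs["rare_rates"] = {
            ChannelType(k): float(v) for k, v in kwargs["rare_rates"].items()
        }
    if "intensity_laws" in kwargs:
        laws = {}
        for key, spec in kwargs["intensity_laws"].items():
            cat, chan = key.split(":")
            laws[(cat, chan)] = _spec_from_dict(spec)
        kwargs["intensity_laws"] = laws
    if "cluster_size_law" in kwargs:
        kwargs["cluster_size_law"] = {
            int(k): float(v) for k, v in kwargs["cluster_size_law"].items()
        }
    for key in ("frame_shape", "background_level", "background_sd"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


def load_config(path: str) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
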