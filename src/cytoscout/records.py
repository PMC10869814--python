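"""Slide, sample and frame record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CHANNELS


@dataclass
class SlideRecord:
    """One slide: the plated aliquot of a blood draw.

    The blood volume analysed by the slide is ``cells_plated / wbc_per_ml``
    (nucleated cells plated divided by the blood's WBC concentration), which
    is what converts raw event counts into events/mL.
    """

    slide_id: str
    sample_id: str
    wbc_per_ml: float
    cells_plated: int

    def __post_init__(self) -> None:
        if self.wbc_per_ml <= 0:
            raise ValueError("wbc_per_ml must be > 0")
        if self.cells_plated <= 0:
            raise ValueError("cells_plated must be > 0")

    @property
    def ml_analyzed(self) -> float:
        return self.cells_plated / self.wbc_per_ml


@dataclass
class SampleRecord:
    """One blood draw (test): cohort arm plus its slides."""

    sample_id: str
    patient_id: str
    cohort: str  # PDAC | ND
    site: str  # PB | PoVB
    timepoint: str  # Pre | During | Post
    slide_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cohort == "ND" and (self.site, self.timepoint) != ("PB", "Pre"):
            raise ValueError("ND samples are PB/Pre only")
        if not self.slide_ids:
            raise ValueError("slide_ids must be non-empty")


@dataclass
class FrameImage:
    """One 4-channel frame: intensity planes in the order DAPI, CK, Vim, CD45/CD31."""

    slide_id: str
    frame_index: int
    planes: np.ndarray  # shape (4, H, W)
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(CHANNELS):
            raise ValueError("planes must have shape (4, H, W)")
        if (self.planes < 0).any():
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, channel: str) -> np.ndarray:
        return self.planes[CHANNELS.index(channel)]
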