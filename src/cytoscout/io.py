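"""File I/O: multi-page TIFF frames and tab-delimited tables.

Frames are written one TIFF per frame with one page per channel in the
fixed order DAPI, CK, Vim, CD45/CD31; pixel size (µm) travels in the image
description.  All tables are UTF-8 TSV with a header row.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import tifffile

from .records import FrameImage

_FRAME_RE = re.compile(r"^(?P<slide>.+)_F(?P<frame>\d+)\.tiff?$")


def frame_filename(slide_id: str, frame_index: int) -> str:
    return f"{slide_id}_F{frame_index:04d}.tif"


def write_frame(frame: FrameImage, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / frame_filename(frame.slide_id, frame.frame_index)
    meta = json.dumps({"pixel_size_um": frame.pixel_size,
                       "channels": ["DAPI", "CK", "Vim", "CD45/CD31"]})
    tifffile.imwrite(path, frame.planes.astype(np.float32), description=meta,
                     photometric="minisblack")
    return path


def write_frames(frames: Iterable[FrameImage], directory: str | Path) -> list[Path]:
    return [write_frame(f, directory) for f in frames]


def read_frame(path: str | Path, pixel_size: float | None = None) -> FrameImage:
    path = Path(path)
    m = _FRAME_RE.match(path.name)
    if not m:
        raise ValueError(f"not a frame file name: {path.name}")
    with tifffile.TiffFile(path) as tif:
        planes = tif.asarray().astype(float)
        if pixel_size is None:
            desc = tif.pages[0].description or "{}"
            try:
                pixel_size = float(json.loads(desc).get("pixel_size_um", 0.2))
            except (ValueError, json.JSONDecodeError):
                pixel_size = 0.2
    return FrameImage(m["slide"], int(m["frame"]), planes, pixel_size)


def iter_frames(directory: str | Path, pixel_size: float | None = None
                ) -> Iterator[FrameImage]:
    for path in sorted(Path(directory).glob("*.tif*")):
        if _FRAME_RE.match(path.name):
            yield read_frame(path, pixel_size)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, encoding="utf-8")
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", **kwargs)
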