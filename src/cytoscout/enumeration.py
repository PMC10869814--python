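"""WBC-normalised enumeration: classified events -> events/mL per sample.

A test pools its slides: events/mL = (count over the sample's slides) /
(sum of mL analysed), where each slide's mL is cells plated / blood WBC
concentration.  Clusters (one contiguous cell mask with several nuclei)
count once; cluster_size is retained as an attribute.  Derived totals:

    total_events    = total_cells + total_oncosomes
    total_oncosomes = oncosomes_distal + oncosomes_proximal
    total_ck_cells  = Epi.CTC + Mes.CTC + D|CK|V|CD + D|CK|CD
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .categories import (
    CELLULAR_CATEGORIES,
    CK_CELLULAR_CATEGORIES,
    ONCOSOME_CATEGORIES,
    RARE_CATEGORIES,
    ChannelType,
)
from .records import SampleRecord, SlideRecord

TOTAL_COLUMNS = (
    "total_events",
    "total_cells",
    "total_ck_cells",
    "total_oncosomes",
    "oncosomes_distal",
    "oncosomes_proximal",
)

ANALYTE_COLUMNS: tuple[str, ...] = tuple(c.value for c in RARE_CATEGORIES) + TOTAL_COLUMNS


def compute_ml_analyzed(slide: SlideRecord) -> float:
    """mL of blood represented by one slide: cells plated / WBC per mL."""
    if slide.wbc_per_ml <= 0:
        raise ValueError("wbc_per_ml must be > 0")
    return slide.cells_plated / slide.wbc_per_ml


def enumerate_sample(
    events: pd.DataFrame,
    slides: Sequence[SlideRecord],
    sample_id: str,
) -> pd.DataFrame:
    """Long-form enumeration rows (sample x rare category) for one sample.

    ``events`` needs columns slide_id, category and (for oncosomes)
    proximity; only rows belonging to the sample's slides are expected.
    """
    slide_ids = {s.slide_id for s in slides}
    if len(events) and not set(events["slide_id"]).issubset(slide_ids):
        unknown = set(events["slide_id"]) - slide_ids
        raise ValueError(f"events reference unknown slides: {sorted(unknown)}")
    ml_total = sum(compute_ml_analyzed(s) for s in slides)

    counts = {cat.value: 0 for cat in RARE_CATEGORIES}
    distal = proximal = 0
    for _, ev in events.iterrows():
        cat = ev["category"]
        cat = cat.value if isinstance(cat, ChannelType) else str(cat)
        if cat not in counts:
            continue  # common / unclassified events are not enumerated
        counts[cat] += 1
        if ChannelType(cat) in ONCOSOME_CATEGORIES:
            if str(ev.get("proximity", "distal")) == "proximal":
                proximal += 1
            else:
                distal += 1

    rows = [
        {
            "sample_id": sample_id,
            "category": cat,
            "count": n,
            "ml_analyzed": ml_total,
            "events_per_ml": n / ml_total,
        }
        for cat, n in counts.items()
    ]
    long = pd.DataFrame(rows)
    long.attrs["oncosomes_distal"] = distal
    long.attrs["oncosomes_proximal"] = proximal
    return long


def derive_totals(long: pd.DataFrame) -> pd.DataFrame:
    """Wide per-sample table with per-category events/mL plus derived totals."""
    if len(long) == 0:
        return pd.DataFrame(columns=("sample_id",) + ANALYTE_COLUMNS).set_index("sample_id")
    cellular = {c.value for c in CELLULAR_CATEGORIES}
    onco = {c.value for c in ONCOSOME_CATEGORIES}
    ck_cells = {c.value for c in CK_CELLULAR_CATEGORIES}

    out_rows = []
    for sample_id, grp in long.groupby("sample_id", sort=True):
        per_ml = dict(zip(grp["category"], grp["events_per_ml"]))
        counts = dict(zip(grp["category"], grp["count"]))
        ml = float(grp["ml_analyzed"].iloc[0])
        row: dict[str, float] = {"sample_id": sample_id, "ml_analyzed": ml}
        row.update({cat.value: per_ml.get(cat.value, 0.0) for cat in RARE_CATEGORIES})
        # totals derive from integer counts, and the proximal split is the
        # complement of the distal one, so the conservation identities
        # (events = cells + oncosomes; oncosomes = distal + proximal) hold
        # exactly in floating point
        row["total_cells"] = sum(counts.get(c, 0) for c in cellular) / ml
        row["total_oncosomes"] = sum(counts.get(c, 0) for c in onco) / ml
        row["total_events"] = row["total_cells"] + row["total_oncosomes"]
        row["total_ck_cells"] = sum(counts.get(c, 0) for c in ck_cells) / ml
        row["oncosomes_distal"] = grp.attrs.get("oncosomes_distal", 0) / ml
        row["oncosomes_proximal"] = row["total_oncosomes"] - row["oncosomes_distal"]
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("sample_id")


def enumerate_cohort(
    events: pd.DataFrame,
    slides: Mapping[str, SlideRecord] | Iterable[SlideRecord],
    samples: Iterable[SampleRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enumerate every sample; returns (long table, wide table with totals)."""
    if not isinstance(slides, Mapping):
        slides = {s.slide_id: s for s in slides}
    longs = []
    for sample in samples:
        sample_slides = [slides[sid] for sid in sample.slide_ids]
        ids = set(sample.slide_ids)
        sub = events[events["slide_id"].isin(ids)] if len(events) else events
        long = enumerate_sample(sub, sample_slides, sample.sample_id)
        longs.append(long)
    attrs_d = {lg["sample_id"].iloc[0]: lg.attrs for lg in longs}
    long_all = pd.concat(longs, ignore_index=True)
    wides = []
    for lg in longs:
        wides.append(derive_totals(lg))
    wide = pd.concat(wides)
    # re-attach the per-sample oncosome split lost by concat
    for sid, at in attrs_d.items():
        ml = wide.loc[sid, "ml_analyzed"]
        distal = at.get("oncosomes_distal", 0) / ml
        wide.loc[sid, "oncosomes_distal"] = distal
        wide.loc[sid, "oncosomes_proximal"] = wide.loc[sid, "total_oncosomes"] - distal
    return long_all, wide.sort_index()
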