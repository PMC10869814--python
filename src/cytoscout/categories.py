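"""Rare-event taxonomy for 4-channel immunofluorescence liquid biopsy data.

Events are stained with DAPI (nuclear DNA), a cytokeratin cocktail (CK),
vimentin (Vim) and a shared CD45/CD31 exclusion channel.  Twelve rare-event
categories are defined by the positivity pattern: eight nucleated (cellular)
phenotypes and four acellular oncosome phenotypes (round, CK-positive,
DAPI-negative extracellular vesicles).  The dominant background population,
DAPI+/CD45-CD31+ leukocytes, is labelled COMMON.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

CHANNELS = ("dapi", "ck", "vim", "cd")
"""Fixed channel order: DAPI, CK, Vim, CD45/CD31."""


class ChannelType(str, Enum):
    """Channel-type classification of a segmented event."""

    # cellular rare phenotypes (nucleated, DAPI+)
    EPI_CTC = "Epi.CTC"            # CK+ Vim- CD-
    MES_CTC = "Mes.CTC"            # CK+ Vim+ CD-
    D_CK_V_CD = "D|CK|V|CD"        # positive in all four channels
    D_CK_CD = "D|CK|CD"
    D_V_CD = "D|V|CD"
    D_V = "D|V"
    D_CD = "D|CD"                  # rare only when outlier-flagged
    DAPI_ONLY = "DAPI-only"
    # oncosome phenotypes (acellular, DAPI-, CK+, round)
    ONC_CK = "Onc.CK"
    ONC_CK_V = "Onc.CK|V"
    ONC_CK_CD = "Onc.CK|CD"
    ONC_CK_V_CD = "Onc.CK|V|CD"
    # non-rare outcomes
    COMMON = "common"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CELLULAR_CATEGORIES: tuple[ChannelType, ...] = (
    ChannelType.EPI_CTC,
    ChannelType.MES_CTC,
    ChannelType.D_CK_V_CD,
    ChannelType.D_CK_CD,
    ChannelType.D_V_CD,
    ChannelType.D_V,
    ChannelType.D_CD,
    ChannelType.DAPI_ONLY,
)

ONCOSOME_CATEGORIES: tuple[ChannelType, ...] = (
    ChannelType.ONC_CK,
    ChannelType.ONC_CK_V,
    ChannelType.ONC_CK_CD,
    ChannelType.ONC_CK_V_CD,
)

RARE_CATEGORIES: tuple[ChannelType, ...] = CELLULAR_CATEGORIES + ONCOSOME_CATEGORIES

#: cellular categories whose phenotype includes cytokeratin
CK_CELLULAR_CATEGORIES: tuple[ChannelType, ...] = (
    ChannelType.EPI_CTC,
    ChannelType.MES_CTC,
    ChannelType.D_CK_V_CD,
    ChannelType.D_CK_CD,
)


@dataclass(frozen=True)
class PositivityVector:
    """Per-channel boolean positivity calls (DAPI, CK, Vim, CD45/CD31)."""

    dapi: bool
    ck: bool
    vim: bool
    cd: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.dapi, self.ck, self.vim, self.cd)


#: ground-truth positivity pattern of each category
CATEGORY_POSITIVITY: dict[ChannelType, PositivityVector] = {
    ChannelType.EPI_CTC: PositivityVector(True, True, False, False),
    ChannelType.MES_CTC: PositivityVector(True, True, True, False),
    ChannelType.D_CK_V_CD: PositivityVector(True, True, True, True),
    ChannelType.D_CK_CD: PositivityVector(True, True, False, True),
    ChannelType.D_V_CD: PositivityVector(True, False, True, True),
    ChannelType.D_V: PositivityVector(True, False, True, False),
    ChannelType.D_CD: PositivityVector(True, False, False, True),
    ChannelType.DAPI_ONLY: PositivityVector(True, False, False, False),
    ChannelType.ONC_CK: PositivityVector(False, True, False, False),
    ChannelType.ONC_CK_V: PositivityVector(False, True, True, False),
    ChannelType.ONC_CK_CD: PositivityVector(False, True, False, True),
    ChannelType.ONC_CK_V_CD: PositivityVector(False, True, True, True),
    ChannelType.COMMON: PositivityVector(True, False, False, True),
}


def is_oncosome(category: ChannelType) -> bool:
    return category in ONCOSOME_CATEGORIES


def is_cellular(category: ChannelType) -> bool:
    return category in CELLULAR_CATEGORIES or category is ChannelType.COMMON
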