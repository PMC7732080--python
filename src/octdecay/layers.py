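"""Closed vocabularies: retinal layer names and ETDRS grid sectors.

Layer names follow the common OCT-segmentation abbreviations.  ``INNER``
is the composite RNFL + GCL + IPL + INL (the territory of the central
retinal artery); ``RETINA`` is the full-thickness measurement; ``CMT``
is central macular thickness (mean over the central 1-mm ETDRS disc).
INNER and RETINA are stored as observed layers in their own right and
are never recomputed as sums of components on real data.
"""

from __future__ import annotations

import enum


class LayerName(str, enum.Enum):
    RETINA = "RETINA"
    INNER = "INNER"
    RNFL = "RNFL"
    GCL = "GCL"
    IPL = "IPL"
    INL = "INL"
    CMT = "CMT"
    OPL = "OPL"
    ONL = "ONL"
    OUTER = "OUTER"
    RPE = "RPE"

    @classmethod
    def parse(cls, value: str) -> "LayerName":
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown layer name {value!r}; expected one of "
                f"{sorted(m.value for m in cls)}"
            ) from None


#: Components whose pre-noise sum defines the composite inner retina.
INNER_COMPONENTS = (LayerName.RNFL, LayerName.GCL, LayerName.IPL, LayerName.INL)

#: Additional components that, with INNER, sum to the full retina.
OUTER_COMPONENTS = (LayerName.OPL, LayerName.ONL, LayerName.OUTER, LayerName.RPE)


class Sector(str, enum.Enum):
    """ETDRS grid sectors.

    ``RING3_MEAN`` is the analysis unit of this package: the mean of the
    four 3-mm-ring quadrants.  Readers accept either quadrant-level rows
    (which :func:`octdecay.cohort.collapse_to_middle_ring` averages) or
    rows already collapsed to ``RING3_MEAN``.
    """

    CENTER_1MM = "CENTER_1MM"
    RING3_SUPERIOR = "RING3_SUPERIOR"
    RING3_NASAL = "RING3_NASAL"
    RING3_INFERIOR = "RING3_INFERIOR"
    RING3_TEMPORAL = "RING3_TEMPORAL"
    RING6_SUPERIOR = "RING6_SUPERIOR"
    RING6_NASAL = "RING6_NASAL"
    RING6_INFERIOR = "RING6_INFERIOR"
    RING6_TEMPORAL = "RING6_TEMPORAL"
    RING3_MEAN = "RING3_MEAN"

    @classmethod
    def parse(cls, value: str) -> "Sector":
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown ETDRS sector {value!r}; expected one of "
                f"{sorted(m.value for m in cls)}"
            ) from None


RING3_QUADRANTS = (
    Sector.RING3_SUPERIOR,
    Sector.RING3_NASAL,
    Sector.RING3_INFERIOR,
    Sector.RING3_TEMPORAL,
)

RING6_QUADRANTS = (
    Sector.RING6_SUPERIOR,
    Sector.RING6_NASAL,
    Sector.RING6_INFERIOR,
    Sector.RING6_TEMPORAL,
)
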