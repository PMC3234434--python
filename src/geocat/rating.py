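"""Preliminary IUCN Red List criterion-B category from EOO/AOO areas.

Criterion B rates restricted-range taxa from the extent of occurrence
(B1) and the area of occupancy (B2).  The thresholds are fixed constants
of the IUCN (2001) Categories and Criteria v3.1 standard:

====================  =========  =========
category              EOO (B1)   AOO (B2)
====================  =========  =========
CR                    < 100 km²  < 10 km²
EN                    < 5,000    < 500
VU                    < 20,000   < 2,000
====================  =========  =========

Comparisons are strict less-than; areas at or above the VU threshold get
the combined label "LC or NT".  The single preliminary rating is the more
threatened of the two per-metric categories.  It is *preliminary* because
a full criterion-B listing additionally requires subcriteria (severe
fragmentation, few locations, continuing decline, extreme fluctuation)
that range areas alone cannot establish.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class Category(IntEnum):
    """Threat categories ordered by severity (higher = more threatened)."""

    LC_OR_NT = 0
    VU = 1
    EN = 2
    CR = 3

    @property
    def label(self) -> str:
        return {
            Category.CR: "CR",
            Category.EN: "EN",
            Category.VU: "VU",
            Category.LC_OR_NT: "LC or NT",
        }[self]


#: strict upper bounds per category, km² (IUCN v3.1 criterion B)
EOO_THRESHOLDS_KM2 = {Category.CR: 100.0, Category.EN: 5000.0, Category.VU: 20000.0}
AOO_THRESHOLDS_KM2 = {Category.CR: 10.0, Category.EN: 500.0, Category.VU: 2000.0}

CAVEAT = ("Preliminary rating from EOO/AOO thresholds alone, subject to "
          "meeting the full requirements of the criteria (criterion B "
          "subcriteria a-c).")


@dataclass
class PreliminaryRating:
    eoo_category: Category | None   # None when EOO is degenerate (<3 points)
    aoo_category: Category
    preliminary: Category
    caveat_note: str = CAVEAT

    @property
    def eoo_label(self) -> str:
        return "not applicable (<3 points)" if self.eoo_category is None \
            else self.eoo_category.label


def rate_metric(area_km2: float, metric: str) -> Category:
    """Category for one metric by strict-< threshold lookup."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    table = {"eoo": EOO_THRESHOLDS_KM2, "aoo": AOO_THRESHOLDS_KM2}[metric]
    for cat in (Category.CR, Category.EN, Category.VU):
        if area_km2 < table[cat]:
            return cat
    return Category.LC_OR_NT


def preliminary_rating(eoo_result, aoo_result, eoo_floor_aoo: bool = False) -> PreliminaryRating:
    """Combine B1 and B2 into the single preliminary category.

    A degenerate EOO (fewer than 3 non-collinear points, area 0) is not a
    meaningful extent, so the preliminary rating comes from AOO alone.
    With ``eoo_floor_aoo`` the IUCN convention that EOO may never be
    smaller than AOO is applied first: EOO is raised to the AOO value
    before rating (off by default).
    """
    eoo_area = eoo_result.area_km2
    aoo_category = rate_metric(aoo_result.area_km2, "aoo")

    if eoo_result.degenerate and not eoo_floor_aoo:
        return PreliminaryRating(eoo_category=None,
                                 aoo_category=aoo_category,
                                 preliminary=aoo_category)

    if eoo_floor_aoo and eoo_area < aoo_result.area_km2:
        eoo_area = aoo_result.area_km2
    eoo_category = rate_metric(eoo_area, "eoo")
    return PreliminaryRating(eoo_category=eoo_category,
                             aoo_category=aoo_category,
                             preliminary=max(eoo_category, aoo_category))
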