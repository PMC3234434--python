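"""Occurrence records and interactive editing/filtering operations.

An :class:`Occurrence` is a single georeferenced record of a taxon
(decimal-degree WGS84 coordinates plus free-form metadata).  An
:class:`OccurrenceSet` is the working collection an assessor edits before
analysis: points can be hidden, moved or deleted, and coarse data-quality
filters (bounding box, coordinate precision) toggle visibility.  Hidden
records are excluded from every analysis step but are never silently
dropped from files or exports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

logger = logging.getLogger("geocat")

VALID_SOURCES = ("user", "csv", "gbif", "flickr", "scratchpad")


class BboxMode(str, Enum):
    HIDE_INSIDE = "hide_inside"
    HIDE_OUTSIDE = "hide_outside"
    DELETE_INSIDE = "delete_inside"


class EditAction(str, Enum):
    MOVE = "move"
    DELETE = "delete"
    HIDE = "hide"
    SHOW = "show"


@dataclass
class Occurrence:
    """One georeferenced record.

    Parameters
    ----------
    id : str
        Opaque unique identifier within a set.
    lat, lon : float
        Decimal degrees WGS84.  May be NaN for records that failed
        georeferencing; such records are hidden by validation.
    source : str
        One of ``user, csv, gbif, flickr, scratchpad``.
    visible : bool
        Whether the record participates in analysis.
    edited : bool
        True iff the coordinates differ from the as-loaded values.
    coordinate_uncertainty_m : float, optional
        Reported georeference uncertainty in metres (non-negative).
    metadata : dict
        Free-form string map (collector, date, locality, raw-record link).
    """

    id: str
    lat: float
    lon: float
    source: str = "user"
    visible: bool = True
    edited: bool = False
    coordinate_uncertainty_m: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {VALID_SOURCES}")
        if self.coordinate_uncertainty_m is not None and self.coordinate_uncertainty_m < 0:
            raise ValueError("coordinate_uncertainty_m must be non-negative")

    def has_coords(self) -> bool:
        return (
            self.lat is not None
            and self.lon is not None
            and not math.isnan(self.lat)
            and not math.isnan(self.lon)
        )

    def coords_in_range(self) -> bool:
        return self.has_coords() and -90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0

    def copy(self) -> "Occurrence":
        return Occurrence(
            id=self.id,
            lat=self.lat,
            lon=self.lon,
            source=self.source,
            visible=self.visible,
            edited=self.edited,
            coordinate_uncertainty_m=self.coordinate_uncertainty_m,
            metadata=dict(self.metadata),
        )


@dataclass
class OccurrenceSet:
    """Ordered collection of occurrences for one taxon.

    ``provenance`` records where the data came from and which display caps
    were applied; ``audit`` is the ordered trail of edit operations applied
    through :func:`edit_point` and the filters.
    """

    taxon_name: str
    occurrences: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [o.id for o in self.occurrences]
        if len(ids) != len(set(ids)):
            raise ValueError("occurrence ids must be unique within a set")

    def __len__(self) -> int:
        return len(self.occurrences)

    def visible_occurrences(self) -> list:
        return [o for o in self.occurrences if o.visible]

    def n_visible(self) -> int:
        return len(self.visible_occurrences())

    def get(self, occ_id: str) -> Occurrence:
        for o in self.occurrences:
            if o.id == occ_id:
                return o
        raise KeyError(f"unknown id {occ_id!r}")

    def copy(self) -> "OccurrenceSet":
        return OccurrenceSet(
            taxon_name=self.taxon_name,
            occurrences=[o.copy() for o in self.occurrences],
            provenance=dict(self.provenance),
            audit=list(self.audit),
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_occurrences`.

    ``flags`` maps record id -> list of reason codes; the count fields
    summarise them.  ``n_duplicate_pairs`` counts unordered pairs of records
    sharing exactly the same (lat, lon).
    """

    n_out_of_range: int = 0
    n_missing: int = 0
    n_duplicate_pairs: int = 0
    n_suspected_swaps: int = 0
    flags: dict = field(default_factory=dict)

    def _flag(self, occ_id: str, reason: str) -> None:
        self.flags.setdefault(occ_id, []).append(reason)

    @property
    def clean(self) -> bool:
        return not self.flags


def validate_occurrences(occ_set: OccurrenceSet) -> ValidationReport:
    """Screen a set for obvious georeferencing mistakes.

    Checks for missing coordinates, out-of-range coordinates, exact
    coordinate duplicates, and suspected latitude/longitude swaps
    (|lat| > 90 is impossible on Earth; values up to 180 look like a
    longitude that landed in the latitude column).  Records with missing or
    out-of-range coordinates are hidden so they cannot poison the analysis;
    suspected swaps are flagged and hidden but never auto-corrected — the
    fix is a manual :func:`edit_point` move.
    """
    if not occ_set.occurrences:
        raise ValueError("no occurrences")

    report = ValidationReport()
    for occ in occ_set.occurrences:
        if not occ.has_coords():
            report.n_missing += 1
            report._flag(occ.id, "missing coordinates")
            occ.visible = False
        elif 90.0 < abs(occ.lat) <= 180.0 and -180.0 <= occ.lon <= 180.0:
            # looks like a swapped pair: plausible longitude in the lat column
            report.n_suspected_swaps += 1
            report._flag(occ.id, "possible lat/lon swap")
            occ.visible = False
        elif not occ.coords_in_range():
            report.n_out_of_range += 1
            report._flag(occ.id, "coordinates out of range")
            occ.visible = False

    # duplicate pairs: count over groups of identical coordinates
    groups: dict = {}
    for occ in occ_set.occurrences:
        if occ.has_coords():
            groups.setdefault((occ.lat, occ.lon), []).append(occ.id)
    for coords, ids in groups.items():
        k = len(ids)
        if k > 1:
            report.n_duplicate_pairs += k * (k - 1) // 2
            for dup_id in ids[1:]:
                report._flag(dup_id, "duplicate coordinates")
            # duplicates remain visible: they are real records
    return report


def filter_bbox(occ_set: OccurrenceSet, min_lat: float, min_lon: float,
                max_lat: float, max_lon: float, mode: BboxMode | str) -> OccurrenceSet:
    """Hide or delete records relative to a lat/lon bounding box.

    Containment is boundary-inclusive (>= min, <= max) so a point exactly on
    the edge counts as inside.  Modes: ``hide_inside``, ``hide_outside``,
    ``delete_inside``.  Returns the (mutated) set.
    """
    mode = BboxMode(mode)
    if min_lat > max_lat or min_lon > max_lon:
        raise ValueError("inverted bounding box: min must not exceed max")

    def inside(o: Occurrence) -> bool:
        return (o.has_coords()
                and min_lat <= o.lat <= max_lat
                and min_lon <= o.lon <= max_lon)

    if mode is BboxMode.DELETE_INSIDE:
        removed = [o.id for o in occ_set.occurrences if inside(o)]
        occ_set.occurrences = [o for o in occ_set.occurrences if not inside(o)]
        n = len(removed)
    else:
        n = 0
        for o in occ_set.occurrences:
            hit = inside(o) if mode is BboxMode.HIDE_INSIDE else not inside(o)
            if hit and o.visible:
                o.visible = False
                n += 1
    occ_set.audit.append(
        f"filter_bbox mode={mode.value} bbox=({min_lat},{min_lon},{max_lat},{max_lon}) affected={n}"
    )
    return occ_set


def filter_precision(occ_set: OccurrenceSet, max_uncertainty_m: float) -> OccurrenceSet:
    """Hide records whose coordinate uncertainty exceeds a threshold.

    Records without a stated uncertainty pass untouched: typical herbarium
    data lacks the field and hiding it all would be destructive.
    """
    if max_uncertainty_m <= 0:
        raise ValueError("max_uncertainty_m must be positive")
    n_hidden = 0
    n_missing = 0
    for o in occ_set.occurrences:
        if o.coordinate_uncertainty_m is None:
            n_missing += 1
        elif o.coordinate_uncertainty_m > max_uncertainty_m and o.visible:
            o.visible = False
            n_hidden += 1
    if n_missing == len(occ_set.occurrences):
        logger.warning("precision filter: no record carries coordinate_uncertainty_m; nothing hidden")
    occ_set.audit.append(f"filter_precision max_uncertainty_m={max_uncertainty_m} hidden={n_hidden}")
    return occ_set


def edit_point(occ_set: OccurrenceSet, occ_id: str, action: EditAction | str,
               new_coords: Optional[tuple] = None) -> OccurrenceSet:
    """Apply a single point edit: move, delete, hide or show.

    ``move`` is the only operation in the package that changes coordinates;
    it always sets ``edited=True``.  Every edit appends to the audit trail.
    """
    action = EditAction(action)
    occ = occ_set.get(occ_id)  # raises KeyError for unknown id

    if action is EditAction.MOVE:
        if new_coords is None:
            raise ValueError("move requires new_coords=(lat, lon)")
        lat, lon = float(new_coords[0]), float(new_coords[1])
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"move target out of range: ({lat}, {lon})")
        occ.lat, occ.lon = lat, lon
        occ.edited = True
        occ_set.audit.append(f"move {occ_id} -> ({lat},{lon})")
    elif action is EditAction.DELETE:
        occ_set.occurrences = [o for o in occ_set.occurrences if o.id != occ_id]
        occ_set.audit.append(f"delete {occ_id}")
    elif action is EditAction.HIDE:
        occ.visible = False
        occ_set.audit.append(f"hide {occ_id}")
    else:  # SHOW
        occ.visible = True
        occ_set.audit.append(f"show {occ_id}")
    return occ_set
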