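"""Readers and writers: occurrence CSV, ``.geocat`` project files, KML.

The ``.geocat`` file is a JSON document bundling everything a project
holds — occurrence records with their visibility/edit flags, the analysis
parameters, the results, and opaque application state — so a saved project
reloads bit-for-bit.  Unknown top-level keys survive a round trip, so
files written by newer versions stay loadable.

All writers are deterministic: identical input produces byte-identical
output (fixed key order; degrees rounded to 6 decimal places ≈ 0.1 m,
areas to 4).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree as ET

from .occurrences import Occurrence, OccurrenceSet
from .params import DEFAULT_CAPS, AnalysisParams
from .projection import ProjectionParams, inverse

logger = logging.getLogger("geocat")

FORMAT_VERSION = "1.0"

# recognised coordinate headers, lower-cased
_LAT_HEADERS = ("latitude", "decimallatitude")
_LON_HEADERS = ("longitude", "decimallongitude")
_UNC_HEADERS = ("coordinateuncertaintyinmeters", "uncertainty_m", "coordinate_uncertainty_m")
_RESERVED = set(_LAT_HEADERS) | set(_LON_HEADERS) | set(_UNC_HEADERS) | {
    "id", "source", "visible", "edited", "taxon"
}


@dataclass
class GeoCatProject:
    """In-memory twin of a ``.geocat`` file."""

    taxon_name: str
    occurrence_set: OccurrenceSet
    parameters: AnalysisParams = field(default_factory=AnalysisParams)
    projection: Optional[ProjectionParams] = None
    results: Optional[dict] = None
    app_state: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # unknown top-level keys, kept verbatim
    format_version: str = FORMAT_VERSION


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_float(text) -> float:
    if text is None:
        return math.nan
    text = str(text).strip()
    if not text:
        return math.nan
    return float(text)


def read_occurrence_csv(path, dialect: str = "generic",
                        caps: Optional[dict] = None,
                        taxon_name: Optional[str] = None) -> OccurrenceSet:
    """Load occurrences from a CSV file.

    Coordinates come from ``latitude``/``longitude`` columns or the Darwin
    Core ``decimalLatitude``/``decimalLongitude`` pair (case-insensitive);
    the GBIF occurrence-download dialect is tab- or comma-delimited,
    auto-detected from the header line.  Rows beyond a per-source display
    cap (default GBIF 500, Flickr 250, 0 = unlimited otherwise) are loaded
    with ``visible=False`` rather than dropped, and a warning is recorded
    in the set's provenance.  Rows whose coordinates fail to parse are
    skipped and counted.
    """
    if dialect not in ("generic", "gbif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'generic' or 'gbif'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    caps = dict(DEFAULT_CAPS if caps is None else caps)

    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError("empty CSV: no header row")
        fh.seek(0)
        delim = _detect_delimiter(first)
        reader = csv.DictReader(fh, delimiter=delim)
        headers = [h.strip() for h in (reader.fieldnames or [])]
        lower = {h.lower(): h for h in headers}

        lat_col = next((lower[h] for h in _LAT_HEADERS if h in lower), None)
        lon_col = next((lower[h] for h in _LON_HEADERS if h in lower), None)
        if lat_col is None or lon_col is None:
            raise ValueError(
                "no coordinate columns found; expected latitude/longitude or "
                "decimalLatitude/decimalLongitude headers"
            )
        unc_col = next((lower[h] for h in _UNC_HEADERS if h in lower), None)
        id_col = lower.get("id")
        source_col = lower.get("source")
        visible_col = lower.get("visible")
        edited_col = lower.get("edited")
        taxon_col = lower.get("taxon")
        meta_cols = [h for h in headers if h.lower() not in _RESERVED]

        occurrences = []
        n_skipped = 0
        per_source_count: dict = {}
        capped_sources = set()
        default_source = "gbif" if dialect == "gbif" else "csv"
        seen_taxon = None
        for i, row in enumerate(reader):
            try:
                lat = _parse_float(row.get(lat_col))
                lon = _parse_float(row.get(lon_col))
            except ValueError:
                n_skipped += 1
                continue
            source = (row.get(source_col) or default_source) if source_col else default_source
            if source not in ("user", "csv", "gbif", "flickr", "scratchpad"):
                source = default_source
            occ_id = (row.get(id_col) or "").strip() if id_col else ""
            if not occ_id:
                occ_id = f"{source}-{i + 1}"
            unc = None
            if unc_col:
                u = _parse_float(row.get(unc_col))
                unc = None if math.isnan(u) else u
            visible = True
            if visible_col and str(row.get(visible_col, "")).strip().lower() in ("false", "0", "no"):
                visible = False
            edited = bool(edited_col and str(row.get(edited_col, "")).strip().lower()
                          in ("true", "1", "yes"))
            if taxon_col and seen_taxon is None:
                seen_taxon = (row.get(taxon_col) or "").strip() or None

            per_source_count[source] = per_source_count.get(source, 0) + 1
            cap = caps.get(source, 0)
            if cap and per_source_count[source] > cap:
                visible = False
                capped_sources.add(source)

            metadata = {c: row[c] for c in meta_cols if row.get(c)}
            occurrences.append(Occurrence(
                id=occ_id, lat=lat, lon=lon, source=source, visible=visible,
                edited=edited, coordinate_uncertainty_m=unc, metadata=metadata,
            ))

    provenance = {"source_file": path.name, "dialect": dialect,
                  "n_rows_skipped": str(n_skipped)}
    for s in sorted(capped_sources):
        provenance[f"cap_applied_{s}"] = str(caps[s])
        logger.warning(
            "query returned more points than the display limit: source %s capped at %d "
            "(extra rows loaded but hidden)", s, caps[s])
    name = taxon_name or seen_taxon or path.stem
    return OccurrenceSet(taxon_name=name, occurrences=occurrences, provenance=provenance)


def write_occurrence_csv(occ_set: OccurrenceSet, path) -> None:
    """Write a set as CSV; coordinates at 6 decimal places.

    The header uses ``latitude``/``longitude`` so the file round-trips
    through :func:`read_occurrence_csv` unchanged.  Metadata keys are
    flattened into extra columns (union over records, sorted).
    """
    if not occ_set.occurrences:
        raise ValueError("cannot write an empty occurrence set")
    meta_keys = sorted({k for o in occ_set.occurrences for k in o.metadata})
    fieldnames = ["id", "taxon", "latitude", "longitude", "source", "visible",
                  "edited", "coordinate_uncertainty_m"] + meta_keys
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for o in occ_set.occurrences:
            row = {
                "id": o.id,
                "taxon": occ_set.taxon_name,
                "latitude": "" if math.isnan(o.lat) else f"{o.lat:.6f}",
                "longitude": "" if math.isnan(o.lon) else f"{o.lon:.6f}",
                "source": o.source,
                "visible": str(o.visible).lower(),
                "edited": str(o.edited).lower(),
                "coordinate_uncertainty_m":
                    "" if o.coordinate_uncertainty_m is None else f"{o.coordinate_uncertainty_m:g}",
            }
            row.update({k: o.metadata.get(k, "") for k in meta_keys})
            writer.writerow(row)


# ---------------------------------------------------------------------------
# .geocat JSON project files

_REQUIRED_KEYS = ("format_version", "taxon_name", "occurrences")


def _round6(v):
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else round(float(v), 6)


def _round4(v):
    return None if v is None else round(float(v), 4)


def _occ_to_json(o: Occurrence) -> dict:
    return {
        "id": o.id,
        "lat": _round6(o.lat),
        "lon": _round6(o.lon),
        "source": o.source,
        "visible": o.visible,
        "edited": o.edited,
        "uncertainty_m": o.coordinate_uncertainty_m,
        "metadata": dict(sorted(o.metadata.items())),
    }


def _occ_from_json(d: dict) -> Occurrence:
    return Occurrence(
        id=d["id"],
        lat=math.nan if d.get("lat") is None else float(d["lat"]),
        lon=math.nan if d.get("lon") is None else float(d["lon"]),
        source=d.get("source", "user"),
        visible=bool(d.get("visible", True)),
        edited=bool(d.get("edited", False)),
        coordinate_uncertainty_m=d.get("uncertainty_m"),
        metadata=dict(d.get("metadata", {})),
    )


def write_geocat(project: GeoCatProject, path) -> None:
    """Serialize a project to a ``.geocat`` JSON file (deterministic bytes)."""
    params = project.parameters.to_dict()
    if project.projection is not None:
        params["projection"] = {
            "lon0": _round6(project.projection.lon0),
            "lat_ts": _round6(project.projection.lat_ts),
            "R": project.projection.R,
        }
    doc = {
        "format_version": project.format_version,
        "taxon_name": project.taxon_name,
        "occurrences": [_occ_to_json(o) for o in project.occurrence_set.occurrences],
        "provenance": dict(sorted(project.occurrence_set.provenance.items())),
        "audit": list(project.occurrence_set.audit),
        "parameters": params,
        "results": project.results,
        "app_state": project.app_state,
    }
    for k in sorted(project.extra):
        doc[k] = project.extra[k]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def read_geocat(path) -> GeoCatProject:
    """Load a ``.geocat`` file; unknown top-level keys are preserved."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed .geocat JSON at line {e.lineno} column {e.colno}: {e.msg}") from e
    missing = [k for k in _REQUIRED_KEYS if k not in doc]
    if missing:
        raise ValueError(f"invalid .geocat file: missing required keys {missing}")

    occ_set = OccurrenceSet(
        taxon_name=doc["taxon_name"],
        occurrences=[_occ_from_json(d) for d in doc["occurrences"]],
        provenance=dict(doc.get("provenance", {})),
        audit=list(doc.get("audit", [])),
    )
    params_dict = dict(doc.get("parameters", {}))
    proj_dict = params_dict.pop("projection", None)
    projection = None
    if proj_dict:
        projection = ProjectionParams(lon0=proj_dict["lon0"], lat_ts=proj_dict["lat_ts"],
                                      R=proj_dict.get("R", ProjectionParams.__dataclass_fields__["R"].default))
    known = {"format_version", "taxon_name", "occurrences", "provenance", "audit",
             "parameters", "results", "app_state"}
    extra = {k: v for k, v in doc.items() if k not in known}
    return GeoCatProject(
        taxon_name=doc["taxon_name"],
        occurrence_set=occ_set,
        parameters=AnalysisParams.from_dict(params_dict),
        projection=projection,
        results=doc.get("results"),
        app_state=dict(doc.get("app_state", {})),
        extra=extra,
        format_version=doc["format_version"],
    )


# ---------------------------------------------------------------------------
# KML export

_KML_NS = "http://www.opengis.net/kml/2.2"


def _kml_style(doc, style_id: str, icon_color: str, poly_color: str | None = None):
    style = ET.SubElement(doc, "Style", id=style_id)
    icon = ET.SubElement(style, "IconStyle")
    ET.SubElement(icon, "color").text = icon_color
    if poly_color:
        poly = ET.SubElement(style, "PolyStyle")
        ET.SubElement(poly, "color").text = poly_color
        ET.SubElement(poly, "outline").text = "1"


def _kml_polygon(parent, name: str, ring_lonlat, style: str) -> None:
    pm = ET.SubElement(parent, "Placemark")
    ET.SubElement(pm, "name").text = name
    ET.SubElement(pm, "styleUrl").text = f"#{style}"
    poly = ET.SubElement(pm, "Polygon")
    bound = ET.SubElement(poly, "outerBoundaryIs")
    ring = ET.SubElement(bound, "LinearRing")
    coords = list(ring_lonlat)
    if coords[0] != coords[-1]:
        coords.append(coords[0])  # KML linear rings close explicitly
    ET.SubElement(ring, "coordinates").text = " ".join(
        f"{lon:.6f},{lat:.6f},0" for lon, lat in coords)


def export_kml(project: GeoCatProject, path) -> None:
    """Export a project to KML 2.2 for Google Earth.

    One Placemark per occurrence (name = record id, description from
    metadata); hidden points carry a distinct greyed style.  If results are
    present, the EOO hull and each AOO cell are written as Polygons.
    Coordinates follow the KML lon,lat order.
    """
    if not project.occurrence_set.occurrences:
        raise ValueError("project has no occurrences to export")
    kml = ET.Element("kml", {"xmlns": _KML_NS})
    doc = ET.SubElement(kml, "Document")
    ET.SubElement(doc, "name").text = project.taxon_name
    _kml_style(doc, "occ-visible", "ff0000ff")
    _kml_style(doc, "occ-hidden", "7f888888")
    _kml_style(doc, "eoo-hull", "ff00aa00", "4c00aa00")
    _kml_style(doc, "aoo-cell", "ffaa0000", "4caa0000")

    for o in project.occurrence_set.occurrences:
        if not o.has_coords():
            continue
        pm = ET.SubElement(doc, "Placemark")
        ET.SubElement(pm, "name").text = o.id
        if o.metadata:
            ET.SubElement(pm, "description").text = "; ".join(
                f"{k}: {v}" for k, v in sorted(o.metadata.items()))
        ET.SubElement(pm, "styleUrl").text = (
            "#occ-visible" if o.visible else "#occ-hidden")
        point = ET.SubElement(pm, "Point")
        ET.SubElement(point, "coordinates").text = f"{o.lon:.6f},{o.lat:.6f},0"

    results = project.results or {}
    if results.get("eoo") and results["eoo"].get("hull_lonlat") \
            and len(results["eoo"]["hull_lonlat"]) >= 3:
        ring = [(lon, lat) for lon, lat in results["eoo"]["hull_lonlat"]]
        _kml_polygon(doc, "EOO hull", ring, "eoo-hull")
    if results.get("aoo") and project.projection is not None:
        w = results["aoo"]["cell_width_km"]
        for cell in results["aoo"]["cells"]:
            i, j = cell["i"], cell["j"]
            corners_xy = [(i * w, j * w), ((i + 1) * w, j * w),
                          ((i + 1) * w, (j + 1) * w), (i * w, (j + 1) * w)]
            ring = []
            for x, y in corners_xy:
                lat, lon = inverse(x, y, project.projection)
                ring.append((float(lon), float(lat)))
            _kml_polygon(doc, f"AOO cell ({i},{j}) n={cell['count']}", ring, "aoo-cell")

    ET.indent(kml)
    tree = ET.ElementTree(kml)
    tree.write(path, encoding="unicode", xml_declaration=True)
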