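"""Analysis pipeline, report generation and multi-species batch mode.

``run_analysis`` is the one-click core: validate the occurrences, project
the visible points to the equal-area km frame, compute the convex-hull
extent of occurrence, resolve the grid cell width, compute the area of
occupancy, and rate both against the criterion-B thresholds.  Results and
the parameters that produced them are stored on the project so the
``.geocat`` file is self-describing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .aoo import AooResult, compute_aoo, resolve_cell_width
from .eoo import EooResult, compute_eoo
from .io import GeoCatProject, _round4, _round6, read_occurrence_csv
from .occurrences import OccurrenceSet, validate_occurrences
from .params import AnalysisParams
from .projection import ProjectedPointSet, inverse, project_points
from .rating import PreliminaryRating, preliminary_rating


@dataclass
class ReportSummary:
    """Flat summary of one analysed project; every number equals the
    corresponding stored result field exactly."""

    taxon: str
    n_total: int
    n_visible: int
    n_edited: int
    eoo_area_km2: float
    eoo_category: str
    aoo_cell_width_km: float
    aoo_n_cells: int
    aoo_area_km2: float
    aoo_category: str
    preliminary: str
    caveat: str
    parameters: dict


def _results_to_dict(eoo: EooResult, aoo: AooResult, rating: PreliminaryRating,
                     projected: ProjectedPointSet) -> dict:
    hull_lonlat = []
    for x, y in eoo.hull_vertices:
        lat, lon = inverse(x, y, projected.params)
        hull_lonlat.append([_round6(lon), _round6(lat)])
    cells = [{"i": i, "j": j, "count": c}
             for (i, j), c in sorted(aoo.cells.items())]
    return {
        "eoo": {
            "area_km2": _round4(eoo.area_km2),
            "hull_lonlat": hull_lonlat,
            "n_points_used": eoo.n_points_used,
            "degenerate": eoo.degenerate,
        },
        "aoo": {
            "cell_width_km": _round4(aoo.cell_width_km),
            "n_cells": aoo.n_cells,
            "area_km2": _round4(aoo.area_km2),
            "cells": cells,
        },
        "rating": {
            "eoo_category": rating.eoo_label,
            "aoo_category": rating.aoo_category.label,
            "preliminary": rating.preliminary.label,
            "caveat": rating.caveat_note,
        },
    }


def run_analysis(project: GeoCatProject, params: AnalysisParams | None = None) -> GeoCatProject:
    """Run the full EOO/AOO/rating pipeline on a project in place.

    Raises if no visible occurrence with valid coordinates remains after
    validation.  Deterministic: the same project and parameters always
    produce identical results.
    """
    if params is not None:
        project.parameters = params
    params = project.parameters

    validate_occurrences(project.occurrence_set)
    projected = project_points(project.occurrence_set)
    eoo = compute_eoo(projected)
    width = resolve_cell_width(params.cell_width_rule, projected.xy)
    aoo = compute_aoo(projected, width)
    rating = preliminary_rating(eoo, aoo, eoo_floor_aoo=params.eoo_floor_aoo)

    project.projection = projected.params
    project.results = _results_to_dict(eoo, aoo, rating, projected)
    return project


def summarize(project: GeoCatProject) -> ReportSummary:
    """Build the report summary from a project's stored results."""
    if not project.results:
        raise ValueError("project has no results; run the analysis first")
    occ = project.occurrence_set
    r = project.results
    return ReportSummary(
        taxon=project.taxon_name,
        n_total=len(occ),
        n_visible=occ.n_visible(),
        n_edited=sum(1 for o in occ.occurrences if o.edited),
        eoo_area_km2=r["eoo"]["area_km2"],
        eoo_category=r["rating"]["eoo_category"],
        aoo_cell_width_km=r["aoo"]["cell_width_km"],
        aoo_n_cells=r["aoo"]["n_cells"],
        aoo_area_km2=r["aoo"]["area_km2"],
        aoo_category=r["rating"]["aoo_category"],
        preliminary=r["rating"]["preliminary"],
        caveat=r["rating"]["caveat"],
        parameters=project.parameters.to_dict(),
    )


def render_report_text(summary: ReportSummary) -> str:
    p = summary.parameters
    lines = [
        f"Taxon: {summary.taxon}",
        f"Occurrences: {summary.n_total} total, {summary.n_visible} visible, "
        f"{summary.n_edited} edited",
        f"EOO: {summary.eoo_area_km2} km2 -> {summary.eoo_category}",
        f"AOO: {summary.aoo_area_km2} km2 ({summary.aoo_n_cells} cells at "
        f"{summary.aoo_cell_width_km} km width) -> {summary.aoo_category}",
        f"Preliminary rating: {summary.preliminary}",
        f"Note: {summary.caveat}",
        f"Parameters: cell_width_rule={p['cell_width_rule']}"
        + (f" user_width_km={p['user_width_km']}" if p.get("user_width_km") else "")
        + f" eoo_floor_aoo={p['eoo_floor_aoo']}",
    ]
    return "\n".join(lines) + "\n"


def generate_report(project: GeoCatProject, path) -> ReportSummary:
    """Write the analysis report (text + machine-readable JSON twin).

    ``path`` gets the plain-text report; ``path`` with a ``.json`` suffix
    gets the same numbers as JSON.  Raises if the project has no results.
    """
    summary = summarize(project)
    path = Path(path)
    path.write_text(render_report_text(summary), encoding="utf-8")
    twin = path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path
    if twin == path:
        twin = path.with_name(path.stem + "_report.json")
    twin.write_text(json.dumps(summary.__dict__, indent=2) + "\n", encoding="utf-8")
    return summary


def run_batch(path, params: AnalysisParams | None = None,
              taxon_column: str = "taxon", dialect: str = "generic") -> pd.DataFrame:
    """Analyse a multi-species occurrence CSV, one row of results per taxon.

    Rows are grouped by the taxon column and each group is analysed
    independently (each species gets its own data-centred projection).  A
    species whose records are all invalid yields a ``failed`` status row
    rather than aborting the batch.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if taxon_column.lower() not in cols:
        raise ValueError(f"missing taxon column {taxon_column!r} in {path}")
    taxon_col = cols[taxon_column.lower()]
    params = params or AnalysisParams()

    full = read_occurrence_csv(path, dialect=dialect, caps=params.caps)
    # occurrence ids are positional (row order), so group by the taxon value
    # of each parsed record's source row
    taxa_by_pos = [str(t) if not pd.isna(t) else "" for t in df[taxon_col].tolist()]
    occ_taxa = taxa_by_pos if len(taxa_by_pos) == len(full.occurrences) else None
    if occ_taxa is None:
        raise ValueError("could not align taxon column with parsed occurrences "
                         "(rows with unparseable coordinates present)")

    rows = []
    order = list(dict.fromkeys(occ_taxa))
    for taxon in order:
        subset = OccurrenceSet(
            taxon_name=taxon,
            occurrences=[o.copy() for o, t in zip(full.occurrences, occ_taxa) if t == taxon],
        )
        project = GeoCatProject(taxon_name=taxon, occurrence_set=subset, parameters=params)
        try:
            run_analysis(project)
            s = summarize(project)
            rows.append({
                "taxon": taxon, "status": "ok",
                "n_points": s.n_total, "n_visible": s.n_visible,
                "eoo_km2": s.eoo_area_km2, "eoo_category": s.eoo_category,
                "aoo_km2": s.aoo_area_km2, "aoo_cells": s.aoo_n_cells,
                "aoo_cell_width_km": s.aoo_cell_width_km,
                "aoo_category": s.aoo_category, "preliminary": s.preliminary,
            })
        except (ValueError, KeyError) as e:
            rows.append({
                "taxon": taxon, "status": "failed",
                "n_points": len(subset), "n_visible": subset.n_visible(),
                "eoo_km2": math.nan, "eoo_category": "",
                "aoo_km2": math.nan, "aoo_cells": 0,
                "aoo_cell_width_km": math.nan,
                "aoo_category": "", "preliminary": "",
                "error": str(e),
            })
    return pd.DataFrame(rows)
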