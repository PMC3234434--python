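import json

import pytest

from geocat import (AnalysisParams, CellWidthKind, CellWidthRule,
                    GeoCatProject, generate_report, run_analysis, run_batch,
                    summarize, write_geocat, write_occurrence_csv)
from geocat.analysis import render_report_text

from conftest import make_square_set


class TestRunAnalysis:
    def test_four_point_square_fixture(self, square_project):
        run_analysis(square_project)
        r = square_project.results
        assert r["eoo"]["area_km2"] == pytest.approx(16.0, abs=1e-3)
        assert r["aoo"]["cell_width_km"] == 2.0
        assert r["aoo"]["n_cells"] == 4
        assert r["aoo"]["area_km2"] == pytest.approx(16.0)
        assert r["rating"]["eoo_category"] == "CR"
        assert r["rating"]["aoo_category"] == "EN"
        assert r["rating"]["preliminary"] == "CR"

    def test_two_runs_produce_byte_identical_project_files(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            proj = GeoCatProject(taxon_name="t", occurrence_set=make_square_set())
            run_analysis(proj)
            path = tmp_path / f"{tag}.geocat"
            write_geocat(proj, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_all_points_hidden_is_an_error(self, square_project):
        for o in square_project.occurrence_set.occurrences:
            o.visible = False
        with pytest.raises(ValueError, match="no visible"):
            run_analysis(square_project)

    def test_user_cell_width_flows_through(self, square_project):
        params = AnalysisParams(
            cell_width_rule=CellWidthRule(kind=CellWidthKind.USER, user_width_km=10.0))
        run_analysis(square_project, params)
        assert square_project.results["aoo"]["cell_width_km"] == 10.0


class TestReport:
    def test_report_numbers_equal_results(self, square_project, tmp_path):
        run_analysis(square_project)
        summary = generate_report(square_project, tmp_path / "report.txt")
        r = square_project.results
        assert summary.eoo_area_km2 == r["eoo"]["area_km2"]
        assert summary.aoo_area_km2 == r["aoo"]["area_km2"]
        assert summary.preliminary == r["rating"]["preliminary"]
        text = (tmp_path / "report.txt").read_text()
        assert f"EOO: {summary.eoo_area_km2} km2" in text
        twin = json.loads((tmp_path / "report.txt.json").read_text())
        assert twin["eoo_area_km2"] == r["eoo"]["area_km2"]

    def test_parameters_echoed_verbatim(self, square_project, tmp_path):
        params = AnalysisParams(
            cell_width_rule=CellWidthRule(kind=CellWidthKind.USER, user_width_km=3.0))
        run_analysis(square_project, params)
        summary = summarize(square_project)
        assert summary.parameters == params.to_dict()
        assert "user_width_km=3.0" in render_report_text(summary)

    def test_report_without_results_raises(self, square_project, tmp_path):
        with pytest.raises(ValueError, match="no results"):
            generate_report(square_project, tmp_path / "r.txt")


class TestBatch:
    def make_batch_csv(self, tmp_path, bad_species=False):
        sets = {"Aus albus": make_square_set(base_lon=10.0),
                "Bus brevis": make_square_set(base_lon=60.0),
                "Cus celer": make_square_set(side_km=40.0, base_lon=120.0)}
        lines = ["taxon,id,latitude,longitude"]
        for taxon, s in sets.items():
            for o in s.occurrences:
                lines.append(f"{taxon},{taxon[:1]}-{o.id},{o.lat:.8f},{o.lon:.8f}")
        if bad_species:
            lines.append("Dus deficiens,d-1,,")
        path = tmp_path / "batch.csv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_three_species_give_three_rows(self, tmp_path):
        table = run_batch(self.make_batch_csv(tmp_path))
        assert len(table) == 3
        assert set(table["status"]) == {"ok"}

    def test_batch_row_matches_single_species_run(self, tmp_path):
        table = run_batch(self.make_batch_csv(tmp_path))
        single = GeoCatProject(taxon_name="Aus albus",
                               occurrence_set=make_square_set(base_lon=10.0))
        run_analysis(single)
        row = table[table["taxon"] == "Aus albus"].iloc[0]
        assert row["eoo_km2"] == single.results["eoo"]["area_km2"]
        assert row["aoo_km2"] == single.results["aoo"]["area_km2"]
        assert row["preliminary"] == single.results["rating"]["preliminary"]

    def test_species_without_valid_coords_yields_failed_row(self, tmp_path):
        table = run_batch(self.make_batch_csv(tmp_path, bad_species=True))
        assert len(table) == 4
        row = table[table["taxon"] == "Dus deficiens"].iloc[0]
        assert row["status"] == "failed"

    def test_missing_taxon_column_raises(self, tmp_path):
        path = tmp_path / "nt.csv"
        path.write_text("id,latitude,longitude\na,1,2\n")
        with pytest.raises(ValueError, match="taxon"):
            run_batch(path)

    def test_independent_projections_per_species(self, tmp_path):
        # species on opposite sides of the globe still both analyse cleanly
        table = run_batch(self.make_batch_csv(tmp_path))
        assert table["eoo_km2"].notna().all()


class TestEndToEndDeterminism:
    def test_csv_and_kml_outputs_byte_stable(self, tmp_path):
        from geocat import export_kml
        outs = []
        for tag in ("a", "b"):
            proj = GeoCatProject(taxon_name="t", occurrence_set=make_square_set())
            run_analysis(proj)
            csv_p = tmp_path / f"{tag}.csv"
            kml_p = tmp_path / f"{tag}.kml"
            write_occurrence_csv(proj.occurrence_set, csv_p)
            export_kml(proj, kml_p)
            outs.append((csv_p.read_bytes(), kml_p.read_bytes()))
        assert outs[0] == outs[1]
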