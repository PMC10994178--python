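"""Collated CSVs, deposition JSON + checksum, and report rendering."""

from __future__ import annotations

import json

import pandas as pd
import pytest

import epumine as em
from epumine.reporting import DepositionError


@pytest.fixture(scope="module")
def csv_paths(analysis, tmp_path_factory):
    prefix = tmp_path_factory.mktemp("csv") / "run1"
    return em.write_collated_csvs(analysis.session, analysis.entries,
                                  analysis.qualities, analysis.summary, prefix)


class TestCollatedCsvs:
    def test_four_files_with_expected_suffixes(self, csv_paths):
        names = [p.name for p in csv_paths]
        assert names == ["run1_datastructure.csv", "run1_optics.csv",
                         "run1_processed.csv", "run1_session.csv"]
        assert all(p.is_file() for p in csv_paths)

    def test_datastructure_row_count_equals_micrographs(self, csv_paths,
                                                        analysis):
        df = pd.read_csv(csv_paths[0])
        assert len(df) == len(analysis.session.records)
        assert df["micrograph_id"].is_unique
        # lineage columns populated for a complete tree
        for col in ("atlas_image", "grid_square_image", "foil_hole_image"):
            assert df[col].notna().all()

    def test_optics_one_row_per_preset(self, csv_paths, analysis):
        df = pd.read_csv(csv_paths[1])
        assert len(df) == len(analysis.session.presets)
        assert set(df["preset_name"]) == {"atlas", "gridsquare", "hole",
                                          "acquisition"}

    def test_session_csv_single_row_round_trips_key_values(self, csv_paths,
                                                           analysis):
        df = pd.read_csv(csv_paths[3])
        assert len(df) == 1
        row = df.iloc[0]
        assert row["n_micrographs"] == analysis.summary.n_micrographs
        assert row["instrument_id"] == analysis.session.config.instrument_id
        assert row["density_mean"] == pytest.approx(
            analysis.summary.reductions["density"][0], rel=1e-5)

    def test_without_preprocessing_processed_csv_skipped(self, analysis,
                                                         tmp_path):
        paths = em.write_collated_csvs(analysis.session, analysis.entries, {},
                                       analysis.summary, tmp_path / "bare",
                                       have_preprocessing=False)
        assert [p.name for p in paths] == ["bare_datastructure.csv",
                                           "bare_optics.csv",
                                           "bare_session.csv"]


@pytest.fixture(scope="module")
def deposition(analysis):
    return em.build_deposition(analysis.summary, analysis.session.config,
                               analysis.session.presets)


class TestDeposition:
    def test_fields_mirror_session_configuration(self, deposition,
                                                 small_scenario):
        assert deposition.microscope == small_scenario.instrument_id
        assert deposition.number_of_images == small_scenario.n_micrographs
        assert deposition.beam_diameter_micron == pytest.approx(1.1)
        assert deposition.hole_size_micron == pytest.approx(1.2)
        assert deposition.hole_space_micron == pytest.approx(1.3)
        assert deposition.shots_per_hole == 2
        assert deposition.Collection == "AFIS"

    def test_total_dose_is_frames_times_fraction(self, deposition,
                                                 small_scenario):
        assert deposition.total_dose_eA2 == pytest.approx(
            small_scenario.n_frames * small_scenario.fraction_dose)

    def test_defocus_ordered_by_magnitude_with_signs(self, deposition):
        assert deposition.nominal_defocus_min_microns == -1.0
        assert deposition.nominal_defocus_max_microns == -3.0

    def test_missing_mandatory_field_names_it(self, analysis):
        config = em.SessionConfig(**{**vars(analysis.session.config),
                                     "grid_type": None})
        with pytest.raises(DepositionError, match="grid_type"):
            em.build_deposition(analysis.summary, config,
                                analysis.session.presets)

    def test_allow_partial_substitutes_placeholders(self, analysis):
        config = em.SessionConfig(**{**vars(analysis.session.config),
                                     "grid_type": None})
        record = em.build_deposition(analysis.summary, config,
                                     analysis.session.presets,
                                     allow_partial=True)
        assert record.grid_type == ""


class TestDepositionJson:
    def test_write_then_verify_passes(self, deposition, tmp_path):
        json_path, checksum_path = em.write_deposition_json(
            deposition, tmp_path / "dep.json")
        assert checksum_path.name == "dep.json.sha256"
        result = em.verify_deposition_json(json_path)
        assert result.ok

    def test_json_is_canonical_and_deterministic(self, deposition, tmp_path):
        p1, c1 = em.write_deposition_json(deposition, tmp_path / "a.json")
        p2, c2 = em.write_deposition_json(deposition, tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()
        assert c1.read_text().split()[0] == c2.read_text().split()[0]
        payload = json.loads(p1.read_text())
        assert list(payload) == sorted(payload)

    def test_single_byte_flip_fails_verification(self, deposition, tmp_path):
        json_path, _ = em.write_deposition_json(deposition, tmp_path / "t.json")
        data = bytearray(json_path.read_bytes())
        data[len(data) // 2] ^= 0x01
        json_path.write_bytes(bytes(data))
        assert not em.verify_deposition_json(json_path).ok

    def test_json_field_names_follow_archive_spelling(self, deposition,
                                                      tmp_path):
        json_path, _ = em.write_deposition_json(deposition, tmp_path / "n.json")
        payload = json.loads(json_path.read_text())
        for key in ("eV", "Mag", "Apix", "C2_micron", "Objective_micron",
                    "beam_diameter_micron", "total_dose_eA2",
                    "average_foils_per_square", "number_of_images"):
            assert key in payload


def count_pdf_pages(path) -> int:
    return path.read_bytes().count(b"/Type /Page ") + \
        path.read_bytes().count(b"/Type/Page/")


@pytest.fixture(scope="module")
def bundle(analysis, tmp_path_factory):
    prefix = tmp_path_factory.mktemp("reports") / "run1"
    return em.render_reports(analysis.session, analysis.entries,
                             analysis.qualities, analysis.summary, prefix)


class TestReports:
    def test_both_documents_rendered(self, bundle):
        assert bundle.session_pdf.is_file()
        assert bundle.processed_pdf.is_file()
        assert bundle.session_pdf.read_bytes().startswith(b"%PDF")
        assert bundle.processed_pdf.read_bytes().startswith(b"%PDF")

    def test_session_content_names_instrument_and_magnification(self, bundle,
                                                                analysis):
        text = "\n".join(bundle.content["session"])
        assert analysis.session.config.instrument_id in text
        assert "81000" in text
        assert "Rate (micrographs/h)" in text

    def test_processed_report_has_six_metric_panels_and_overlay(self, bundle):
        panels = [c for c in bundle.content["processed"]
                  if not c.startswith("Particle picks")]
        assert len(panels) == 6
        assert any(c.startswith("Particle picks") for c in bundle.content["processed"])

    def test_empty_session_yields_session_report_only(self, tmp_path):
        sc = em.example_scenario(n_micrographs=0, n_squares_collected=1,
                                 foils_per_square=(1,))
        root = em.generate_session_tree(sc, tmp_path)
        a = em.analyze_session(root)
        bundle = em.render_reports(a.session, a.entries, a.qualities,
                                   a.summary, tmp_path / "empty")
        assert bundle.session_pdf.is_file()
        assert bundle.processed_pdf is None
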