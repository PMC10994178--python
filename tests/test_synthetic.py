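"""Generator contracts: layout, determinism, ground-truth honesty."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import epumine as em
from epumine.synthetic import GenerationError, generate_pick_coordinates

from conftest import brute_force_clustered


def tree_signature(root: Path) -> dict:
    """Relative path -> content bytes for every file under root."""
    return {str(p.relative_to(root)): p.read_bytes()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestSessionTree:
    def test_layout_matches_expected_structure(self, session_root, small_scenario):
        assert (session_root / "processing" / "gain" / "README").is_file()
        atlas_dms = list(session_root.glob(
            "atlas/Supervisor_*_Atlas/Sample1/Atlas/Atlas.dm"))
        assert len(atlas_dms) == 1
        assert list(session_root.glob(
            "atlas/Supervisor_*_Atlas/ScreeningSession.dm"))
        epu_dirs = list(session_root.glob("metadata/Supervisor_*_EPU"))
        assert len(epu_dirs) == 1
        assert (epu_dirs[0] / "EpuSession.dm").is_file()
        data_xml = list(epu_dirs[0].glob("Images-Disc1/GridSquare_*/Data/"
                                         "FoilHole_*_Data_*.xml"))
        assert len(data_xml) == small_scenario.n_micrographs
        # every acquisition XML has a paired raw placeholder
        for xml in data_xml:
            square = xml.parent.parent.name
            raw = session_root / "raw" / square / "Data" / f"{xml.stem}_fractions.mrc"
            assert raw.is_file() and raw.stat().st_size == 0

    def test_foil_hole_images_match_targeting_plan(self, session_root, small_scenario):
        holes = list(session_root.glob(
            "metadata/Supervisor_*_EPU/Images-Disc1/GridSquare_*/FoilHoles/"
            "FoilHoles_*.xml"))
        assert len(holes) == sum(small_scenario.foils_per_square)

    def test_fixed_seed_trees_are_byte_identical(self, small_scenario, tmp_path):
        sc = small_scenario.model_copy(update={"n_micrographs": 8,
                                               "foils_per_square": (2, 2, 2),
                                               "picks_per_micrograph": (10.0, 2.0)})
        r1 = em.generate_session_tree(sc, tmp_path / "a")
        em.generate_preprocessing_tree(sc, r1)
        r2 = em.generate_session_tree(sc, tmp_path / "b")
        em.generate_preprocessing_tree(sc, r2)
        assert tree_signature(r1) == tree_signature(r2)

    def test_empty_session_still_has_session_metadata(self, tmp_path):
        sc = em.example_scenario(n_micrographs=0, n_squares_collected=1,
                                 foils_per_square=(1,))
        root = em.generate_session_tree(sc, tmp_path)
        assert list(root.glob("metadata/Supervisor_*_EPU/EpuSession.dm"))
        assert not list(root.glob("metadata/**/Data/FoilHole_*.xml"))

    def test_scenario_invariants_name_offending_field(self):
        with pytest.raises(ValueError, match="n_squares_collected"):
            em.example_scenario(n_squares_available=2, n_squares_collected=3,
                                foils_per_square=(1, 1, 1))
        with pytest.raises(ValueError, match="foils_per_square"):
            em.example_scenario(n_squares_collected=2, foils_per_square=(5,))
        with pytest.raises(ValueError, match="n_micrographs"):
            em.example_scenario(n_micrographs=100, n_squares_collected=1,
                                foils_per_square=(10,), shots_per_hole=2)


class TestPreprocessingTree:
    def test_requires_session_tree_first(self, small_scenario, tmp_path):
        with pytest.raises(GenerationError, match="generate the session tree"):
            em.generate_preprocessing_tree(small_scenario, tmp_path / "nowhere")

    def test_motion_tables_encode_the_stated_dose_convention(self, analysis):
        # 10 frames of 1 e-/A^2; per-frame drift is the profile x a scale
        for entry in analysis.entries:
            trace = entry.motion
            assert trace is not None
            assert len(trace.per_frame_shift) == 10
            early, late, total = em.split_motion(trace)
            assert early == pytest.approx(0.4 * total)
            assert late == pytest.approx(0.6 * total)

    def test_zero_clustering_scenario_keeps_picks_apart(self, tmp_path):
        sc = em.example_scenario(seed=3, n_micrographs=4, n_squares_collected=1,
                                 foils_per_square=(2,),
                                 clustered_fraction_true=0.0,
                                 picks_per_micrograph=(60.0, 5.0))
        root = em.generate_session_tree(sc, tmp_path)
        em.generate_preprocessing_tree(sc, root)
        a = em.analyze_session(root)
        d_px = sc.particle_diameter_true / sc.acquisition_preset.pixel_size
        for entry in a.entries:
            centres = entry.picks.centres_px()
            flags = brute_force_clustered(centres, 0.8 * d_px)
            assert not flags.any()

    def test_zero_pick_scenario_writes_valid_empty_cbox(self, tmp_path):
        sc = em.example_scenario(seed=5, n_micrographs=2, n_squares_collected=1,
                                 foils_per_square=(1,),
                                 picks_per_micrograph=(0.0, 0.0))
        root = em.generate_session_tree(sc, tmp_path)
        proc = em.generate_preprocessing_tree(sc, root)
        cboxes = list(proc.glob("AutoPick/job*/CBOX/*.cbox"))
        assert len(cboxes) == 2
        picks = em.parse_preprocessing(proc).picks
        assert len(picks) == 2
        assert all(len(p) == 0 for p in picks)


class TestPickCoordinates:
    def test_clustered_count_matches_request(self):
        rng = np.random.default_rng(0)
        centres, mask = generate_pick_coordinates(rng, 100, 60.0, (5760, 4092),
                                                  clustered_fraction=0.3)
        assert len(centres) == 100
        assert mask.sum() == 30
        measured = brute_force_clustered(centres, 0.8 * 60.0)
        assert (measured == mask).all()

    def test_odd_clustered_count_resolved_with_triplet(self):
        rng = np.random.default_rng(1)
        centres, mask = generate_pick_coordinates(rng, 50, 60.0, (5760, 4092),
                                                  clustered_fraction=0.1)
        measured = brute_force_clustered(centres, 0.8 * 60.0)
        assert measured.sum() == mask.sum() == 5

    def test_single_pick_never_clustered(self):
        rng = np.random.default_rng(2)
        centres, mask = generate_pick_coordinates(rng, 1, 60.0, (5760, 4092),
                                                  clustered_fraction=1.0)
        assert len(centres) == 1 and not mask.any()


class TestFacilityTree:
    def test_layout_one_visit_per_scenario(self, tmp_path):
        scenarios = [
            em.example_scenario(seed=i, session_id=f"bi1000-{i}",
                                n_micrographs=2, n_squares_collected=1,
                                foils_per_square=(1,),
                                picks_per_micrograph=(5.0, 1.0))
            for i in range(3)
        ]
        root = em.generate_facility_tree(scenarios, tmp_path / "facility",
                                         with_preprocessing=False)
        visits = list(root.glob("TITAN52334150/2023/Data/*"))
        assert sorted(v.name for v in visits) == [f"bi1000-{i}" for i in range(3)]

    def test_two_instruments_two_top_level_dirs(self, tmp_path):
        scenarios = [
            em.example_scenario(seed=0, instrument_id="KRIOS1", session_id="v1",
                                n_micrographs=0, n_squares_collected=1,
                                foils_per_square=(1,)),
            em.example_scenario(seed=1, instrument_id="KRIOS2", session_id="v2",
                                n_micrographs=0, n_squares_collected=1,
                                foils_per_square=(1,)),
        ]
        root = em.generate_facility_tree(scenarios, tmp_path / "f",
                                         with_preprocessing=False)
        tops = sorted(p.name for p in root.iterdir() if p.is_dir())
        assert tops == ["KRIOS1", "KRIOS2"]

    def test_duplicate_visits_and_empty_list_rejected(self, tmp_path):
        sc = em.example_scenario(n_micrographs=0, n_squares_collected=1,
                                 foils_per_square=(1,))
        with pytest.raises(GenerationError, match="duplicate"):
            em.generate_facility_tree([sc, sc], tmp_path / "dup")
        with pytest.raises(GenerationError):
            em.generate_facility_tree([], tmp_path / "empty")
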