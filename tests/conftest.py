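"""Shared fixtures: one small synthetic session reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import epumine as em


@pytest.fixture(scope="session")
def small_scenario() -> em.Scenario:
    """A compact but fully featured session: 24 micrographs, 3 squares."""
    return em.example_scenario(
        seed=7,
        n_micrographs=24,
        n_squares_collected=3,
        foils_per_square=(5, 5, 4),
        picks_per_micrograph=(40.0, 5.0),
        n_frames=10,
        fraction_dose=1.0,
        motion_profile=tuple([1.0] * 10),
        acquisition_interval=30.0,
    )


@pytest.fixture(scope="session")
def session_root(small_scenario, tmp_path_factory):
    root = em.generate_session_tree(small_scenario,
                                    tmp_path_factory.mktemp("session"))
    em.generate_preprocessing_tree(small_scenario, root)
    return root


@pytest.fixture(scope="session")
def analysis(session_root) -> em.SessionAnalysis:
    return em.analyze_session(session_root)


def brute_force_clustered(centres: np.ndarray, threshold: float) -> np.ndarray:
    """O(n²) all-pairs nearest-neighbour oracle for clustering flags."""
    n = len(centres)
    if n < 2:
        return np.zeros(n, dtype=bool)
    d = cdist(centres, centres)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) < threshold
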