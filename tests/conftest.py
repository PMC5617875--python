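"""Shared fixtures: random similarity spaces and the desk-scale study run."""

from __future__ import annotations

import numpy as np
import pytest

from simseg import RunConfig, run_pipeline, simulate_coverage, standard_fixture


def random_similarity_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix satisfying axioms (s0)-(s2)."""
    A = rng.normal(size=(n, n))
    sim = (A + A.T) / 2
    np.fill_diagonal(sim, np.abs(sim).max() + rng.uniform(0.1, 1.0))
    return sim


@pytest.fixture(scope="session")
def desk_data():
    """Desk-scale oscillatory genome: tracks, truth intervals, genome."""
    genome = standard_fixture("desk", seed=1)
    tracks, truth = simulate_coverage(genome)
    return genome, tracks, truth


@pytest.fixture(scope="session")
def desk_run(desk_data):
    """Full pipeline on the desk fixture under the reference parameters
    (icor scoring, eps = 3, nu = 3, M = 100)."""
    genome, tracks, truth = desk_data
    cfg = RunConfig(
        params={"scoring": "icor", "E": 3.0, "nui": 3.0, "M": 100.0, "K": 10, "seed": 1}
    )
    result = run_pipeline(tracks, cfg, targets=truth)
    return cfg, result


@pytest.fixture(scope="session")
def tiny_data():
    genome = standard_fixture("tiny", seed=1)
    tracks, truth = simulate_coverage(genome)
    return genome, tracks, truth


TINY_PARAMS = {
    # pre-segmentation windows re-scaled to the 5-kb toy chromosome
    "avg": 200,
    "favg": 50,
    "minrd": 8,
    "minsg": 200,
    "min.gap.len": 200,
}
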