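"""Shared fixtures: simulated cohort collections and their fitted stages.

Session-scoped so that the (cheap but repeated) simulate -> DE -> meta chain
runs once per configuration for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from afmeta import (ExpressionStudy, SimulationConfig, combine_studies, run_de,
                    simulate_collection, simulate_ko_library)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """4 genes x 4 samples, 2 cases vs 2 controls, hand-set values."""
    values = np.array([
        [2.0, 2.0, 1.0, 1.0],   # clean +1 effect, zero residual variance
        [1.0, 3.0, 0.0, 2.0],   # +1 effect with spread
        [5.0, 5.0, 5.0, 5.0],   # flat
        [0.0, 1.0, 4.0, 5.0],   # down-regulated
    ])
    return ExpressionStudy(
        study_id="tiny",
        features=["g1", "g2", "g3", "g4"],
        samples=["s1", "s2", "s3", "s4"],
        values=values,
        groups=["case", "case", "control", "control"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """Five-cohort synthetic collection at the stated-world defaults, seed 1."""
    return simulate_collection(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def fitted_chain(default_sim):
    """(per-cohort DE results, meta results, selected signature) for seed 1."""
    studies, truth = default_sim
    des = [run_de(s) for s in studies]
    meta = combine_studies(des)
    signature = meta.select_signature()
    return des, meta, signature


@pytest.fixture(scope="session")
def planted_library(default_sim):
    """Synthetic KO library whose planted term overlaps the true up genes."""
    _, truth = default_sim
    return simulate_ko_library(truth, universe=list(truth.genes), seed=11)


@pytest.fixture(scope="session")
def null_sim():
    """Null collection (no differential genes) and its fitted chain, seed 3."""
    studies, truth = simulate_collection(SimulationConfig(frac_de=0.0, seed=3))
    des = [run_de(s) for s in studies]
    meta = combine_studies(des)
    return des, meta
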