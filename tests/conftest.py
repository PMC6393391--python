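"""Shared fixtures: synthetic phantoms and experiment runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import skelasso as sk

from phantom_utils import FoldExperiment  # tests dir is on sys.path


@pytest.fixture(scope="session")
def default_cfg() -> sk.SolverConfig:
    return sk.SolverConfig()


def make_y_tree() -> sk.NeuronTree:
    """Minimal Y: node 1 -> 2 (fork) -> {3, 4}."""
    ids = np.array([1, 2, 3, 4])
    parents = np.array([-1, 1, 2, 2])
    xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 1, 0], [2, -1, 0]], dtype=float)
    return sk.NeuronTree(ids, np.full(4, 3), xyz, np.ones(4), parents)


@pytest.fixture
def y_tree() -> sk.NeuronTree:
    return make_y_tree()


@pytest.fixture(scope="session")
def y_phantom():
    """Noiseless symmetric Y-junction phantom with its ground-truth tree."""
    spec = sk.BranchPhantomSpec()
    image, tree = sk.make_branch_phantom(spec)
    return spec, image, tree


@pytest.fixture(scope="session")
def fold30(default_cfg) -> FoldExperiment:
    """Sharp-corner phantom: 30 degrees, noise SD 50."""
    return FoldExperiment(30.0, 50.0, seed=1, cfg=default_cfg)


@pytest.fixture(scope="session")
def fold90(default_cfg) -> FoldExperiment:
    """Mild-corner phantom: 90 degrees, noise SD 100."""
    return FoldExperiment(90.0, 100.0, seed=1, cfg=default_cfg)
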