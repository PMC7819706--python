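"""Shared fixtures: small trees and cached synthetic study runs."""

import numpy as np
import pytest

from phylostrat.experiments import default_study, reduced_config
from phylostrat.pipeline import run_pipeline
from phylostrat.synthetic_data import simulate_dataset
from phylostrat.tree import TimeTree


@pytest.fixture(scope="session")
def four_leaf_tree():
    """((A,B),(C,D)) with crown ages 50/100 MY and root at 200 MY."""
    return TimeTree.from_newick("((A:50,B:50):150,(C:100,D:100):100);")


@pytest.fixture(scope="session")
def balanced_tree_64():
    """Fully balanced 64-leaf ultrametric tree, root at 640 MY."""
    return make_balanced_tree(depth=6, root_age=640.0)


def make_balanced_tree(depth: int, root_age: float) -> TimeTree:
    parent, age = [-1], [root_age]
    leaf_names = {}
    frontier = [(0, 0)]  # (node index, depth)
    counter = 0
    while frontier:
        idx, d = frontier.pop(0)
        if d == depth:
            continue
        for _ in range(2):
            child_age = root_age * (1 - (d + 1) / depth)
            parent.append(idx)
            age.append(child_age)
            child = len(parent) - 1
            if d + 1 == depth:
                leaf_names[f"L{counter:03d}"] = child
                counter += 1
            else:
                frontier.append((child, d + 1))
    return TimeTree(parent, age, leaf_names)


@pytest.fixture(scope="session")
def reduced_run():
    """One reduced-scale synthetic dataset plus its full pipeline result."""
    cfg = reduced_config(seed=7)
    ds = simulate_dataset(cfg)
    result = run_pipeline(ds, n_reps=200, seed=7)
    return cfg, ds, result


@pytest.fixture(scope="session")
def default_run():
    """The default-scale synthetic study (~60 species, ~800 pfams)."""
    ds, result = default_study(seed=0, n_reps=1000)
    return ds, result


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
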