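import numpy as np
import pytest

from venmorph.swc_io import NeuronTree, SwcNode
from venmorph.synthetic import PYR_PRESET, VEN_PRESET, generate_neuron


def make_tree(rows, provenance="fixture"):
    """Build a NeuronTree from (id, type, x, y, z, r, parent) tuples."""
    return NeuronTree(
        nodes=[SwcNode(*row) for row in rows], provenance=provenance
    )


@pytest.fixture
def straight_dendrite():
    """Soma + a 2-compartment dendrite with a right-angle kink:
    Euclid 5 µm vs path 7 µm → contraction 5/7."""
    return make_tree([
        (1, 1, 0, 0, 0, 5, -1),
        (2, 3, 3, 0, 0, 1, 1),
        (3, 3, 3, 4, 0, 1, 2),
    ])


@pytest.fixture
def bifurcating_tree():
    """Soma + stem that splits once into two single-compartment tips."""
    return make_tree([
        (1, 1, 0, 0, 0, 5, -1),
        (2, 3, 10, 0, 0, 2, 1),
        (3, 3, 20, 5, 0, 2, 2),
        (4, 3, 20, -5, 0, 2, 2),
    ])


@pytest.fixture
def clean_ven():
    return generate_neuron(VEN_PRESET, seed=7, cell_id="clean_ven")


@pytest.fixture
def clean_pyr():
    return generate_neuron(PYR_PRESET, seed=7, cell_id="clean_pyr")


def small_tree_family():
    """Enumerated family of hand-built trees (≤ 12 nodes) plus random small
    trees, used for oracle cross-checks."""
    trees = {
        # soma sphere + straight chain
        "chain": make_tree([
            (1, 1, 0, 0, 0, 4, -1),
            (2, 3, 5, 0, 0, 1.5, 1),
            (3, 3, 10, 1, 0, 1.2, 2),
            (4, 3, 15, 1, 2, 1.0, 3),
        ]),
        # symmetric bifurcation, daughters = parent diameter
        "symmetric_bif": make_tree([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 8, 0, 0, 2, 1),
            (3, 3, 14, 4, 0, 2, 2),
            (4, 3, 14, -4, 0, 2, 2),
        ]),
        # asymmetric subtree tip counts (2 vs 1)
        "asymmetric": make_tree([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 4, 0, 10, 0, 2.4, 1),
            (3, 4, -4, 18, 0, 1.8, 2),
            (4, 4, 4, 18, 1, 1.8, 2),
            (5, 4, 2, 26, 1, 1.2, 4),
            (6, 4, 8, 24, 1, 1.2, 4),
        ]),
        # multi-node soma chain with two stems
        "contour_soma": make_tree([
            (1, 1, -3, 0, 0, 2, -1),
            (2, 1, 0, 5, 1, 2, 1),
            (3, 1, 3, 0, -1, 2, 2),
            (4, 3, -8, -4, 0, 1.5, 1),
            (5, 3, -14, -8, 0, 1.2, 4),
            (6, 4, 8, 4, 0, 1.5, 3),
            (7, 4, 15, 9, 2, 1.0, 6),
        ]),
        # axon plus two dendritic stems
        "with_axon": make_tree([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 2, 0, -10, 0, 1.0, 1),
            (3, 2, 0, -22, -1, 0.8, 2),
            (4, 3, 6, 6, 0, 2, 1),
            (5, 3, 12, 12, 0, 1.6, 4),
            (6, 4, -6, 6, 0, 2, 1),
            (7, 4, -12, 14, 1, 1.6, 6),
            (8, 4, -18, 20, 1, 1.3, 7),
        ]),
    }
    # random small trees: soma + randomly attached neurite nodes
    for seed in range(8):
        rng = np.random.default_rng(seed)
        rows = [(1, 1, 0.0, 0.0, 0.0, 4.0, -1)]
        for nid in range(2, 2 + int(rng.integers(4, 11))):
            parent = int(rng.integers(1, nid))
            rows.append((
                nid, int(rng.choice([3, 4])),
                float(rng.normal(0, 20)), float(rng.normal(0, 20)),
                float(rng.normal(0, 3)), float(rng.uniform(0.5, 2.5)),
                parent,
            ))
        trees[f"random_{seed}"] = make_tree(rows)
    return trees
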