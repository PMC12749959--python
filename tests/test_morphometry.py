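import math

import numpy as np
import pandas as pd
import pytest

from venmorph.morphometry import (
    FEATURE_COLUMNS,
    compute_features,
    decompose_branches,
    feature_table,
    standardize,
)
from venmorph.swc_io import SwcNode
from venmorph.synthetic import GeneratorConfig, generate_cohort

from conftest import make_tree, small_tree_family
from _bruteforce import bf_features


class TestBranchDecomposition:
    def test_unbranched_dendrite_single_branch(self, straight_dendrite):
        branches = decompose_branches(straight_dendrite)
        assert len(branches) == 1
        (b,) = branches
        assert b.n_compartments == 2
        assert b.order == 1
        assert b.path_length == pytest.approx(7.0)
        assert b.euclidean_length == pytest.approx(5.0)

    def test_single_bifurcation_three_branches(self, bifurcating_tree):
        branches = decompose_branches(bifurcating_tree)
        assert len(branches) == 3
        assert sorted(b.order for b in branches) == [1, 2, 2]

    @pytest.mark.parametrize("name,tree", small_tree_family().items())
    def test_branches_partition_all_compartments(self, name, tree):
        branches = decompose_branches(tree)
        soma_ids = {n.id for n in tree.soma_nodes}
        n_nonsoma_comp = sum(
            1 for n in tree.nodes
            if n.id not in soma_ids and n.parent_id != -1
        )
        assert sum(b.n_compartments for b in branches) == n_nonsoma_comp

    def test_soma_required(self):
        tree = make_tree([(1, 3, 0, 0, 0, 1, -1), (2, 3, 5, 0, 0, 1, 1)])
        with pytest.raises(ValueError, match="soma"):
            decompose_branches(tree)


class TestFeatureDefinitions:
    def test_contraction_hand_value(self, straight_dendrite):
        f = compute_features(straight_dendrite)
        assert f["average_contraction"] == pytest.approx(5.0 / 7.0)

    def test_symmetric_bifurcation_ralls_and_asymmetry(self, bifurcating_tree):
        f = compute_features(bifurcating_tree)
        # both daughters carry the parent diameter → (1 + 1) · d^1.5/d^1.5
        assert f["average_ralls_ratio"] == pytest.approx(2.0)
        assert f["partition_asymmetry"] == 0.0

    def test_sphere_soma_surface(self):
        tree = make_tree([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 10, 0, 0, 1, 1),
        ])
        f = compute_features(tree)
        assert f["soma_surface"] == pytest.approx(100 * math.pi)

    def test_single_node_soma_ratio_is_one(self):
        tree = make_tree([(1, 1, 0, 0, 0, 5, -1), (2, 3, 9, 0, 0, 1, 1)])
        assert compute_features(tree)["height_to_width_ratio"] == 1.0

    def test_soma_only_tree_flags_branch_metrics(self):
        tree = make_tree([(1, 1, 0, 0, 0, 5, -1)])
        f = compute_features(tree)
        assert math.isnan(f["average_length"])
        assert f["total_volume"] == pytest.approx(4 / 3 * math.pi * 125)


class TestOracleEquivalence:
    """Every metric matches the independent brute-force implementation."""

    @pytest.mark.parametrize("name,tree", small_tree_family().items())
    def test_all_metrics_match_bruteforce(self, name, tree):
        ours = compute_features(tree)
        oracle = bf_features(tree)
        for key, expected in oracle.items():
            got = ours[key]
            if isinstance(expected, float) and math.isnan(expected):
                assert math.isnan(got), key
            else:
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                    f"{name}: {key} {got} != {expected}"
                )


class TestGeometricInvariance:
    _COUNT_KEYS = [
        "number_of_stems", "total_number_of_trees", "number_of_branches",
        "max_branch_order", "average_branch_order", "average_fragmentation",
        "max_fragmentation",
    ]
    _LENGTH_KEYS = ["average_length", "max_path_distance"]

    def test_translation_leaves_all_metrics_unchanged(self, clean_ven):
        from venmorph.swc_io import translated

        f0 = compute_features(clean_ven)
        f1 = compute_features(translated(clean_ven, 11.0, -7.0, 3.0))
        for key in FEATURE_COLUMNS:
            v0, v1 = f0[key], f1[key]
            assert v1 == pytest.approx(v0, rel=1e-9), key

    def test_rotation_about_z_preserves_intrinsic_metrics(self, clean_ven):
        theta = 0.7
        c, s = math.cos(theta), math.sin(theta)
        from dataclasses import replace

        rotated = clean_ven.with_nodes([
            replace(n, x=c * n.x - s * n.y, y=s * n.x + c * n.y)
            for n in clean_ven.nodes
        ])
        f0 = compute_features(clean_ven)
        f1 = compute_features(rotated)
        for key in self._COUNT_KEYS + self._LENGTH_KEYS + [
            "average_contraction", "partition_asymmetry",
            "average_ralls_ratio", "total_volume", "soma_surface",
            "average_diameter",
        ]:
            assert f1[key] == pytest.approx(f0[key], rel=1e-9), key

    def test_uniform_scaling_laws(self, clean_pyr):
        s = 2.5
        from dataclasses import replace

        scaled = clean_pyr.with_nodes([
            replace(n, x=s * n.x, y=s * n.y, z=s * n.z, radius=s * n.radius)
            for n in clean_pyr.nodes
        ])
        f0 = compute_features(clean_pyr)
        f1 = compute_features(scaled)
        for key in self._LENGTH_KEYS + [
            "overall_width", "overall_height", "overall_depth",
            "average_diameter",
        ]:
            assert f1[key] == pytest.approx(s * f0[key], rel=1e-9), key
        assert f1["soma_surface"] == pytest.approx(s**2 * f0["soma_surface"], rel=1e-9)
        assert f1["total_volume"] == pytest.approx(s**3 * f0["total_volume"], rel=1e-9)
        for key in self._COUNT_KEYS + [
            "average_contraction", "partition_asymmetry",
            "average_ralls_ratio", "height_to_width_ratio",
        ]:
            assert f1[key] == pytest.approx(f0[key], rel=1e-9), key


class TestFeatureTable:
    def test_shape_and_column_order(self, clean_ven, clean_pyr):
        table = feature_table(
            {"a": clean_ven, "b": clean_pyr}, {"a": "VEN", "b": "pyramidal"}
        )
        assert list(table.columns) == FEATURE_COLUMNS + ["label"]
        assert len(table) == 2
        assert list(table["label"]) == ["VEN", "pyramidal"]

    def test_duplicate_ids_rejected(self, clean_ven):
        with pytest.raises(ValueError, match="duplicate"):
            feature_table([("a", clean_ven), ("a", clean_ven)])

    def test_csv_roundtrip_lossless(self, tmp_path, clean_ven, clean_pyr):
        table = feature_table({"a": clean_ven, "b": clean_pyr})
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        for col in FEATURE_COLUMNS:
            np.testing.assert_allclose(
                back[col].to_numpy(), table[col].to_numpy(), rtol=1e-9
            )

    def test_class_contrast_in_soma_ratio(self):
        trees, labels = generate_cohort(
            GeneratorConfig(n_ven=30, n_pyr=30, seed=13)
        )
        table = feature_table(trees, labels)
        means = table.groupby("label")["height_to_width_ratio"].mean()
        assert means["VEN"] > means["pyramidal"]


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": ["a", "b", "c"]})
        out = standardize(df)
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        df = pd.DataFrame({"x": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(df)
        assert (out["x"] == 0.0).all()

    def test_moments_after_scaling(self, clean_ven, clean_pyr):
        table = feature_table({"a": clean_ven, "b": clean_pyr})
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = standardize(table)
        for col in ("average_length", "total_volume"):
            vals = out[col].astype(float)
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0)
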