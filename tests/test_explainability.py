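import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from graphvar.embedding_extraction import BlockRegistry
from graphvar.explainability import (
    FamilyShapSummary,
    ShapMatrix,
    compute_shap,
    family_shap_summary,
    margin_output,
    sum_shap_blocks,
)
from graphvar.pathogenicity_classifier import train_classifier


# --- independent Shapley oracle: cover-weighted conditional expectation over
# the booster's dumped trees, exhaustive enumeration over feature coalitions

def _tree_expectation(node, x, known):
    if "leaf" in node:
        return node["leaf"]
    f = int(node["split"][1:])
    kids = {c["nodeid"]: c for c in node["children"]}
    yes, no = kids[node["yes"]], kids[node["no"]]
    if f in known:
        child = yes if x[f] < node["split_condition"] else no
        return _tree_expectation(child, x, known)
    cy, cn = yes["cover"], no["cover"]
    return (cy * _tree_expectation(yes, x, known) + cn * _tree_expectation(no, x, known)) / (cy + cn)


def _brute_force_shap(booster, x, n_features):
    trees = [json.loads(t) for t in booster.get_dump(dump_format="json", with_stats=True)]
    phi = np.zeros(n_features)
    for i in range(n_features):
        others = [j for j in range(n_features) if j != i]
        for r in range(n_features):
            for s in itertools.combinations(others, r):
                w = math.factorial(len(s)) * math.factorial(n_features - len(s) - 1) / math.factorial(n_features)
                phi[i] += w * sum(
                    _tree_expectation(t, x, frozenset(s) | {i}) - _tree_expectation(t, x, frozenset(s))
                    for t in trees
                )
    return phi


@pytest.fixture(scope="module")
def depth2_model():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(300, 3))
    y = ((x[:, 0] > 0) & (x[:, 1] < 0.5)).astype(int)
    model = train_classifier(x, y, {"n_estimators": 1, "max_depth": 2, "learning_rate": 1.0}, seed=0)
    return model, x


class TestComputeShap:
    def test_matches_exhaustive_coalition_oracle(self, depth2_model):
        model, x = depth2_model
        shap = compute_shap(model, x[:10])
        booster = model.get_booster()
        for k in range(10):
            oracle = _brute_force_shap(booster, x[k], 3)
            np.testing.assert_allclose(shap.values[k], oracle, atol=1e-4)

    def test_additivity_to_margin(self, depth2_model):
        model, x = depth2_model
        shap = compute_shap(model, x[:50])
        margins = margin_output(model, x[:50])
        np.testing.assert_allclose(shap.base_value + shap.values.sum(axis=1), margins, atol=1e-5)

    def test_stump_attribution_equals_margin_minus_base(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 3))
        y = (x[:, 1] > 0).astype(int)
        model = train_classifier(x, y, {"n_estimators": 1, "max_depth": 1, "learning_rate": 1.0}, seed=0)
        shap = compute_shap(model, x[:20])
        margins = margin_output(model, x[:20])
        np.testing.assert_allclose(shap.values[:, 1], margins - shap.base_value, atol=1e-5)
        np.testing.assert_allclose(shap.values[:, [0, 2]], 0.0, atol=1e-6)

    def test_matches_xgboost_native_contributions(self, depth2_model):
        # independent cross-check: the booster's own float32 TreeSHAP
        model, x = depth2_model
        shap = compute_shap(model, x[:40])
        contribs = model.get_booster().predict(xgb.DMatrix(x[:40]), pred_contribs=True)
        np.testing.assert_allclose(shap.values, contribs[:, :-1], atol=1e-5)
        assert shap.base_value == pytest.approx(float(contribs[0, -1]), abs=1e-5)

    def test_additivity_is_double_precision(self, depth2_model):
        model, x = depth2_model
        shap = compute_shap(model, x[:40])
        margins = margin_output(model, x[:40])
        assert np.abs(shap.base_value + shap.values.sum(axis=1) - margins).max() < 1e-10

    def test_layout_mismatch_rejected(self, depth2_model):
        model, x = depth2_model
        with pytest.raises(ValueError):
            compute_shap(model, x[:5, :2])


class TestBlockSums:
    @pytest.fixture
    def shap6(self, rng):
        reg = BlockRegistry(blocks=[("a", 0, 2), ("b", 2, 3), ("c", 5, 1)])
        values = rng.normal(size=(7, 6))
        return ShapMatrix(values=values, base_value=0.3, registry=reg)

    def test_matches_slice_sum_oracle(self, shap6):
        sums = sum_shap_blocks(shap6)
        np.testing.assert_allclose(sums["a"], shap6.values[:, 0:2].sum(axis=1))
        np.testing.assert_allclose(sums["b"], shap6.values[:, 2:5].sum(axis=1))
        np.testing.assert_allclose(sums["c"], shap6.values[:, 5])

    def test_row_totals_preserved(self, shap6):
        sums = sum_shap_blocks(shap6)
        np.testing.assert_allclose(sums.sum(axis=1), shap6.values.sum(axis=1))

    def test_single_full_width_block(self, rng):
        reg = BlockRegistry(blocks=[("all", 0, 6)])
        values = rng.normal(size=(4, 6))
        sums = sum_shap_blocks(ShapMatrix(values, 0.0, reg))
        np.testing.assert_allclose(sums["all"], values.sum(axis=1))

    def test_zero_columns_give_zero_sum(self):
        reg = BlockRegistry(blocks=[("a", 0, 2), ("b", 2, 2)])
        values = np.zeros((3, 4))
        values[:, 0] = 1.0
        sums = sum_shap_blocks(ShapMatrix(values, 0.0, reg))
        assert (sums["b"] == 0.0).all()

    def test_invariant_to_permutation_within_block(self, shap6):
        before = sum_shap_blocks(shap6)
        shap6.values[:, [2, 3, 4]] = shap6.values[:, [4, 2, 3]]
        after = sum_shap_blocks(shap6)
        np.testing.assert_allclose(before["b"], after["b"])

    def test_uncovered_columns_rejected(self, rng):
        reg = BlockRegistry(blocks=[("a", 0, 2)])
        with pytest.raises(ValueError):
            sum_shap_blocks(ShapMatrix(rng.normal(size=(3, 6)), 0.0, reg))


class TestFamilySummary:
    def test_absolute_of_sum_rule(self):
        block_sums = pd.DataFrame({"wt_pooled": [1.0], "var_pooled": [-1.0]})
        variants = pd.DataFrame({"family_id": ["F0"]})
        s = family_shap_summary(block_sums, variants)
        assert s.family_means == {"F0": 2.0}

    def test_all_zero_sums(self):
        block_sums = pd.DataFrame({"wt_pooled": [0.0, 0.0], "wt_node": [0.0, 0.0]})
        variants = pd.DataFrame({"family_id": ["F0", "F1"]})
        s = family_shap_summary(block_sums, variants)
        assert (s.mean, s.std, s.median) == (0.0, 0.0, 0.0)

    def test_hand_computed_three_families(self):
        # spreadsheet-style oracle over 3 families x 2 variants
        block_sums = pd.DataFrame({
            "wt_pooled": [1.0, 2.0, -1.0, 3.0, 0.5, 0.5],
            "var_node": [0.0, -2.0, 1.0, 1.0, -0.5, 0.5],
        })
        variants = pd.DataFrame({"family_id": ["A", "A", "B", "B", "C", "C"]})
        # totals: 1, 4, 2, 4, 1, 1 -> family means A=2.5, B=3, C=1
        s = family_shap_summary(block_sums, variants)
        assert s.family_means == {"A": 2.5, "B": 3.0, "C": 1.0}
        means = np.array([2.5, 3.0, 1.0])
        assert s.mean == pytest.approx(means.mean())
        assert s.std == pytest.approx(means.std(ddof=0))
        assert s.median == pytest.approx(np.median(means))

    def test_invariant_to_variant_order(self, rng):
        block_sums = pd.DataFrame({"wt_pooled": rng.normal(size=10), "var_node": rng.normal(size=10)})
        variants = pd.DataFrame({"family_id": [f"F{i % 3}" for i in range(10)]})
        s1 = family_shap_summary(block_sums, variants)
        perm = rng.permutation(10)
        s2 = family_shap_summary(
            block_sums.iloc[perm].reset_index(drop=True),
            variants.iloc[perm].reset_index(drop=True),
        )
        assert s1.mean == pytest.approx(s2.mean)
        assert s1.family_means == pytest.approx(s2.family_means)

    def test_unmapped_variants_dropped(self):
        block_sums = pd.DataFrame({"wt_pooled": [1.0, 5.0]})
        variants = pd.DataFrame({"family_id": ["F0", None]})
        s = family_shap_summary(block_sums, variants)
        assert s.family_means == {"F0": 1.0}

    def test_no_mapped_variants_rejected(self):
        block_sums = pd.DataFrame({"wt_pooled": [1.0]})
        variants = pd.DataFrame({"family_id": [None]})
        with pytest.raises(ValueError):
            family_shap_summary(block_sums, variants)
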