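"""Exact path-dependent tree SHAP in double precision.

Computes Shapley attributions for a boosted-tree ensemble under the usual
path-dependent value function: a feature subset S fixes its features to the
query row's values, all other splits are marginalised by the training cover
fractions recorded at each branch.

The per-leaf factorisation makes this exact and polynomial: for one leaf,
the probability of reaching it is a product over the *distinct* features on
its path of either an indicator (feature known) or a product of cover ratios
(feature unknown). Features absent from the path are null players, so the
Shapley sum for a leaf ranges only over its own k <= depth features, and the
inner sum over subsets collapses to an elementary-symmetric-polynomial
recurrence in O(k^2).

Working in float64 from the dumped tree parameters keeps the additivity
identity (base value + row sums = margin) at ~1e-12, far below the rounding
of the booster's native float32 contribution output.
"""

from __future__ import annotations

import json
import math

import numpy as np

__all__ = ["TreeEnsemble"]

try:  # pragma: no cover - decoration only
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _margin_kernel(x, base, node_start, left, right, feat, thr, is_leaf, value):
    n = x.shape[0]
    out = np.full(n, base)
    n_trees = node_start.shape[0] - 1
    for s in range(n):
        for t in range(n_trees):
            node = node_start[t]
            while not is_leaf[node]:
                if x[s, feat[node]] < thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[s] += value[node]
    return out


@njit(cache=False)
def _shap_kernel(x, n_features, leaf_value, leaf_edge_start, leaf_edge_end,
                 leaf_slot_start, leaf_k, edge_slot, edge_feat, edge_thr,
                 edge_left, edge_ratio, slot_feat, fact):
    n = x.shape[0]
    phi = np.zeros((n, n_features))
    max_k = 0
    for li in range(leaf_k.shape[0]):
        if leaf_k[li] > max_k:
            max_k = leaf_k[li]
    a = np.empty(max_k)
    b = np.empty(max_k)
    dp = np.empty(max_k + 1)
    for s in range(n):
        for li in range(leaf_value.shape[0]):
            k = leaf_k[li]
            for j in range(k):
                a[j] = 1.0
                b[j] = 1.0
            for e in range(leaf_edge_start[li], leaf_edge_end[li]):
                sl = edge_slot[e]
                taken = x[s, edge_feat[e]] < edge_thr[e]
                if taken != edge_left[e]:
                    a[sl] = 0.0
                b[sl] *= edge_ratio[e]
            v = leaf_value[li]
            for i in range(k):
                diff = a[i] - b[i]
                if diff == 0.0:
                    continue
                # subset sum over the other known-path features via the
                # elementary-symmetric recurrence; unknown (a=0) features
                # can never be in S and contribute their b as a constant
                dp[0] = 1.0
                p = 0
                factor0 = 1.0
                for j in range(k):
                    if j == i:
                        continue
                    if a[j] == 1.0:
                        dp[p + 1] = dp[p]
                        for m in range(p, 0, -1):
                            dp[m] = dp[m - 1] + dp[m] * b[j]
                        dp[0] = dp[0] * b[j]
                        p += 1
                    else:
                        factor0 *= b[j]
                ssum = 0.0
                for m in range(p + 1):
                    ssum += dp[m] * fact[m] * fact[k - 1 - m] / fact[k]
                phi[s, slot_feat[leaf_slot_start[li] + i]] += v * diff * factor0 * ssum
    return phi


class TreeEnsemble:
    """Float64 view of a fitted xgboost booster for margins and SHAP."""

    def __init__(self, booster):
        self.n_features = booster.num_features()
        cfg = json.loads(booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        objective = cfg["learner"]["objective"]["name"]
        if objective.startswith(("binary:logistic", "reg:logistic")):
            self.base_margin = math.log(base_score / (1.0 - base_score))
        else:
            self.base_margin = base_score
        self._parse(booster.get_dump(dump_format="json", with_stats=True))

    # -- parsing ----------------------------------------------------------
    def _parse(self, dumps):
        left, right, feat, thr, is_leaf, value = [], [], [], [], [], []
        roots = []
        leaf_value, leaf_edge_start, leaf_edge_end = [], [], []
        leaf_slot_start, leaf_k = [], []
        edge_slot, edge_feat, edge_thr, edge_left, edge_ratio = [], [], [], [], []
        slot_feat = []
        expected = 0.0

        for dump in dumps:
            tree = json.loads(dump)
            roots.append(len(left))
            ids = {}

            def collect(node):
                ids[node["nodeid"]] = len(left)
                left.append(-1)
                right.append(-1)
                feat.append(0)
                thr.append(0.0)
                is_leaf.append("leaf" in node)
                value.append(node.get("leaf", 0.0))
                for child in node.get("children", []):
                    collect(child)

            collect(tree)

            def link(node):
                row = ids[node["nodeid"]]
                if "leaf" not in node:
                    feat[row] = int(node["split"][1:])
                    thr[row] = float(node["split_condition"])
                    left[row] = ids[node["yes"]]
                    right[row] = ids[node["no"]]
                    for child in node["children"]:
                        link(child)

            link(tree)

            # leaf paths: (feature, threshold, taken-if-yes, cover ratio)
            def walk(node, path):
                if "leaf" in node:
                    slots = {}
                    estart = len(edge_slot)
                    sstart = len(slot_feat)
                    prob = 1.0
                    for f, t, is_yes, ratio in path:
                        if f not in slots:
                            slots[f] = len(slots)
                            slot_feat.append(f)
                        edge_slot.append(slots[f])
                        edge_feat.append(f)
                        edge_thr.append(t)
                        edge_left.append(is_yes)
                        edge_ratio.append(ratio)
                        prob *= ratio
                    leaf_value.append(node["leaf"])
                    leaf_edge_start.append(estart)
                    leaf_edge_end.append(len(edge_slot))
                    leaf_slot_start.append(sstart)
                    leaf_k.append(len(slots))
                    nonlocal expected
                    expected += node["leaf"] * prob
                    return
                kids = {c["nodeid"]: c for c in node["children"]}
                f = int(node["split"][1:])
                t = float(node["split_condition"])
                for key, is_yes in ((node["yes"], True), (node["no"], False)):
                    child = kids[key]
                    ratio = child["cover"] / node["cover"]
                    walk(child, path + [(f, t, is_yes, ratio)])

            walk(tree, [])

        self._node_start = np.array(roots + [len(left)], dtype=np.int64)
        self._left = np.array(left, dtype=np.int64)
        self._right = np.array(right, dtype=np.int64)
        self._feat = np.array(feat, dtype=np.int64)
        self._thr = np.array(thr, dtype=np.float32).astype(np.float64)
        self._is_leaf = np.array(is_leaf, dtype=np.bool_)
        self._value = np.array(value, dtype=np.float64)

        self._leaf_value = np.array(leaf_value, dtype=np.float64)
        self._leaf_edge_start = np.array(leaf_edge_start, dtype=np.int64)
        self._leaf_edge_end = np.array(leaf_edge_end, dtype=np.int64)
        self._leaf_slot_start = np.array(leaf_slot_start, dtype=np.int64)
        self._leaf_k = np.array(leaf_k, dtype=np.int64)
        self._edge_slot = np.array(edge_slot, dtype=np.int64)
        self._edge_feat = np.array(edge_feat, dtype=np.int64)
        self._edge_thr = np.array(edge_thr, dtype=np.float32).astype(np.float64)
        self._edge_left = np.array(edge_left, dtype=np.bool_)
        self._edge_ratio = np.array(edge_ratio, dtype=np.float64)
        self._slot_feat = np.array(slot_feat, dtype=np.int64)
        max_k = int(self._leaf_k.max()) if len(self._leaf_k) else 1
        self._fact = np.array([math.factorial(m) for m in range(max_k + 1)], dtype=np.float64)
        self.expected_value = self.base_margin + expected

    # -- queries ----------------------------------------------------------
    @staticmethod
    def _as_query(x: np.ndarray) -> np.ndarray:
        # xgboost evaluates splits in float32; quantizing the query (and the
        # parsed thresholds) through float32 reproduces its branch decisions
        # exactly, including ties at representable boundaries
        return np.ascontiguousarray(
            np.asarray(x, dtype=np.float32), dtype=np.float64
        )

    def margins(self, x: np.ndarray) -> np.ndarray:
        x = self._as_query(x)
        return _margin_kernel(
            x, self.base_margin, self._node_start, self._left, self._right,
            self._feat, self._thr, self._is_leaf, self._value,
        )

    def shap_values(self, x: np.ndarray) -> np.ndarray:
        x = self._as_query(x)
        if len(self._leaf_value) == 0:
            return np.zeros((x.shape[0], self.n_features))
        return _shap_kernel(
            x, self.n_features, self._leaf_value, self._leaf_edge_start,
            self._leaf_edge_end, self._leaf_slot_start, self._leaf_k,
            self._edge_slot, self._edge_feat, self._edge_thr,
            self._edge_left, self._edge_ratio, self._slot_feat, self._fact,
        )
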