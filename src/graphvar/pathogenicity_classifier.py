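"""Gradient-boosted pathogenicity classifier with fold-wise tuning.

The protocol: for each of the five gene-exclusive folds, hyperparameters are
searched (seeded random search, default 100 trials) with the trial objective
being accuracy on that fold's evaluation set; the validation set drives
early-stopping rounds inside each fit. The five winning parameter sets are
then averaged (arithmetic mean for reals, geometric mean for log-scale
reals, rounded mean for integers, mode for categoricals) and a single
meta-optimised model is trained on all remaining (non-hold-out) variants
and evaluated once on the family hold-out. A fixed-threshold baseline on the
deleteriousness proxy score (pathogenic iff score >= 20) is the reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb

from ._ranking import auroc_rank

__all__ = [
    "ParamSpec",
    "HyperparameterSpace",
    "ClassifierMetrics",
    "default_space",
    "sample_params",
    "tune_hyperparameters",
    "average_hyperparameters",
    "train_classifier",
    "predict_proba",
    "compute_metrics",
    "threshold_baseline",
    "save_run_log",
]


@dataclass
class ParamSpec:
    name: str
    kind: str                      # real | log-real | integer | categorical
    low: float | None = None
    high: float | None = None
    choices: tuple = ()

    def __post_init__(self):
        if self.kind not in ("real", "log-real", "integer", "categorical"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical needs choices")
        elif self.low is None or self.high is None or self.low > self.high:
            raise ValueError(f"{self.name}: bounds must be ordered")


@dataclass
class HyperparameterSpace:
    params: list  # of ParamSpec

    def spec(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [p.name for p in self.params]


def default_space() -> HyperparameterSpace:
    """Standard ranges for the xgboost knobs that matter for tabular data."""
    return HyperparameterSpace(params=[
        ParamSpec("learning_rate", "log-real", 0.01, 0.3),
        ParamSpec("max_depth", "integer", 2, 10),
        ParamSpec("n_estimators", "integer", 50, 500),
        ParamSpec("subsample", "real", 0.5, 1.0),
        ParamSpec("colsample_bytree", "real", 0.5, 1.0),
        ParamSpec("min_child_weight", "integer", 1, 10),
        ParamSpec("reg_lambda", "log-real", 1e-3, 10.0),
        ParamSpec("gamma", "real", 0.0, 5.0),
    ])


def sample_params(space: HyperparameterSpace, rng: np.random.Generator) -> dict:
    out = {}
    for p in space.params:
        if p.kind == "real":
            out[p.name] = float(rng.uniform(p.low, p.high))
        elif p.kind == "log-real":
            out[p.name] = float(np.exp(rng.uniform(np.log(p.low), np.log(p.high))))
        elif p.kind == "integer":
            out[p.name] = int(rng.integers(int(p.low), int(p.high) + 1))
        else:
            out[p.name] = p.choices[rng.integers(len(p.choices))]
    return out


def _fit_xgb(params: dict, x_train, y_train, x_val=None, y_val=None, seed: int = 0,
             early_stopping_rounds: int | None = 10) -> xgb.XGBClassifier:
    kwargs = dict(params)
    model = xgb.XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        early_stopping_rounds=early_stopping_rounds if x_val is not None else None,
        **kwargs,
    )
    if x_val is not None:
        model.fit(x_train, y_train, eval_set=[(x_val, y_val)], verbose=False)
    else:
        model.fit(x_train, y_train, verbose=False)
    return model


def tune_hyperparameters(
    split,
    space: HyperparameterSpace | None = None,
    n_trials: int = 100,
    seed: int = 0,
    return_trials: bool = False,
):
    """Seeded random search maximising evaluation-set accuracy.

    ``split`` is ``((x_train, y_train), (x_val, y_val), (x_eval, y_eval))``;
    the validation part drives early stopping inside each trial's fit, the
    evaluation part scores the trial. Ties keep the earlier trial.
    """
    if space is None:
        space = default_space()
    (x_tr, y_tr), (x_va, y_va), (x_ev, y_ev) = split
    for part, y in (("train", y_tr), ("validation", y_va), ("evaluation", y_ev)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{part} labels contain a single class")
    rng = np.random.default_rng(seed)
    best_params, best_acc = None, -np.inf
    trials = []
    for t in range(n_trials):
        params = sample_params(space, rng)
        model = _fit_xgb(params, x_tr, y_tr, x_va, y_va, seed=seed)
        acc = float(np.mean(model.predict(x_ev) == np.asarray(y_ev)))
        trials.append({"trial": t, "params": params, "eval_accuracy": acc})
        if acc > best_acc:
            best_acc, best_params = acc, params
    if return_trials:
        return best_params, trials
    return best_params


def average_hyperparameters(param_sets, space: HyperparameterSpace) -> dict:
    """Fold-wise parameter averaging: mean / geometric mean / rounded mean / mode."""
    if not param_sets:
        raise ValueError("need at least one parameter set")
    for ps in param_sets:
        if set(ps) != set(space.names):
            raise ValueError("parameter sets do not match the space")
    out = {}
    for p in space.params:
        values = [ps[p.name] for ps in param_sets]
        if p.kind == "real":
            out[p.name] = float(np.mean(values))
        elif p.kind == "log-real":
            out[p.name] = float(np.exp(np.mean(np.log(values))))
        elif p.kind == "integer":
            m = float(np.mean(values))
            out[p.name] = int(math.copysign(math.floor(abs(m) + 0.5), m))
        else:
            counts = {}
            for v in values:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            out[p.name] = next(c for c in p.choices if counts.get(c, 0) == best)
    return out


def train_classifier(features, labels, params: dict, seed: int = 0) -> xgb.XGBClassifier:
    """Fit the gradient-boosted binary classifier; reproducible under seed."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    return _fit_xgb(params, features, labels, seed=seed, early_stopping_rounds=None)


def predict_proba(model, features) -> np.ndarray:
    """Probability of the pathogenic (positive) class.

    Accepts either the sklearn-style classifier or a bare Booster (as loaded
    from a saved model file).
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(features)[:, 1]
    return model.predict(xgb.DMatrix(np.asarray(features, dtype=float)))


@dataclass
class ClassifierMetrics:
    auroc: float
    mcc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    confusion: dict                     # tp/fp/fn/tn
    pr_curve: list = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pr_curve"] = [[float(r), float(p)] for r, p in self.pr_curve]
        return d


def _safe_div(a, b):
    return a / b if b else 0.0


def mcc_score(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 by convention when a factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> ClassifierMetrics:
    """Full metric suite at a probability threshold (default 0.5).

    AUROC uses the Mann-Whitney rank statistic; the PR curve is the list of
    (recall, precision) points over descending score thresholds.
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probabilities, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined with a single class")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))

    order = np.argsort(-probs, kind="stable")
    y = labels[order]
    tp_cum = np.cumsum(y)
    recall = tp_cum / labels.sum()
    precision = tp_cum / np.arange(1, len(y) + 1)
    pr_curve = list(zip(recall.tolist(), precision.tolist()))

    return ClassifierMetrics(
        auroc=auroc_rank(labels, probs),
        mcc=mcc_score(tp, fp, fn, tn),
        accuracy=(tp + tn) / labels.size,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        pr_curve=pr_curve,
    )


def threshold_baseline(scores, cutoff: float = 20.0) -> np.ndarray:
    """Binary filter on the deleteriousness score: pathogenic iff score >= cutoff."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def save_run_log(path, payload: dict) -> None:
    """Lightweight JSON run log (params, metrics, seeds) for one experiment."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
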