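"""SHAP-based attribution for the trained classifier.

Per-feature attributions are exact path-dependent tree SHAP values computed
in double precision from the fitted ensemble's trees (see ``_treeshap``),
additive on the margin scale: base value plus the row's SHAP values equals
the model's margin output. Because every embedding dimension is its own
model feature, attributions are summed over each feature block's index span
to obtain a single value per structural embedding, and the absolute block
totals are averaged per protein family to ask whether some families benefit
more from structural information than others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._treeshap import TreeEnsemble
from .embedding_extraction import BlockRegistry, STRUCTURAL_BLOCKS

__all__ = [
    "ShapMatrix",
    "FamilyShapSummary",
    "compute_shap",
    "sum_shap_blocks",
    "family_shap_summary",
    "shap_bar_plot",
    "family_boxplot",
]


@dataclass
class ShapMatrix:
    values: np.ndarray          # (n_variants, n_features)
    base_value: float
    registry: BlockRegistry | None = None


def _booster(model):
    return model.get_booster() if hasattr(model, "get_booster") else model


def compute_shap(model, features, registry: BlockRegistry | None = None) -> ShapMatrix:
    """Exact tree-path SHAP values for every row (margin scale, float64).

    Additivity ``base_value + sum(row) == margin(row)`` holds to numerical
    precision (~1e-12), since attributions and margins are both evaluated in
    double precision from the same tree parameters.
    """
    features = np.asarray(features, dtype=float)
    ensemble = TreeEnsemble(_booster(model))
    if features.ndim != 2 or features.shape[1] != ensemble.n_features:
        raise ValueError(
            f"feature matrix width {features.shape[1] if features.ndim == 2 else '?'} "
            f"does not match model ({ensemble.n_features})"
        )
    if registry is not None and registry.total_width != ensemble.n_features:
        raise ValueError("block registry does not cover the model's feature layout")
    return ShapMatrix(
        values=ensemble.shap_values(features),
        base_value=ensemble.expected_value,
        registry=registry,
    )


def margin_output(model, features) -> np.ndarray:
    """Raw (pre-sigmoid) model output in float64, the scale SHAP lives on."""
    return TreeEnsemble(_booster(model)).margins(np.asarray(features, dtype=float))


def sum_shap_blocks(shap: ShapMatrix, registry: BlockRegistry | None = None) -> pd.DataFrame:
    """Signed per-variant SHAP sum over each feature block's span.

    Row totals over blocks equal the row totals over features (additivity is
    preserved by block summation).
    """
    registry = registry or shap.registry
    if registry is None:
        raise ValueError("a block registry is required")
    if registry.total_width != shap.values.shape[1]:
        raise ValueError("registry spans do not cover all SHAP columns")
    out = {}
    for name in registry.names:
        out[name] = shap.values[:, registry.span(name)].sum(axis=1)
    return pd.DataFrame(out)


@dataclass
class FamilyShapSummary:
    family_means: dict          # family_id -> mean absolute structural SHAP total
    mean: float
    std: float                  # population standard deviation across families
    median: float

    def to_dict(self) -> dict:
        return {
            "family_means": {k: float(v) for k, v in self.family_means.items()},
            "mean": self.mean,
            "std": self.std,
            "median": self.median,
        }


def family_shap_summary(
    block_sums: pd.DataFrame,
    variants: pd.DataFrame,
    structural_blocks=STRUCTURAL_BLOCKS,
    absolute: str = "of_sum",
    shap: ShapMatrix | None = None,
) -> FamilyShapSummary:
    """Average absolute structural-SHAP totals per protein family.

    Per variant, total = sum over structural embedding blocks of the absolute
    block value; per family, the mean of these totals; then mean, population
    standard deviation and median across family means. Variants without a
    family mapping are dropped. ``absolute="of_sum"`` (default) takes the
    absolute value of each signed block sum; ``absolute="of_each"`` sums
    absolute per-feature SHAP values inside each block (requires ``shap``).
    """
    if absolute not in ("of_sum", "of_each"):
        raise ValueError("absolute must be 'of_sum' or 'of_each'")
    blocks = [b for b in structural_blocks if b in block_sums.columns]
    if not blocks:
        raise ValueError("no structural blocks present in the block sums")
    if absolute == "of_sum":
        totals = block_sums[blocks].abs().sum(axis=1).to_numpy()
    else:
        if shap is None or shap.registry is None:
            raise ValueError("absolute='of_each' requires the ShapMatrix with registry")
        totals = np.zeros(len(block_sums))
        for b in blocks:
            totals += np.abs(shap.values[:, shap.registry.span(b)]).sum(axis=1)

    families = variants["family_id"].reset_index(drop=True)
    mask = families.notna() & (families != "")
    if not mask.any():
        raise ValueError("no variants carry a family mapping")
    df = pd.DataFrame({"family": families[mask], "total": totals[mask.to_numpy()]})
    family_means = df.groupby("family")["total"].mean()
    return FamilyShapSummary(
        family_means=family_means.to_dict(),
        mean=float(family_means.mean()),
        std=float(family_means.std(ddof=0)),
        median=float(family_means.median()),
    )


def shap_bar_plot(block_sums: pd.DataFrame, path) -> None:
    """Bar plot of mean absolute SHAP per feature block."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = block_sums.abs().mean().sort_values()
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(means) + 1))
    ax.barh(means.index, means.values)
    ax.set_xlabel("mean |SHAP| (block sum)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def family_boxplot(summary: FamilyShapSummary, path) -> None:
    """Boxplot of the mean absolute structural SHAP totals across families."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    ax.boxplot(list(summary.family_means.values()), tick_labels=["families"])
    ax.set_ylabel("mean |structural SHAP| per family")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
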