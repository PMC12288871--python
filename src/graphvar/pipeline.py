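"""End-to-end orchestration: cohort -> graphs -> GAE -> features -> classifier.

This is the glue the CLI and the reproduction script drive. The stages are:

1. build residue-scoped graphs for every structure (wild type and variant);
2. train the graph autoencoder on all graphs (70/20/10 structure-level split);
3. embed every structure and assemble per-variant feature rows for one or
   more feature-set presets;
4. block a family hold-out (families overlapping a reference protein set),
   split the remainder into gene-exclusive folds;
5. per fold, tune the boosted-tree hyperparameters (objective: evaluation-
   fold accuracy), average the fold winners, train one meta-model on all
   non-hold-out variants, and score it once on the hold-out;
6. optionally compute SHAP attributions, block sums and the per-family
   summary on the hold-out.
"""

from __future__ import annotations

import numpy as np

from .cohort_splits import assign_gene_folds, build_family_holdout, fold_split
from .embedding_extraction import assemble_features, embed_structure
from .explainability import compute_shap, family_shap_summary, sum_shap_blocks
from .graph_autoencoder import EncoderConfig, TrainConfig, train_gae
from .pathogenicity_classifier import (
    average_hyperparameters,
    compute_metrics,
    default_space,
    mcc_score,
    threshold_baseline,
    train_classifier,
    tune_hyperparameters,
    predict_proba,
)
from ._ranking import auroc_rank
from .protein_graphs import GraphConfig, build_residue_graph
from .synthetic_data import Cohort

__all__ = [
    "build_cohort_graphs",
    "embed_cohort",
    "build_feature_matrix",
    "choose_reference_proteins",
    "run_experiment",
    "FULL_FEATURE_SET",
    "EMBEDDING_FEATURE_SET",
]

EMBEDDING_FEATURE_SET = ("wt_pooled", "var_pooled", "wt_node", "var_node", "cos_pooled", "cos_node")
FULL_FEATURE_SET = ("cadd",) + EMBEDDING_FEATURE_SET


def build_cohort_graphs(cohort: Cohort, config: GraphConfig | None = None) -> dict:
    """Residue-scoped graph per (protein_id, allele) structure key."""
    if config is None:
        config = GraphConfig(scope="residue")
    return {key: build_residue_graph(s, config) for key, s in cohort.structures.items()}


def embed_cohort(model, graphs: dict) -> dict:
    return {key: embed_structure(model, g) for key, g in graphs.items()}


def build_feature_matrix(cohort: Cohort, embeddings: dict, feature_set):
    """(n_variants x d) matrix in the cohort's row order, plus the registry."""
    rows = []
    registry = None
    for _, rec in cohort.variants.iterrows():
        wt = embeddings[(rec["protein_id"], "wt")]
        var = embeddings[(rec["protein_id"], f"var-{rec['variant_key']}")]
        row = assemble_features(
            wt, var, int(rec["position"]), feature_set,
            proxy_score=rec.get("proxy_score"),
        )
        rows.append(row.values)
        registry = row.blocks
    return np.vstack(rows), registry


def choose_reference_proteins(cohort: Cohort, fraction: float = 0.2, seed: int = 0) -> set:
    """Emulate an external reference set overlapping a fraction of the genes."""
    genes = sorted(cohort.variants["gene_id"].unique())
    rng = np.random.default_rng(seed)
    n_ref = max(1, int(round(fraction * len(genes))))
    ref_genes = set(rng.choice(genes, size=n_ref, replace=False))
    mask = cohort.variants["gene_id"].isin(ref_genes)
    return set(cohort.variants.loc[mask, "protein_id"])


def run_experiment(
    cohort: Cohort,
    feature_sets: dict | None = None,
    embedding_dim: int = 16,
    n_layers: int = 2,
    n_trials: int = 10,
    k_folds: int = 5,
    holdout_fraction: float = 0.2,
    gae_max_epochs: int = 20,
    shap_for: tuple = (),
    seed: int = 0,
) -> dict:
    """Run the full pipeline on a cohort; returns a nested results dict.

    ``feature_sets`` maps experiment names to block subsets (defaults to
    embeddings-only and embeddings+proxy). ``shap_for`` names experiments
    for which hold-out SHAP attributions and the family summary are added.
    """
    if feature_sets is None:
        feature_sets = {
            "embeddings": EMBEDDING_FEATURE_SET,
            "embeddings+cadd": FULL_FEATURE_SET,
        }

    graphs = build_cohort_graphs(cohort)
    enc_cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=embedding_dim, n_layers=n_layers)
    gae_model, history = train_gae(
        list(graphs.values()), enc_cfg,
        TrainConfig(seed=seed, max_epochs=gae_max_epochs),
    )
    embeddings = embed_cohort(gae_model, graphs)

    variants = cohort.variants
    y_all = (variants["label"] == "pathogenic").to_numpy(int)

    reference = choose_reference_proteins(cohort, fraction=holdout_fraction, seed=seed)
    holdout, remaining = build_family_holdout(variants, reference, cohort.family_map)
    assignment = assign_gene_folds(remaining["gene_id"].unique(), k_folds, seed=seed)

    results: dict = {
        "gae": {
            "test_auc": history.test_auc,
            "test_ap": history.test_ap,
            "best_epoch": history.best_epoch,
            "stopped_epoch": history.stopped_epoch,
        },
        "n_holdout": int(len(holdout)),
        "n_remaining": int(len(remaining)),
        "experiments": {},
    }

    # proxy-score reference: AUROC of the raw score and the fixed >=20 filter
    y_hold = y_all[holdout.index.to_numpy()]
    proxy_hold = holdout["proxy_score"].to_numpy(float)
    baseline_pred = threshold_baseline(proxy_hold)
    tp = int(np.sum((baseline_pred == 1) & (y_hold == 1)))
    fp = int(np.sum((baseline_pred == 1) & (y_hold == 0)))
    fn = int(np.sum((baseline_pred == 0) & (y_hold == 1)))
    tn = int(np.sum((baseline_pred == 0) & (y_hold == 0)))
    results["proxy_baseline"] = {
        "auroc": auroc_rank(y_hold, proxy_hold),
        "threshold_accuracy": (tp + tn) / max(1, len(y_hold)),
        "threshold_mcc": mcc_score(tp, fp, fn, tn),
    }

    space = default_space()
    for name, feature_set in feature_sets.items():
        x_all, registry = build_feature_matrix(cohort, embeddings, feature_set)
        fold_params = []
        for eval_fold in range(1, k_folds + 1):
            train_df, val_df, eval_df = fold_split(remaining, assignment, eval_fold)
            parts = []
            ok = True
            for df in (train_df, val_df, eval_df):
                ix = df.index.to_numpy()
                if len(ix) == 0 or len(np.unique(y_all[ix])) < 2:
                    ok = False
                    break
                parts.append((x_all[ix], y_all[ix]))
            if not ok:
                continue  # degenerate fold (single-class); skip its vote
            fold_params.append(
                tune_hyperparameters(tuple(parts), space, n_trials=n_trials, seed=seed + eval_fold)
            )
        if not fold_params:
            raise RuntimeError("all folds were degenerate; cannot tune")
        avg_params = average_hyperparameters(fold_params, space)

        rem_ix = remaining.index.to_numpy()
        hold_ix = holdout.index.to_numpy()
        model = train_classifier(x_all[rem_ix], y_all[rem_ix], avg_params, seed=seed)
        probs = predict_proba(model, x_all[hold_ix])
        metrics = compute_metrics(y_all[hold_ix], probs)
        entry = {
            "params": avg_params,
            "metrics": metrics,
            "model": model,
            "registry": registry,
        }
        if name in shap_for:
            shap = compute_shap(model, x_all[hold_ix], registry)
            block_sums = sum_shap_blocks(shap)
            entry["shap"] = shap
            entry["block_sums"] = block_sums
            entry["holdout_features"] = x_all[hold_ix]
            try:
                entry["family_summary"] = family_shap_summary(
                    block_sums, holdout.reset_index(drop=True)
                )
            except ValueError:
                entry["family_summary"] = None
        results["experiments"][name] = entry
    return results
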