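"""Leakage-aware cohort splitting.

Two guards against similarity-driven leakage between training and final
evaluation:

* a family-based hold-out — every variant whose protein belongs to the same
  protein family as any protein shared with an external reference set is
  moved to the hold-out table and never touched before final evaluation;
* gene-exclusive five-fold cross-validation — folds are balanced by gene
  count and a gene's variants never span two folds, so per-fold training,
  validation and evaluation sets are gene-disjoint.

Variant tables are pandas DataFrames with (at least) columns
``protein_id, gene_id, family_id, position, wt_aa, alt_aa, label``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "FoldAssignment",
    "build_family_holdout",
    "assign_gene_folds",
    "fold_split",
]


@dataclass
class VariantRecord:
    """One missense substitution; the classifier's row key."""

    protein_id: str
    gene_id: str
    position: int
    wt_aa: str
    alt_aa: str
    label: str                       # "benign" | "pathogenic"
    family_id: str | None = None
    proxy_score: float | None = None

    def __post_init__(self):
        if self.wt_aa == self.alt_aa:
            raise ValueError("wt_aa and alt_aa must differ")
        if self.label not in ("benign", "pathogenic"):
            raise ValueError(f"label must be benign/pathogenic, got {self.label!r}")


@dataclass
class FoldAssignment:
    mapping: dict          # gene_id -> fold in 1..k
    k: int

    def genes_in(self, fold: int) -> set:
        return {g for g, f in self.mapping.items() if f == fold}


def build_family_holdout(
    variants: pd.DataFrame,
    reference_proteins,
    family_map: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split variants into (hold-out, remaining) by blocked protein families.

    A family is blocked when any of its proteins occurs both in the cohort
    and in the external reference set; all variants of blocked-family
    proteins go to the hold-out. The two tables partition the input.
    """
    reference_proteins = set(reference_proteins)
    overlap = set(variants["protein_id"]) & reference_proteins
    blocked_families = {family_map[p] for p in overlap if p in family_map}
    fam = variants["protein_id"].map(family_map)
    in_holdout = fam.isin(blocked_families) | variants["protein_id"].isin(overlap)
    holdout = variants[in_holdout].copy()
    remaining = variants[~in_holdout].copy()
    return holdout, remaining


def assign_gene_folds(genes, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle then round-robin; fold gene counts differ by at most 1."""
    genes = sorted(set(genes))
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    mapping = {genes[g]: (i % k) + 1 for i, g in enumerate(order)}
    return FoldAssignment(mapping=mapping, k=k)


def fold_split(
    variants: pd.DataFrame,
    assignment: FoldAssignment,
    eval_fold: int,
    val_fold: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(train, validation, evaluation) tables for one fold rotation.

    Evaluation takes ``eval_fold``'s genes, validation takes ``val_fold``
    (default: the next fold cyclically), training the remaining k-2 folds.
    """
    if val_fold is None:
        val_fold = (eval_fold % assignment.k) + 1
    if not (1 <= eval_fold <= assignment.k and 1 <= val_fold <= assignment.k):
        raise ValueError("fold indices out of range")
    if eval_fold == val_fold:
        raise ValueError("evaluation and validation folds must differ")
    fold_of = variants["gene_id"].map(assignment.mapping)
    eval_df = variants[fold_of == eval_fold].copy()
    val_df = variants[fold_of == val_fold].copy()
    train_df = variants[~fold_of.isin([eval_fold, val_fold])].copy()
    return train_df, val_df, eval_df
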