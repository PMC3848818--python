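"""Assessment procedures: cross-validation reproducibility of the gene
rankings, Welch/Benjamini-Hochberg differential expression for the
DC-vs-DE comparison, and correlation-tree clustering of gene lists.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr, ttest_ind
from statsmodels.stats.multitest import multipletests

from .corrnet import ConditionPair, ExpressionMatrix, FisherZMatrix, ThresholdGrid
from .fdr import _SEED_MOD, score_vector

__all__ = [
    "ReproducibilityResult",
    "top_overlap",
    "crossval_reproducibility",
    "welch_bh_de",
    "cluster_genes",
    "standardize_rows",
]


def _top_genes(scores: pd.Series, frac: float, method: str) -> set:
    """Gene ids in the top ``frac`` of a score vector (strongest DC first)."""
    if not (0 < frac <= 1):
        raise ValueError("top fraction must lie in (0, 1]")
    k = max(1, int(round(frac * len(scores))))
    ascending = method == "dcglob"  # small p = strong; large d = strong
    ranked = scores.sort_values(ascending=ascending, kind="mergesort")
    return set(ranked.index[:k])


def top_overlap(
    train_scores: pd.Series,
    valid_scores: pd.Series,
    top_frac_train: float,
    top_frac_valid: float,
    method: str = "dcloc",
) -> float:
    """Percentage of training top-list genes found in the validation top list."""
    top_train = _top_genes(train_scores, top_frac_train, method)
    top_valid = _top_genes(valid_scores.reindex(train_scores.index), top_frac_valid, method)
    return 100.0 * len(top_train & top_valid) / len(top_train)


@dataclass(eq=False)
class ReproducibilityResult:
    """Outcome of one two-fold cross-validation draw."""

    method: str
    n_per_group: int
    top_frac_train: float
    top_frac_valid: float
    overlap_percent: float
    rank_correlation: float
    train_scores: pd.Series
    valid_scores: pd.Series


def crossval_reproducibility(
    pooled_a: ExpressionMatrix,
    pooled_b: ExpressionMatrix,
    n_per_group: int,
    method: str = "dcloc",
    top_frac_train: float = 0.05,
    top_frac_valid: float = 0.05,
    seed: int = 0,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> ReproducibilityResult:
    """Two-fold cross-validation of a DC gene ranking.

    Disjoint training and validation groups of ``n_per_group`` samples
    are drawn without replacement from each pooled condition; both
    splits are scored with the chosen algorithm. A training top-list
    gene counts as validated if it reappears in the validation top list.
    Also reports the Spearman rank correlation of the two score vectors.
    """
    if pooled_a.gene_ids != pooled_b.gene_ids:
        raise ValueError("pooled conditions must share the same gene set")
    for pooled in (pooled_a, pooled_b):
        if 2 * n_per_group > pooled.n_samples:
            raise ValueError(
                f"cannot draw disjoint train/validation groups of {n_per_group} "
                f"from {pooled.n_samples} samples"
            )
    rng = np.random.default_rng(seed % _SEED_MOD)
    perm_a = rng.permutation(pooled_a.n_samples)
    perm_b = rng.permutation(pooled_b.n_samples)
    train = ConditionPair(
        pooled_a.subset_samples(perm_a[:n_per_group]),
        pooled_b.subset_samples(perm_b[:n_per_group]),
    )
    valid = ConditionPair(
        pooled_a.subset_samples(perm_a[n_per_group : 2 * n_per_group]),
        pooled_b.subset_samples(perm_b[n_per_group : 2 * n_per_group]),
    )
    train_scores = score_vector(train, method, grid, absolute=absolute)
    valid_scores = score_vector(valid, method, grid, absolute=absolute)
    overlap = top_overlap(train_scores, valid_scores, top_frac_train, top_frac_valid, method)
    rho = spearmanr(train_scores.to_numpy(), valid_scores.to_numpy()).statistic
    return ReproducibilityResult(
        method=method,
        n_per_group=n_per_group,
        top_frac_train=top_frac_train,
        top_frac_valid=top_frac_valid,
        overlap_percent=overlap,
        rank_correlation=float(rho),
        train_scores=train_scores,
        valid_scores=valid_scores,
    )


def welch_bh_de(pair: ConditionPair, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test with Benjamini-Hochberg correction.

    Returns columns ``gene_id, t, p, p_adj, significant`` in the input
    gene order. Genes constant in both groups have no defined test and
    are reported with ``p = 1`` (with a warning).
    """
    if pair.n_a < 2 or pair.n_b < 2:
        raise ValueError("Welch's test needs at least 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are
        # detected and reported explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = ttest_ind(pair.a.values, pair.b.values, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) constant in both groups; p set to 1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": pair.gene_ids,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )


def cluster_genes(zmat: FisherZMatrix, corr_cutoff: float = 0.4) -> pd.Series:
    """Average-linkage clustering with 1 - Pearson correlation as distance.

    The correlation tree is cut at height ``1 - corr_cutoff``, i.e.
    clusters are merged while their average Pearson correlation exceeds
    ``corr_cutoff``. Cluster ids are assigned by decreasing cluster size
    (ties by first gene position). Returns a Series gene id -> cluster.
    """
    if zmat.n_genes < 2:
        raise ValueError("clustering needs at least 2 genes")
    c = np.tanh(zmat.z)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(tree, t=1.0 - corr_cutoff, criterion="distance")
    order = sorted(
        set(raw),
        key=lambda lab: (-(raw == lab).sum(), int(np.flatnonzero(raw == lab)[0])),
    )
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([relabel[lab] for lab in raw], index=list(zmat.gene_ids), name="cluster")


def standardize_rows(em: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to standard deviation 1.

    The convention for exported heatmap matrices; constant rows are
    rejected (their scale is undefined).
    """
    sd = em.values.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("cannot standardize constant expression rows")
    values = (em.values - em.values.mean(axis=1, keepdims=True)) / sd
    return ExpressionMatrix(em.gene_ids, em.sample_ids, values)
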