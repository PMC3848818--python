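"""Local-topology differential correlation (DCloc).

At each grid threshold a gene's neighborhoods in the two condition
networks are compared by a Jaccard-type dissimilarity
``d = 1 - |V_A n V_B| / |V_A u V_B|`` (zeroed when the union has fewer
than 3 genes, so that only cluster-scale changes count). Averaging over
the grid gives a per-gene score ``d in [0, 1]``: the fraction of a
gene's correlation neighborhood not shared between the conditions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .corrnet import (
    ConditionPair,
    ThresholdGrid,
    correlation_matrices,
    default_z_max,
    make_grid,
)

__all__ = [
    "local_dissimilarity",
    "dcloc_scores",
    "dcloc_scores_from_z",
    "dc_gene_list",
    "DEFAULT_K",
]

DEFAULT_K = 100
MIN_UNION = 3


def local_dissimilarity(v_a, v_b) -> float:
    """Jaccard dissimilarity of two neighbor sets, with a small-union guard.

    Returns ``1 - |v_a n v_b| / |v_a u v_b|``, or 0 when the union holds
    fewer than 3 genes (differences between one or two neighbors reflect
    a single correlation, not a topology change). Neighbor sets must not
    contain the gene itself.
    """
    v_a, v_b = set(v_a), set(v_b)
    union = v_a | v_b
    if len(union) < MIN_UNION:
        return 0.0
    return 1.0 - len(v_a & v_b) / len(union)


def dcloc_scores(
    pair: ConditionPair,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Rank all genes by local topological differential correlation.

    Returns a DataFrame with columns ``gene_id, d, signed_sum,
    mean_neighbors_a, mean_neighbors_b, direction`` sorted by descending
    ``d`` (ties broken by gene id). ``d`` averages the per-threshold
    dissimilarity over the grid; ``signed_sum`` accumulates the same
    terms signed by which condition has the larger neighborhood, and
    ``direction`` is its sign ("A" when the gene is better connected in
    condition A wherever the networks disagree).
    """
    za, zb = correlation_matrices(pair)
    if grid is None:
        grid = make_grid(DEFAULT_K, default_z_max(za, zb))
    return dcloc_scores_from_z(za, zb, grid, absolute=absolute)


def dcloc_scores_from_z(za, zb, grid: ThresholdGrid, absolute: bool = False) -> pd.DataFrame:
    """Like :func:`dcloc_scores` but starting from Fisher-z matrices.

    Useful when the correlation matrices are already available or
    hand-constructed.
    """
    base_a = np.abs(za.z) if absolute else za.z
    base_b = np.abs(zb.z) if absolute else zb.z
    g = za.n_genes
    sum_d = np.zeros(g)
    signed = np.zeros(g)
    sum_na = np.zeros(g)
    sum_nb = np.zeros(g)
    for t in grid.thresholds:
        adj_a = base_a > t
        np.fill_diagonal(adj_a, False)
        adj_b = base_b > t
        np.fill_diagonal(adj_b, False)
        n_a = adj_a.sum(axis=1)
        n_b = adj_b.sum(axis=1)
        inter = (adj_a & adj_b).sum(axis=1)
        union = n_a + n_b - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            d_t = np.where(union >= MIN_UNION, 1.0 - inter / np.maximum(union, 1), 0.0)
        sum_d += d_t
        signed += d_t * np.sign(n_a - n_b)
        sum_na += n_a
        sum_nb += n_b
    d = sum_d / grid.k
    direction = np.where(signed > 0, "A", np.where(signed < 0, "B", "none"))
    table = pd.DataFrame(
        {
            "gene_id": za.gene_ids,
            "d": d,
            "signed_sum": signed,
            "mean_neighbors_a": sum_na / grid.k,
            "mean_neighbors_b": sum_nb / grid.k,
            "direction": direction,
        }
    )
    table = table.sort_values(
        ["d", "gene_id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )
    return table


def dc_gene_list(scores: pd.DataFrame, cutoff: float) -> dict:
    """Genes with ``d > cutoff``, split by direction.

    The comparison is strict, so a cutoff of 1 yields an empty list
    (``d`` never exceeds 1).
    """
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must lie in [0, 1]")
    hits = scores[scores["d"] > cutoff]
    return {
        key: hits.loc[hits["direction"] == key, "gene_id"].tolist()
        for key in ("A", "B", "none")
    }
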