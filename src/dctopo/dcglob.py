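"""Global-topology differential correlation (DCglob).

For every threshold on the grid, genes sitting in a >=3-gene connected
component of *both* condition networks are removed; the remaining genes
that still form >=3-gene components in exactly one condition's induced
subnetwork are exclusive to that condition at this threshold. Sweeping
the grid gives each gene a pair of boolean indicator profiles; the
longest contiguous run of exclusivity, measured as a Fisher-z interval
length, is converted to a one-sided p-value by Steiger's comparison of
correlation coefficients.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .corrnet import (
    ConditionPair,
    FisherZMatrix,
    ThresholdGrid,
    ThresholdNetwork,
    _in_min3,
    correlation_matrices,
    default_z_max,
    make_grid,
)

__all__ = [
    "ExclusiveSets",
    "IndicatorProfiles",
    "GlobRun",
    "exclusive_component_genes",
    "indicator_profiles",
    "indicator_profiles_from_z",
    "max_run",
    "interval_to_pvalue",
    "dcglob_scores",
    "DEFAULT_K",
]

DEFAULT_K = 200


@dataclass(eq=False)
class ExclusiveSets:
    """Genes exclusive to one condition's component structure at a threshold.

    ``removed`` holds genes clustered (component size >= 3) in both
    networks; ``a_tilde``/``b_tilde`` are the genes in >=3-components of
    the subnetwork induced on the remaining genes, per condition. The two
    tilde sets are provably disjoint: induced components only shrink.
    """

    t: float
    removed: frozenset
    a_tilde: frozenset
    b_tilde: frozenset


def _exclusive_masks(adj_a: np.ndarray, adj_b: np.ndarray):
    """Boolean masks (a_tilde, b_tilde, removed) from two adjacencies."""
    in_a = _in_min3(adj_a)
    in_b = _in_min3(adj_b)
    removed = in_a & in_b
    keep = np.flatnonzero(~removed)
    a_mask = np.zeros(adj_a.shape[0], dtype=bool)
    b_mask = np.zeros(adj_a.shape[0], dtype=bool)
    if keep.size:
        sub = np.ix_(keep, keep)
        a_mask[keep[_in_min3(adj_a[sub])]] = True
        b_mask[keep[_in_min3(adj_b[sub])]] = True
    return a_mask, b_mask, removed


def exclusive_component_genes(net_a: ThresholdNetwork, net_b: ThresholdNetwork) -> ExclusiveSets:
    """Apply the remove-then-recompute rule at a single threshold."""
    if net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must be over the same gene set")
    a_mask, b_mask, removed = _exclusive_masks(net_a.adjacency, net_b.adjacency)
    ids = np.asarray(net_a.gene_ids, dtype=object)
    return ExclusiveSets(
        t=net_a.t,
        removed=frozenset(ids[removed]),
        a_tilde=frozenset(ids[a_mask]),
        b_tilde=frozenset(ids[b_mask]),
    )


@dataclass(eq=False)
class IndicatorProfiles:
    """Per-gene boolean exclusivity profiles over the threshold grid.

    ``i_a[g, m] = 1`` iff gene ``g`` is in a component exclusive to
    condition A at grid threshold ``t_m``; never 1 in both conditions at
    the same threshold.
    """

    gene_ids: tuple
    grid: ThresholdGrid
    i_a: np.ndarray
    i_b: np.ndarray


def indicator_profiles(
    pair: ConditionPair,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> IndicatorProfiles:
    """Sweep the grid, collecting exclusivity indicators for every gene."""
    za, zb = correlation_matrices(pair)
    if grid is None:
        grid = make_grid(DEFAULT_K, default_z_max(za, zb))
    return indicator_profiles_from_z(za, zb, grid, absolute=absolute)


def indicator_profiles_from_z(
    za: FisherZMatrix, zb: FisherZMatrix, grid: ThresholdGrid, absolute: bool = False
) -> IndicatorProfiles:
    base_a = np.abs(za.z) if absolute else za.z
    base_b = np.abs(zb.z) if absolute else zb.z
    g = za.n_genes
    i_a = np.zeros((g, grid.k), dtype=bool)
    i_b = np.zeros((g, grid.k), dtype=bool)
    for m, t in enumerate(grid.thresholds):
        adj_a = base_a > t
        np.fill_diagonal(adj_a, False)
        adj_b = base_b > t
        np.fill_diagonal(adj_b, False)
        a_mask, b_mask, _ = _exclusive_masks(adj_a, adj_b)
        i_a[:, m] = a_mask
        i_b[:, m] = b_mask
    if (i_a & i_b).any():  # pragma: no cover - structurally impossible
        raise AssertionError("gene exclusive to both conditions at one threshold")
    return IndicatorProfiles(za.gene_ids, grid, i_a, i_b)


@dataclass(eq=False)
class GlobRun:
    """Longest exclusivity run of one gene: grid interval and direction."""

    direction: str  # "A", "B" or "none"
    start_idx: int | None
    end_idx: int | None
    run_start: float
    run_end: float
    run_length: float


def _runs(row: np.ndarray):
    """(start, end) index pairs of maximal runs of True in a boolean vector."""
    idx = np.flatnonzero(row)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def _longest_run(row: np.ndarray):
    """Longest run; among equally long runs, the one at higher thresholds."""
    best = None
    for s, e in _runs(row):
        if best is None or (e - s) >= (best[1] - best[0]):
            best = (s, e)
    return best


def max_run(i_a: np.ndarray, i_b: np.ndarray, grid: ThresholdGrid) -> GlobRun:
    """Longest contiguous exclusivity run across both conditions.

    Returns the longer of the best A-run and best B-run. On equal length
    the run with the higher mean threshold wins (stronger correlations),
    with a final deterministic preference for condition A. Both profiles
    empty gives an empty run with direction "none".
    """
    if len(i_a) != grid.k or len(i_b) != grid.k:
        raise ValueError("profile length does not match grid size")
    run_a = _longest_run(np.asarray(i_a, dtype=bool))
    run_b = _longest_run(np.asarray(i_b, dtype=bool))
    if run_a is None and run_b is None:
        return GlobRun("none", None, None, np.nan, np.nan, 0.0)
    if run_a is None:
        choice, direction = run_b, "B"
    elif run_b is None:
        choice, direction = run_a, "A"
    else:
        len_a, len_b = run_a[1] - run_a[0], run_b[1] - run_b[0]
        if len_a > len_b:
            choice, direction = run_a, "A"
        elif len_b > len_a:
            choice, direction = run_b, "B"
        else:
            # tie on length: higher mean threshold, then A
            mean_a = run_a[0] + run_a[1]
            mean_b = run_b[0] + run_b[1]
            if mean_b > mean_a:
                choice, direction = run_b, "B"
            else:
                choice, direction = run_a, "A"
    s, e = choice
    t = grid.thresholds
    return GlobRun(direction, s, e, float(t[s]), float(t[e]), float(t[e] - t[s]))


def interval_to_pvalue(run_length: float, n_a: int, n_b: int) -> float:
    """One-sided p-value for a Fisher-z interval length via Steiger's test.

    The difference of two independent Fisher-z correlation estimates has
    standard error ``sqrt(1/(n_a-3) + 1/(n_b-3))``; the run length is the
    observed z-scale gap sustained across the grid, so
    ``p = P(N(0,1) > run_length / SE)``. A zero-length run gives 0.5.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("Steiger's test needs more than 3 samples per group")
    if run_length < 0:
        raise ValueError("run length must be nonnegative")
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    return float(norm.sf(run_length / se))


def dcglob_scores(
    pair: ConditionPair,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Rank all genes by global topological differential correlation.

    Returns a DataFrame with columns ``gene_id, direction, run_start,
    run_end, run_length, p``, sorted by ascending p (ties broken by gene
    id). Genes never exclusive at any threshold get ``p = 1`` ("no
    evidence", ranking below a zero-length observed run at ``p = 0.5``).
    The computation is fully deterministic.
    """
    profiles = indicator_profiles(pair, grid, absolute=absolute)
    grid = profiles.grid
    rows = []
    for g, gene in enumerate(profiles.gene_ids):
        run = max_run(profiles.i_a[g], profiles.i_b[g], grid)
        if run.direction == "none":
            p = 1.0
        else:
            p = interval_to_pvalue(run.run_length, pair.n_a, pair.n_b)
        rows.append(
            (gene, run.direction, run.run_start, run.run_end, run.run_length, p)
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "direction", "run_start", "run_end", "run_length", "p"]
    )
    table = table.sort_values(["p", "gene_id"], kind="mergesort", ignore_index=True)
    return table
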