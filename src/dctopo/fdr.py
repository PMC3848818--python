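"""Subsampling-based false discovery rate estimation.

The null hypothesis is that both patient groups share one correlation
structure. It is emulated by repeatedly drawing two disjoint random
groups from the pooled cohort, ignoring labels, and counting how many
genes the chosen algorithm calls differentially correlated at the
cutoff. With ``pi0 = 1`` (a deliberate slight overestimate),
``FDR = pi0 * mean(n_0) / n_AB``: expected false positives over
observed discoveries — the standard subsampling/permutation FDR
estimator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrnet import (
    ConditionPair,
    ExpressionMatrix,
    ThresholdGrid,
    _condition_z,
    correlation_matrices,
    default_z_max,
    make_grid,
)
from . import dcglob as _dcglob
from . import dcloc as _dcloc

__all__ = [
    "NullDistribution",
    "FdrEstimate",
    "draw_null_pair",
    "score_vector",
    "null_scores",
    "count_dc",
    "null_counts",
    "estimate_fdr",
    "fdr_curve",
    "DEFAULT_B",
]

DEFAULT_B = 100
_SEED_MOD = 2**31

METHODS = ("dcglob", "dcloc")


def _check_method(method: str) -> str:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


def _default_grid(pooled: ExpressionMatrix, method: str) -> ThresholdGrid:
    """One grid for a whole subsampling analysis, from the pooled data.

    Observed and null runs must share a single threshold set for their
    detection counts to be comparable, so the grid end is fixed once
    from the strongest off-diagonal correlation in the pooled cohort.
    """
    zp = _condition_z(pooled)
    mask = ~np.eye(zp.n_genes, dtype=bool)
    z_max = float(np.abs(zp.z[mask]).max())
    k = _dcglob.DEFAULT_K if method == "dcglob" else _dcloc.DEFAULT_K
    return make_grid(k, z_max)


@dataclass(eq=False)
class NullDistribution:
    """Null counts of detected genes over B random subsample pairs.

    The 5%/95% percentile confidence bounds use linear interpolation
    (quantile type 7, the numpy default).
    """

    method: str
    cutoff: float
    counts: np.ndarray
    base_seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("null counts must be nonnegative")

    @property
    def b(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def se(self) -> float:
        """Standard error of the mean; NaN for a single replicate."""
        if self.b < 2:
            return float("nan")
        return float(np.std(self.counts, ddof=1) / np.sqrt(self.b))

    @property
    def ci_5(self) -> float:
        return float(np.percentile(self.counts, 5))

    @property
    def ci_95(self) -> float:
        return float(np.percentile(self.counts, 95))


@dataclass(eq=False)
class FdrEstimate:
    """FDR at one cutoff: ``pi0 * mean_null / n_ab`` (None when n_ab = 0).

    Values above 1 are reported as-is with ``flagged=True`` rather than
    truncated, so the caller sees that the cutoff detects fewer genes
    than expected under the null.
    """

    n_ab: int
    mean_null: float
    pi0: float = 1.0
    fdr: float | None = field(init=False)
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_ab < 0:
            raise ValueError("observed count must be nonnegative")
        if self.n_ab == 0:
            self.fdr = None
            self.flagged = False
        else:
            self.fdr = self.pi0 * self.mean_null / self.n_ab
            self.flagged = self.fdr > 1.0


def draw_null_pair(
    pooled: ExpressionMatrix, n_a: int, n_b: int, seed: int | np.random.Generator
) -> ConditionPair:
    """Two disjoint random groups from the pooled cohort, ignoring labels.

    Deterministic given the seed. Disjointness matters: overlapping
    groups would share samples and deflate apparent differential
    correlation under the null.
    """
    if n_a + n_b > pooled.n_samples:
        raise ValueError(
            f"cannot draw {n_a}+{n_b} disjoint samples from {pooled.n_samples}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(pooled.n_samples)
    return ConditionPair(
        pooled.subset_samples(perm[:n_a]),
        pooled.subset_samples(perm[n_a : n_a + n_b]),
        allow_unequal=(n_a != n_b),
    )


def score_vector(
    pair: ConditionPair,
    method: str,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> pd.Series:
    """Per-gene score of the chosen algorithm, indexed by gene id.

    For ``dcglob`` the score is the p-value (smaller = stronger DC); for
    ``dcloc`` it is ``d`` (larger = stronger DC).
    """
    _check_method(method)
    if method == "dcglob":
        table = _dcglob.dcglob_scores(pair, grid, absolute=absolute)
        return table.set_index("gene_id")["p"].reindex(list(pair.gene_ids))
    table = _dcloc.dcloc_scores(pair, grid, absolute=absolute)
    return table.set_index("gene_id")["d"].reindex(list(pair.gene_ids))


def count_dc(scores: pd.Series, method: str, cutoff: float) -> int:
    """Number of detected genes at a cutoff: ``p < cutoff`` or ``d > cutoff``."""
    _check_method(method)
    if method == "dcglob":
        return int((scores < cutoff).sum())
    return int((scores > cutoff).sum())


def null_scores(
    pooled: ExpressionMatrix,
    method: str,
    n_a: int,
    n_b: int,
    b: int = DEFAULT_B,
    base_seed: int = 0,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-gene scores for B independent null subsample pairs.

    One column per replicate (``null_000`` ...); replicate ``i`` uses
    seed ``base_seed + i``. Computing scores once and thresholding at
    many cutoffs afterwards is what makes FDR curves affordable.
    """
    _check_method(method)
    if b < 1:
        raise ValueError("need at least one null replicate")
    if grid is None:
        grid = _default_grid(pooled, method)
    cols = {}
    for i in range(b):
        pair = draw_null_pair(pooled, n_a, n_b, (base_seed + i) % _SEED_MOD)
        cols[f"null_{i:03d}"] = score_vector(pair, method, grid, absolute=absolute)
    return pd.DataFrame(cols)


def null_counts(
    pooled: ExpressionMatrix,
    method: str,
    cutoff: float,
    n_a: int,
    n_b: int,
    b: int = DEFAULT_B,
    base_seed: int = 0,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
    scores: pd.DataFrame | None = None,
) -> NullDistribution:
    """Null distribution of detected-gene counts at one cutoff.

    ``scores`` may carry a precomputed ``null_scores`` table to avoid
    rerunning the algorithm.
    """
    if scores is None:
        scores = null_scores(pooled, method, n_a, n_b, b, base_seed, grid, absolute)
    counts = np.array([count_dc(scores[c], method, cutoff) for c in scores.columns])
    return NullDistribution(method=method, cutoff=cutoff, counts=counts, base_seed=base_seed)


def estimate_fdr(n_ab: int, null, pi0: float = 1.0) -> FdrEstimate:
    """FDR estimate ``pi0 * mean(n_0) / n_ab``.

    ``null`` is a :class:`NullDistribution` or directly the mean null
    count. ``pi0`` is the proportion of genes that are not
    differentially correlated; 1.0 overestimates the FDR slightly and is
    the safe default when detections are few relative to all genes.
    """
    mean_null = null.mean if isinstance(null, NullDistribution) else float(null)
    return FdrEstimate(n_ab=int(n_ab), mean_null=mean_null, pi0=pi0)


def fdr_curve(
    pooled: ExpressionMatrix,
    pair: ConditionPair,
    method: str,
    cutoffs,
    b: int = DEFAULT_B,
    base_seed: int = 0,
    grid: ThresholdGrid | None = None,
    absolute: bool = False,
    null_score_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detected counts and FDR estimates over a grid of cutoffs.

    The B null subsample runs are shared across all cutoffs: scores are
    computed once per null pair and thresholded at every cutoff.
    Returns columns ``cutoff, n_ab, mean_null, se, ci_5, ci_95, fdr``.
    """
    _check_method(method)
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs and sorted(cutoffs, reverse=True) != cutoffs:
        raise ValueError("cutoff grid must be ordered")
    if grid is None:
        # one shared grid covering the observed pair's correlation range:
        # observed and null counts are only comparable when thresholded
        # over the same threshold series
        za, zb = correlation_matrices(pair)
        k = _dcglob.DEFAULT_K if method == "dcglob" else _dcloc.DEFAULT_K
        grid = make_grid(k, default_z_max(za, zb))
    observed = score_vector(pair, method, grid, absolute=absolute)
    if null_score_table is None:
        null_score_table = null_scores(
            pooled, method, pair.n_a, pair.n_b, b, base_seed, grid, absolute
        )
    rows = []
    for cut in cutoffs:
        null = null_counts(
            pooled, method, cut, pair.n_a, pair.n_b, b, base_seed,
            scores=null_score_table,
        )
        n_ab = count_dc(observed, method, cut)
        est = estimate_fdr(n_ab, null)
        rows.append(
            (cut, n_ab, null.mean, null.se, null.ci_5, null.ci_95,
             np.nan if est.fdr is None else est.fdr)
        )
    return pd.DataFrame(
        rows, columns=["cutoff", "n_ab", "mean_null", "se", "ci_5", "ci_95", "fdr"]
    )
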