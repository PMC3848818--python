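"""Correlation-network substrate shared by the DCglob and DCloc algorithms.

Expression containers, the Fisher z-transform of Pearson correlation,
equidistant threshold grids on the Fisher-z scale, hard-thresholded
correlation networks and their connected components.

The central object is the per-condition Fisher-transformed correlation
matrix ``z_ij = atanh(c_ij)``: thresholding it at a grid value ``t``
yields an undirected network whose edge sets shrink monotonically as
``t`` grows, which is what both topology-comparison algorithms exploit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "CORR_CLIP",
    "Z_CLIP",
    "ExpressionMatrix",
    "ConditionPair",
    "FisherZMatrix",
    "ThresholdGrid",
    "ThresholdNetwork",
    "fisher_transform",
    "correlation_matrices",
    "make_grid",
    "default_z_max",
    "network_at",
    "components_min3",
]

# Pearson correlations are clipped to +-(1 - 1e-6) before atanh so that
# perfectly correlated gene pairs (e.g. duplicated rows) map to a finite z.
CORR_CLIP = 1.0 - 1e-6
Z_CLIP = float(np.arctanh(CORR_CLIP))

MIN_COMPONENT = 3  # smallest component size at which topology is meaningful


@dataclass(eq=False)
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Rows are genes, columns are samples; identifiers must be unique and
    all values finite (missing values are not supported).
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, indices) -> "ExpressionMatrix":
        """New matrix restricted to the given sample positions (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.gene_ids,
            tuple(self.sample_ids[i] for i in indices),
            self.values[:, indices],
        )


@dataclass(eq=False)
class ConditionPair:
    """Two expression matrices over an identical gene set, one per condition.

    Group sizes must be equal unless ``allow_unequal`` is set: comparing
    unequal groups gives the two correlation estimates different sampling
    variability, which inflates apparent differential correlation.
    """

    a: ExpressionMatrix
    b: ExpressionMatrix
    allow_unequal: bool = False

    def __post_init__(self) -> None:
        if self.a.gene_ids != self.b.gene_ids:
            raise ValueError("conditions must share the same gene ids in the same order")
        if set(self.a.sample_ids) & set(self.b.sample_ids):
            raise ValueError("conditions must have disjoint sample ids")
        if self.a.n_samples != self.b.n_samples:
            if not self.allow_unequal:
                raise ValueError(
                    f"unequal group sizes ({self.a.n_samples} vs {self.b.n_samples}); "
                    "pass allow_unequal=True to override (risks false positives)"
                )
            warnings.warn(
                "comparing unequal group sizes: correlation estimates have "
                "different sampling variability, expect false positives",
                stacklevel=2,
            )

    @property
    def gene_ids(self) -> tuple:
        return self.a.gene_ids

    @property
    def n_a(self) -> int:
        return self.a.n_samples

    @property
    def n_b(self) -> int:
        return self.b.n_samples

    def swapped(self) -> "ConditionPair":
        """The same pair with the roles of the conditions exchanged."""
        return ConditionPair(self.b, self.a, allow_unequal=self.allow_unequal)


@dataclass(eq=False)
class FisherZMatrix:
    """Symmetric matrix of Fisher-transformed Pearson correlations.

    The diagonal is set to 0 and excluded from all downstream use; ``n``
    is the number of samples the correlations were estimated from.
    """

    gene_ids: tuple
    z: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        z = np.asarray(self.z, dtype=float)
        g = len(self.gene_ids)
        if z.shape != (g, g):
            raise ValueError("z matrix shape does not match gene list")
        self.z = z

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def fisher_transform(c):
    """Fisher z-transform ``z = atanh(c) = 0.5*ln((1+c)/(1-c))``.

    Input correlations are clipped to ``+-(1 - 1e-6)`` so that the result
    is always finite. Scalar in, scalar out; arrays are transformed
    elementwise.
    """
    arr = np.asarray(c, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite correlation value")
    if (np.abs(arr) > 1.0 + 1e-9).any():
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -CORR_CLIP, CORR_CLIP))
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def _condition_z(em: ExpressionMatrix) -> FisherZMatrix:
    if em.n_samples < 4:
        raise ValueError("need at least 4 samples per condition to compare correlations")
    sd = em.values.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(em.gene_ids[i] for i in bad[:5])
        raise ValueError(f"constant expression row(s): {names} (correlation undefined)")
    c = np.corrcoef(em.values)
    np.clip(c, -CORR_CLIP, CORR_CLIP, out=c)
    z = np.arctanh(c)
    z = (z + z.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(z, 0.0)
    return FisherZMatrix(em.gene_ids, z, em.n_samples)


def correlation_matrices(pair: ConditionPair) -> tuple[FisherZMatrix, FisherZMatrix]:
    """Per-condition Fisher-transformed Pearson correlation matrices."""
    return _condition_z(pair.a), _condition_z(pair.b)


@dataclass(eq=False)
class ThresholdGrid:
    """``k`` equidistant Fisher-z thresholds ``t_m = m * z_max / k``.

    Zero is excluded (a zero threshold would connect every positively
    correlated pair into one near-complete graph) and ``z_max`` is the
    last grid value, so the grid covers ``(0, z_max]``.
    """

    k: int
    z_max: float
    thresholds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("grid needs at least 2 thresholds")
        if not (self.z_max > 0):
            raise ValueError("z_max must be positive")
        self.thresholds = np.linspace(self.z_max / self.k, self.z_max, self.k)

    @property
    def delta(self) -> float:
        return self.z_max / self.k


def make_grid(k: int, z_max: float) -> ThresholdGrid:
    """Equidistant threshold grid on the Fisher-z scale."""
    return ThresholdGrid(k=k, z_max=float(z_max))


def default_z_max(za: FisherZMatrix, zb: FisherZMatrix) -> float:
    """Largest off-diagonal |z| over both conditions.

    Mirrors choosing the grid end from the strongest correlation present
    in the data, so the grid covers the full range of correlations.
    """
    g = za.n_genes
    if g < 2:
        raise ValueError("need at least two genes")
    mask = ~np.eye(g, dtype=bool)
    return float(max(np.abs(za.z[mask]).max(), np.abs(zb.z[mask]).max()))


@dataclass(eq=False)
class ThresholdNetwork:
    """Hard-thresholded correlation network at a single threshold ``t``.

    Undirected simple graph: edge {i, j} present iff ``z_ij > t``
    (strictly), stored as a boolean adjacency matrix with a False
    diagonal.
    """

    gene_ids: tuple
    adjacency: np.ndarray
    t: float

    def edge_set(self) -> set:
        """Edges as a set of frozensets of gene ids (for small graphs)."""
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return {frozenset((self.gene_ids[i], self.gene_ids[j])) for i, j in zip(ii, jj)}


def network_at(zmat: FisherZMatrix, t: float, absolute: bool = False) -> ThresholdNetwork:
    """Network with an edge wherever the Fisher-z correlation exceeds ``t``.

    With ``absolute=True`` edges are placed on ``|z| > t`` so that strong
    negative correlations also connect genes; the default follows the
    signed convention (negative correlations never produce edges).
    """
    if not (t > 0):
        raise ValueError("threshold must be positive")
    base = np.abs(zmat.z) if absolute else zmat.z
    adj = base > t
    np.fill_diagonal(adj, False)
    adj |= adj.T  # defensive: z is symmetric, keep adjacency exactly so
    return ThresholdNetwork(zmat.gene_ids, adj, float(t))


def _component_labels(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component labels and component sizes of a boolean adjacency."""
    n_comp, labels = _cc(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes


def _in_min3(adj: np.ndarray) -> np.ndarray:
    """Boolean mask of nodes lying in a connected component of size >= 3."""
    if adj.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    labels, sizes = _component_labels(adj)
    return sizes[labels] >= MIN_COMPONENT


def components_min3(net: ThresholdNetwork) -> list[frozenset]:
    """Connected components with at least 3 genes, largest first.

    Components of one or two genes are discarded: with fewer than three
    nodes there is no non-trivial topology to compare, and pairwise
    correlation changes are better studied directly.
    """
    labels, sizes = _component_labels(net.adjacency)
    comps = []
    for lab in np.flatnonzero(sizes >= MIN_COMPONENT):
        members = frozenset(net.gene_ids[i] for i in np.flatnonzero(labels == lab))
        comps.append(members)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps
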