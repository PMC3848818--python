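"""Synthetic two-condition expression data with planted correlation modules.

The generator emulates the motivating biological scenario: a regulatory
module whose target genes are co-expressed in one condition (the
regulator is functional) but uncorrelated in the other (the regulator is
broken), on a background of independent genes. Each module is a single
latent factor: a gene in module ``m`` of condition ``q`` is

    x_g = sqrt(rho_q) * f_m + sqrt(1 - rho_q) * eps_g

with ``f_m`` and ``eps_g`` i.i.d. standard normal across samples, so the
expected pairwise Pearson correlation between two module genes is
exactly ``rho_q``. Ground truth (module membership and a differential-
correlation flag) is returned alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrnet import ConditionPair, ExpressionMatrix

__all__ = ["PlantedModule", "SyntheticSpec", "generate", "toy_fixture"]


@dataclass(frozen=True)
class PlantedModule:
    """One latent-factor module: size and per-condition correlation.

    ``de_shift`` adds a constant to the module genes in condition B,
    creating differential expression without touching correlation.
    """

    size: int
    rho_a: float
    rho_b: float
    de_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be positive")
        for rho in (self.rho_a, self.rho_b):
            if not (0.0 <= rho < 1.0):
                raise ValueError("module correlation must lie in [0, 1)")

    @property
    def is_dc(self) -> bool:
        return self.rho_a != self.rho_b


@dataclass
class SyntheticSpec:
    """Study design for the generator.

    Defaults plant one 20-gene module correlated at rho = 0.8 in
    condition A and uncorrelated in B, among 2000 independent background
    genes, with 100 samples per group — a strong, localized correlation
    change of the kind the algorithms target.
    """

    n_genes: int = 2020
    n_samples_per_group: int = 100
    modules: list = field(default_factory=lambda: [PlantedModule(20, 0.8, 0.0)])
    background_rho: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 4:
            raise ValueError("need at least 4 samples per group")
        if not (0.0 <= self.background_rho < 1.0):
            raise ValueError("background correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed total gene count")


def _factor_block(rng: np.random.Generator, size: int, rho: float, n: int) -> np.ndarray:
    f = rng.standard_normal(n)
    eps = rng.standard_normal((size, n))
    return np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps


def generate(spec: SyntheticSpec) -> tuple[ConditionPair, pd.DataFrame]:
    """Draw one two-condition data set plus its ground-truth table.

    Deterministic given ``spec.seed``. The truth table has columns
    ``gene_id, module, dc_flag``; ``dc_flag`` is set for genes whose
    module has ``rho_a != rho_b`` (background genes are never flagged).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_per_group
    width = len(str(spec.n_genes))
    gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(spec.n_genes))
    n_module = sum(m.size for m in spec.modules)
    n_bg = spec.n_genes - n_module

    data = {}
    for cond in ("A", "B"):
        blocks = []
        for mod in spec.modules:
            rho = mod.rho_a if cond == "A" else mod.rho_b
            block = _factor_block(rng, mod.size, rho, n)
            if cond == "B" and mod.de_shift:
                block = block + mod.de_shift
            blocks.append(block)
        if n_bg:
            if spec.background_rho > 0:
                blocks.append(_factor_block(rng, n_bg, spec.background_rho, n))
            else:
                blocks.append(rng.standard_normal((n_bg, n)))
        data[cond] = np.vstack(blocks) * spec.noise_sd

    samples_a = tuple(f"A_s{i + 1:03d}" for i in range(n))
    samples_b = tuple(f"B_s{i + 1:03d}" for i in range(n))
    pair = ConditionPair(
        ExpressionMatrix(gene_ids, samples_a, data["A"]),
        ExpressionMatrix(gene_ids, samples_b, data["B"]),
    )

    module_col, flag_col = [], []
    for m_idx, mod in enumerate(spec.modules, start=1):
        module_col += [m_idx] * mod.size
        flag_col += [mod.is_dc] * mod.size
    module_col += [0] * n_bg
    flag_col += [False] * n_bg
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "module": module_col, "dc_flag": flag_col}
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Hand-written toy fixtures for oracle tests.
# ---------------------------------------------------------------------------

# A monotone base series plus small distinct perturbations: any two of
# these four rows have Pearson correlation > 0.99.
_MODULE_ROWS = [
    [0.0, 1.1, 1.9, 3.0, 4.1, 4.9, 6.0, 7.1],
    [0.2, 0.9, 2.1, 2.9, 4.0, 5.2, 5.9, 7.0],
    [-0.1, 1.0, 2.2, 3.1, 3.9, 5.0, 6.1, 6.9],
    [0.1, 1.2, 2.0, 3.2, 4.2, 5.1, 5.8, 7.2],
]
# Scrambled (mutually weakly correlated) rows used as background and as
# the "broken module" state.
_SCRAMBLE_ROWS = [
    [3.0, 0.5, 6.1, 1.2, 7.0, 2.3, 5.1, 4.0],
    [5.0, 2.1, 0.3, 6.8, 1.5, 7.2, 3.9, 0.8],
    [1.5, 6.2, 2.8, 0.2, 4.9, 7.1, 0.7, 3.3],
    [4.1, 0.0, 6.0, 1.9, 7.1, 1.1, 3.0, 4.9],
    [2.9, 5.9, 0.2, 7.0, 0.9, 4.0, 5.2, 2.1],
    [6.1, 2.2, 3.9, -0.1, 5.0, 1.0, 6.9, 3.1],
]


def _samples(prefix: str, n: int) -> tuple:
    return tuple(f"{prefix}{i + 1}" for i in range(n))


def _identical() -> ConditionPair:
    """Both conditions carry the very same values: every DC score is null."""
    values = np.array(
        [
            [1.0, 2.0, 1.5, 3.0, 2.5, 2.0],
            [2.0, 1.0, 2.5, 1.5, 3.0, 2.2],
            [5.0, 4.0, 4.5, 5.5, 4.2, 5.1],
            [0.5, 1.5, 0.7, 1.2, 0.9, 1.1],
        ]
    )
    genes = ("G1", "G2", "G3", "G4")
    return ConditionPair(
        ExpressionMatrix(genes, _samples("a", 6), values),
        ExpressionMatrix(genes, _samples("b", 6), values.copy()),
    )


def _one_module_flip() -> ConditionPair:
    """Four genes tightly co-expressed in A only, over two background genes.

    In condition A the module rows M1-M4 follow a common monotone trend
    (pairwise r > 0.99); in condition B the same values are scrambled,
    destroying the module while keeping each gene's marginal
    distribution. N1/N2 are weakly correlated background in both
    conditions.
    """
    genes = ("M1", "M2", "M3", "M4", "N1", "N2")
    a = np.array(_MODULE_ROWS + _SCRAMBLE_ROWS[:2])
    b = np.array(
        [
            [4.1, 0.0, 6.0, 1.9, 7.1, 1.1, 3.0, 4.9],
            [2.9, 5.9, 0.2, 7.0, 0.9, 4.0, 5.2, 2.1],
            [6.1, 2.2, 3.9, -0.1, 5.0, 1.0, 6.9, 3.1],
            [1.2, 7.2, 4.2, 0.1, 5.8, 2.0, 3.2, 5.1],
            [0.5, 6.1, 3.0, 5.1, 2.3, 7.0, 4.0, 1.2],
            [7.2, 0.3, 5.0, 1.5, 6.8, 0.8, 2.1, 3.9],
        ]
    )
    return ConditionPair(
        ExpressionMatrix(genes, _samples("a", 8), a),
        ExpressionMatrix(genes, _samples("b", 8), b),
    )


def _tie_case() -> ConditionPair:
    """Mirror construction: P-module correlated in A, Q-module in B.

    The Q rows in condition B carry exactly the values the P rows carry
    in condition A (and vice versa), so the two conditions are exact
    mirror images under the gene relabeling P<->Q. P genes and Q genes
    therefore receive identical DC score magnitudes in opposite
    directions — equal-length exclusive runs that exercise deterministic
    tie handling in ranked output.
    """
    genes = ("P1", "P2", "P3", "Q1", "Q2", "Q3")
    corr = np.array(_MODULE_ROWS[:3])
    scram = np.array(_SCRAMBLE_ROWS[:3])
    a = np.vstack([corr, scram])
    b = np.vstack([scram, corr])
    return ConditionPair(
        ExpressionMatrix(genes, _samples("a", 8), a),
        ExpressionMatrix(genes, _samples("b", 8), b),
    )


_FIXTURES = {
    "identical": _identical,
    "one_module_flip": _one_module_flip,
    "tie_case": _tie_case,
}


def toy_fixture(name: str) -> ConditionPair:
    """Small hard-coded condition pairs used by oracle tests."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
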