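"""3:1 codon-junction dinucleotide signatures.

The 3:1 dinucleotide of consecutive codons — third base of codon i paired
with first base of codon i+1 — sits at the least selectively constrained
dinucleotide context of a coding sequence, so its relative-abundance vector
behaves like a genomic signature. For each of the 16 dinucleotides XY,

    rho*_XY = f_XY / (f_X * f_Y)

where f_XY is the junction dinucleotide frequency and f_X, f_Y are the
position-specific mononucleotide frequencies (third-position and
first-position marginals of the junction counts — pooled base frequencies
would be inconsistent with the 3:1 restriction). Junctions never span gene
boundaries, and junctions touching an ambiguous codon are skipped.

Signatures are compared by the sigma difference (mean absolute rho*
difference over the 16 dinucleotides) and by Spearman/Kendall rank
covariation of the two 16-vectors.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CodingSequence

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
#: Row-major order of the 16 dinucleotides (AA, AC, ..., TT).
DINUCLEOTIDES = tuple(x + y for x in BASES for y in BASES)


@dataclass(frozen=True)
class Dinuc31Profile:
    """Junction counts and derived relative abundances for one sequence set."""

    counts: np.ndarray  # 4x4, rows = third-position base, cols = first-position base

    def __post_init__(self) -> None:
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be a 4x4 matrix")
        if self.junction_count == 0:
            raise ValueError("profile has no valid junctions")

    @property
    def junction_count(self) -> int:
        return int(self.counts.sum())

    @property
    def f_xy(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def f3(self) -> np.ndarray:
        """Third-position base frequencies (row marginal)."""
        return self.f_xy.sum(axis=1)

    @property
    def f1(self) -> np.ndarray:
        """First-position base frequencies (column marginal)."""
        return self.f_xy.sum(axis=0)

    @property
    def rho(self) -> np.ndarray:
        """4x4 matrix of rho*_XY; 0 where a marginal frequency is 0."""
        denom = np.outer(self.f3, self.f1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, self.f_xy / denom, 0.0)
        return r

    def rho_vector(self) -> np.ndarray:
        """rho* values in :data:`DINUCLEOTIDES` order (length 16)."""
        return self.rho.reshape(-1)

    def rho_dict(self) -> dict[str, float]:
        return dict(zip(DINUCLEOTIDES, self.rho_vector().tolist()))


def _junction_counts(cds: CodingSequence) -> np.ndarray:
    counts = np.zeros((4, 4), dtype=np.int64)
    codons = cds.codons()
    for i in range(len(codons) - 1):
        a, b = codons[i], codons[i + 1]
        if set(a) <= set(BASES) and set(b) <= set(BASES):
            counts[_IDX[a[2]], _IDX[b[0]]] += 1
    return counts


def dinuc31_profile(
    genes: CodingSequence | Iterable[CodingSequence],
) -> Dinuc31Profile:
    """3:1 junction profile of one gene or of a pooled gene set (a genome).

    For gene sets, junction and positional base counts are pooled across
    genes before any frequency is formed; junctions are taken only within
    genes.
    """
    if isinstance(genes, CodingSequence):
        genes = [genes]
    counts = np.zeros((4, 4), dtype=np.int64)
    for g in genes:
        counts += _junction_counts(g)
    return Dinuc31Profile(counts=counts)


def sigma_difference(a: Dinuc31Profile, b: Dinuc31Profile) -> float:
    """Mean absolute rho* difference over exactly 16 dinucleotides."""
    return float(np.abs(a.rho_vector() - b.rho_vector()).mean())


@dataclass(frozen=True)
class RankCovariation:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.spearman_rho) or np.isnan(self.kendall_tau))


def rank_covariation(
    a: Dinuc31Profile,
    b: Dinuc31Profile,
    n_permutations: int | None = None,
    seed: int = 0,
) -> RankCovariation:
    """Spearman's rho and Kendall's tau between two 16-value signatures.

    Average ranks for ties; two-sided p-values from the standard large-sample
    approximations, or — with ``n_permutations`` — from a seeded Monte Carlo
    permutation test (exact permutation over 16! values being infeasible).
    A constant signature makes both coefficients undefined (returned as NaN).
    """
    x, y = a.rho_vector(), b.rho_vector()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return RankCovariation(nan, nan, nan, nan)
    rho, rho_p = stats.spearmanr(x, y)
    tau, tau_p = stats.kendalltau(x, y)
    if n_permutations:
        rng = np.random.default_rng(seed)
        hits_rho = hits_tau = 1  # add-one: the observed permutation counts
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            r, _ = stats.spearmanr(x, perm)
            t, _ = stats.kendalltau(x, perm)
            hits_rho += abs(r) >= abs(rho) - 1e-12
            hits_tau += abs(t) >= abs(tau) - 1e-12
        rho_p = hits_rho / (n_permutations + 1)
        tau_p = hits_tau / (n_permutations + 1)
    return RankCovariation(float(rho), float(rho_p), float(tau), float(tau_p))
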