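"""Relative synonymous codon usage (RSCU), the genome-vs-gene chi-square
comparison, and the codon adaptation index (CAI).

RSCU of codon i in an n-fold degenerate family is the observed count divided
by the count expected under equal synonymous usage: RSCU_i = n X_i / sum_j X_j.
Start (ATG), Trp (TGG) and stop codons are excluded throughout, leaving 59
codons over 18 amino acids.

CAI of a gene against a genome reference RSCU table is CAIobs / CAImax, where
CAIobs is the mean reference RSCU over the gene's codon occurrences and
CAImax the mean over the same occurrences of the family-maximum reference
RSCU — so a gene built only from each amino acid's most frequent codon scores
exactly 1.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

from scipy import stats

from .genetic_code import (
    codon_to_family_aa,
    rscu_chi2_df,
    synonymous_families,
)
from .io import CodingSequence

CAI_FLAG_THRESHOLD_DEFAULT = 1.5
CHI2_ALPHA_DEFAULT = 0.05


def count_codons(genes: CodingSequence | Iterable[CodingSequence]) -> Counter:
    """Occurrences of the 59 degenerate sense codons, pooled over genes.

    Ambiguous codons, ATG, TGG and stop codons are skipped.
    """
    if isinstance(genes, CodingSequence):
        genes = [genes]
    counts: Counter = Counter()
    for g in genes:
        for codon in g.countable_codons():
            if codon_to_family_aa(codon) is not None:
                counts[codon] += 1
    return counts


@dataclass(frozen=True)
class RSCUTable:
    """RSCU values keyed by codon; NaN for codons of absent amino acids."""

    rscu: dict[str, float]
    codon_counts: dict[str, int]
    aa_counts: dict[str, int]

    def family_max(self, aa: str) -> float:
        return max(self.rscu[c] for c in synonymous_families()[aa])


def rscu(counts: Counter | dict[str, int]) -> RSCUTable:
    """RSCU table from codon counts (only degenerate sense codons enter)."""
    values: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    clean: dict[str, int] = {}
    for aa, codons in synonymous_families().items():
        total = sum(int(counts.get(c, 0)) for c in codons)
        aa_counts[aa] = total
        n = len(codons)
        for c in codons:
            x = int(counts.get(c, 0))
            clean[c] = x
            values[c] = n * x / total if total > 0 else float("nan")
    return RSCUTable(rscu=values, codon_counts=clean, aa_counts=aa_counts)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    effective_df: int
    p: float


def rscu_chi2_test(
    gene_counts: Counter | dict[str, int], reference: RSCUTable
) -> Chi2Result:
    """Chi-square comparison of a gene's codon usage against a genome reference.

    Expected counts apportion the gene's per-amino-acid totals by the
    reference's within-family codon proportions; the statistic sums
    (obs-exp)^2/exp over codons with positive expectation. The reported df is
    fixed at the code-table value (41 for the standard code) regardless of
    which amino acids the gene happens to use; the effective df (codons
    actually contributing minus families actually present) is reported
    alongside for transparency.
    """
    fams = synonymous_families()
    chi2 = 0.0
    eff_df = 0
    any_codon = False
    for aa, codons in fams.items():
        gene_total = sum(int(gene_counts.get(c, 0)) for c in codons)
        if gene_total == 0:
            continue
        any_codon = True
        ref_total = sum(reference.codon_counts.get(c, 0) for c in codons)
        if ref_total == 0:
            warnings.warn(
                f"amino acid {aa} absent from reference; family skipped",
                stacklevel=2,
            )
            continue
        contributing = 0
        for c in codons:
            exp = gene_total * reference.codon_counts.get(c, 0) / ref_total
            if exp > 0:
                obs = int(gene_counts.get(c, 0))
                chi2 += (obs - exp) ** 2 / exp
                contributing += 1
        eff_df += max(contributing - 1, 0)
    if not any_codon:
        raise ValueError("gene has no countable degenerate codons")
    df = rscu_chi2_df()
    return Chi2Result(
        chi2=chi2, df=df, effective_df=eff_df, p=float(stats.chi2.sf(chi2, df))
    )


@dataclass(frozen=True)
class CAIResult:
    cai: float
    cai_obs: float
    cai_max: float
    n_codons: int


_GEOMETRIC_FLOOR = 0.01  # floor on reference RSCU inside log means


def cai(
    gene_counts: Counter | dict[str, int],
    reference: RSCUTable,
    mean: str = "arithmetic",
    max_weighting: str = "gene",
) -> CAIResult:
    """Codon adaptation index of a gene against a genome reference RSCU table.

    Each codon occurrence contributes its reference RSCU to CAIobs and its
    family's maximum reference RSCU to CAImax, so CAImax is weighted by the
    gene's own amino-acid composition and a gene of only most-frequent
    codons scores exactly 1. Occurrences of amino acids absent from the
    reference are skipped with a warning.

    ``mean``: "arithmetic" (default) or "geometric" (classic log-mean form;
    zero reference RSCU values are floored at 0.01 inside the logs).
    ``max_weighting``: "gene" (default, per-occurrence) or "genome"
    (CAImax as the unweighted mean of family maxima over the reference's
    present amino acids — with this variant CAI = 1 is generally not
    attainable and values may exceed 1 for genes rich in strongly
    biased families).
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean {mean!r}")
    if max_weighting not in ("gene", "genome"):
        raise ValueError(f"unknown max_weighting {max_weighting!r}")
    fams = synonymous_families()
    obs_sum = 0.0
    max_sum = 0.0
    n = 0

    def term(v: float) -> float:
        return math.log(max(v, _GEOMETRIC_FLOOR)) if mean == "geometric" else v

    for aa, codons in fams.items():
        if reference.aa_counts.get(aa, 0) == 0:
            used = sum(int(gene_counts.get(c, 0)) for c in codons)
            if used:
                warnings.warn(
                    f"amino acid {aa} absent from reference; "
                    f"{used} occurrence(s) skipped",
                    stacklevel=2,
                )
            continue
        fam_max = reference.family_max(aa)
        for c in codons:
            x = int(gene_counts.get(c, 0))
            if x == 0:
                continue
            obs_sum += x * term(reference.rscu[c])
            max_sum += x * term(fam_max)
            n += x
    if n == 0:
        raise ValueError("gene has no codons covered by the reference")
    if max_weighting == "genome":
        maxima = [
            term(reference.family_max(aa))
            for aa in fams
            if reference.aa_counts.get(aa, 0) > 0
        ]
        cai_max = sum(maxima) / len(maxima)
    else:
        cai_max = max_sum / n
    cai_obs = obs_sum / n
    if mean == "geometric":
        cai_obs, cai_max = math.exp(cai_obs), math.exp(cai_max)
    return CAIResult(cai=cai_obs / cai_max, cai_obs=cai_obs, cai_max=cai_max, n_codons=n)


def genome_reference(
    genes: "Iterable",
    method: str = "pooled",
) -> RSCUTable:
    """Genome-wide reference RSCU table.

    "pooled" (default) computes RSCU from codon counts summed over all genes
    (length-weighted, the natural genome-frequency estimate); "mean" averages
    the per-gene RSCU values, weighting genes equally, and carries the pooled
    counts so chi-square expectations remain well defined.
    """
    genes = list(genes)
    pooled = count_codons(genes)
    if method == "pooled":
        return rscu(pooled)
    if method != "mean":
        raise ValueError(f"unknown method {method!r}")
    fams = synonymous_families()
    per_gene = [rscu(count_codons(g)) for g in genes]
    values: dict[str, float] = {}
    for aa, codons in fams.items():
        for c in codons:
            vals = [
                t.rscu[c] for t in per_gene if t.aa_counts.get(aa, 0) > 0
            ]
            values[c] = sum(vals) / len(vals) if vals else float("nan")
    base = rscu(pooled)
    return RSCUTable(rscu=values, codon_counts=base.codon_counts, aa_counts=base.aa_counts)


@dataclass(frozen=True)
class GenomeCAISummary:
    mean: float
    dispersion: float
    n_genes: int


def genome_cai_summary(
    cai_values: Iterable[float], dispersion: str = "sd"
) -> GenomeCAISummary:
    """Mean and dispersion (per-gene SD by default, SEM optional) of CAI."""
    vals = [float(v) for v in cai_values]
    if len(vals) < 2:
        raise ValueError("need at least 2 genes")
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    sd = math.sqrt(var)
    if dispersion == "sem":
        sd /= math.sqrt(len(vals))
    elif dispersion != "sd":
        raise ValueError(f"unknown dispersion {dispersion!r}")
    return GenomeCAISummary(mean=mean, dispersion=sd, n_genes=len(vals))


def cai_deviation_flag(
    gene_cai: float,
    genome: GenomeCAISummary,
    threshold: float = CAI_FLAG_THRESHOLD_DEFAULT,
) -> bool:
    """True when |gene CAI - genome mean| exceeds threshold dispersion units."""
    if genome.dispersion == 0:
        raise ValueError("zero CAI dispersion; deviation undefined")
    return abs(gene_cai - genome.mean) > threshold * genome.dispersion
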