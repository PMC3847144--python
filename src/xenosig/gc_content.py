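"""GC content by codon position and the two-dispersion-unit deviation rule.

A gene is compositionally atypical for GC when its total GC deviates from the
genome mean by at least two dispersion units, or when its first- and
third-position deviations share a sign and at least one of them reaches two
dispersion units. "Dispersion" is, by default, the standard deviation of the
per-gene GC distribution across the genome (see ``dispersion`` argument); the
standard error of the mean is available but flags almost everything in
genomes of realistic size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CodingSequence

GC_FLAG_THRESHOLD_DEFAULT = 2.0

_POSITIONS = ("gc1", "gc2", "gc3", "gct")


@dataclass(frozen=True)
class GCProfile:
    """Per-gene GC percentages at the three codon positions and in total."""

    gc1: float
    gc2: float
    gc3: float
    gct: float
    counted_codons: int


@dataclass(frozen=True)
class GenomeGCSummary:
    """Unweighted per-gene mean and dispersion of GC at each position."""

    mean: dict[str, float]
    dispersion: dict[str, float]
    n_genes: int


@dataclass(frozen=True)
class GCDeviation:
    """Deviations (in dispersion units) and the two flagging clauses."""

    dev: dict[str, float]
    total_clause: bool
    positional_clause: bool
    flag: bool


def gc_profile(cds: CodingSequence) -> GCProfile:
    """GC% at codon positions 1-3 and overall, over unambiguous codons."""
    codons = cds.countable_codons()
    n = len(codons)
    if n == 0:
        raise ValueError(f"{cds.gene_id}: no countable codons")
    gc = [0, 0, 0]
    for codon in codons:
        for p in range(3):
            if codon[p] in "GC":
                gc[p] += 1
    return GCProfile(
        gc1=100.0 * gc[0] / n,
        gc2=100.0 * gc[1] / n,
        gc3=100.0 * gc[2] / n,
        gct=100.0 * (gc[0] + gc[1] + gc[2]) / (3 * n),
        counted_codons=n,
    )


def genome_gc_summary(
    profiles: list[GCProfile], dispersion: str = "sd"
) -> GenomeGCSummary:
    """Unweighted mean and dispersion of per-gene GC at each position.

    ``dispersion``: "sd" (sample standard deviation across genes, default) or
    "sem" (SD / sqrt(n_genes)).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genes for a genome GC summary")
    if dispersion not in ("sd", "sem"):
        raise ValueError(f"unknown dispersion {dispersion!r}")
    mean, disp = {}, {}
    for pos in _POSITIONS:
        vals = np.array([getattr(p, pos) for p in profiles], dtype=float)
        mean[pos] = float(vals.mean())
        sd = float(vals.std(ddof=1))
        disp[pos] = sd / math.sqrt(len(vals)) if dispersion == "sem" else sd
    return GenomeGCSummary(mean=mean, dispersion=disp, n_genes=len(profiles))


def gc_deviation_flag(
    gene: GCProfile,
    genome: GenomeGCSummary,
    threshold: float = GC_FLAG_THRESHOLD_DEFAULT,
) -> GCDeviation:
    """Apply the two-clause deviation rule.

    Clause 1: |total GC deviation| >= threshold dispersion units.
    Clause 2: GC1 and GC3 deviations share a sign and at least one reaches
    the threshold. Zero dispersion at a tested position raises (degenerate
    genome).
    """
    dev = {}
    for pos in _POSITIONS:
        d = genome.dispersion[pos]
        if d == 0:
            raise ValueError(f"zero dispersion at {pos}; deviation undefined")
        dev[pos] = (getattr(gene, pos) - genome.mean[pos]) / d
    total_clause = abs(dev["gct"]) >= threshold
    positional_clause = (
        dev["gc1"] * dev["gc3"] > 0
        and max(abs(dev["gc1"]), abs(dev["gc3"])) >= threshold
    )
    return GCDeviation(
        dev=dev,
        total_clause=total_clause,
        positional_clause=positional_clause,
        flag=total_clause or positional_clause,
    )
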