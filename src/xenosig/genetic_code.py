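"""Standard genetic code bookkeeping for codon-usage statistics.

Codon-usage measures (RSCU, CAI, the chi-square comparison) are defined over
the *degenerate sense* codons of the standard code: the 61 sense codons minus
ATG (Met) and TGG (Trp), whose amino acids admit no synonymous choice, leaving
59 codons spread over 18 amino acids. Stop codons never enter any count.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
#: All 64 codons in lexicographic order.
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD.stop_codons)
#: Codons excluded from codon-usage analyses: start (ATG), Trp (TGG) and stops.
NONDEGENERATE_CODONS = frozenset({"ATG", "TGG"})

#: codon -> one-letter amino acid, sense codons only.
CODON_TO_AA = dict(_STANDARD.forward_table)


@lru_cache(maxsize=1)
def synonymous_families() -> dict[str, tuple[str, ...]]:
    """Map each degenerate amino acid to its tuple of synonymous sense codons.

    Met and Trp are omitted (single-codon amino acids carry no usage signal).
    """
    fams: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        if codon in NONDEGENERATE_CODONS:
            continue
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in sorted(fams.items())}


@lru_cache(maxsize=1)
def degenerate_codons() -> tuple[str, ...]:
    """The 59 sense codons that enter RSCU/CAI counts, sorted."""
    return tuple(sorted(c for fam in synonymous_families().values() for c in fam))


def codon_to_family_aa(codon: str) -> str | None:
    """Amino acid of a codon if it belongs to a degenerate family, else None."""
    if codon in NONDEGENERATE_CODONS or codon in STOP_CODONS:
        return None
    return CODON_TO_AA.get(codon)


def rscu_chi2_df() -> int:
    """Degrees of freedom of the codon-usage chi-square comparison.

    One free proportion per codon within each amino-acid family:
    (number of degenerate sense codons) - (number of degenerate amino acids).
    Computed from the code table at runtime; 41 for the standard code.
    """
    fams = synonymous_families()
    return sum(len(v) for v in fams.values()) - len(fams)
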