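"""Reciprocal-best-hit orthology from all-against-all protein searches.

A pair of genes in two genomes is called orthologous when each is the other's
best surviving similarity hit after fixed cutoffs (E-value <= 1e-5, bitscore
>= 50, and mutual alignment coverage when sequence lengths are available —
the "full-length sequences" requirement, default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SimilarityHit

EVALUE_MAX_DEFAULT = 1e-5
BITSCORE_MIN_DEFAULT = 50.0
MIN_COVERAGE_DEFAULT = 0.8


@dataclass(frozen=True)
class RBHPair:
    genome_a: str
    gene_a: str
    genome_b: str
    gene_b: str
    forward_bitscore: float
    reverse_bitscore: float


def filter_hits(
    hits: list[SimilarityHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    bitscore_min: float = BITSCORE_MIN_DEFAULT,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
) -> list[SimilarityHit]:
    """Keep hits passing the E-value, bitscore and (if lengths known) mutual
    coverage cutoffs. Coverage = alignment_length / sequence_length, required
    on both query and subject sides."""
    out = []
    for h in hits:
        if h.evalue > evalue_max or h.bitscore < bitscore_min:
            continue
        if h.query_length and h.alignment_length / h.query_length < min_coverage:
            continue
        if h.subject_length and h.alignment_length / h.subject_length < min_coverage:
            continue
        out.append(h)
    return out


def _dedupe(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Keep only the max-bitscore hit for each (query, subject) pair."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or _hit_order(h) > _hit_order(prev):
            best[key] = h
    return list(best.values())


def _hit_order(h: SimilarityHit) -> tuple[float, float, str]:
    # higher bitscore, then lower evalue, then lexicographically smaller subject
    # (subject string negated lexicographically via tuple comparison workaround)
    return (h.bitscore, -h.evalue, _neg_str(h.subject_id))


def _neg_str(s: str) -> tuple[int, ...]:
    # tuple that sorts in reverse lexicographic order of s
    return tuple(-ord(c) for c in s)


def best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best surviving hit per query: highest bitscore, ties broken by lowest
    E-value then lexicographically smallest subject id (deterministic)."""
    best: dict[str, SimilarityHit] = {}
    for h in _dedupe(hits):
        prev = best.get(h.query_id)
        if prev is None or _hit_order(h) > _hit_order(prev):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: list[SimilarityHit],
    hits_ba: list[SimilarityHit],
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[RBHPair]:
    """Mutual-argmax pairs between two (already filtered) hit lists.

    ``hits_ab`` are queries from genome A against genome B, ``hits_ba`` the
    reverse direction. A pair (a, b) is emitted iff b is a's best hit and a
    is b's best hit. Output is sorted by (genome_a, gene_a).
    """
    fwd = best_hits(hits_ab)
    rev = best_hits(hits_ba)
    pairs = []
    for a, hit in sorted(fwd.items()):
        b = hit.subject_id
        back = rev.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(
                RBHPair(
                    genome_a=genome_a,
                    gene_a=a,
                    genome_b=genome_b,
                    gene_b=b,
                    forward_bitscore=hit.bitscore,
                    reverse_bitscore=back.bitscore,
                )
            )
    return pairs
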