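"""Input readers and shared domain types.

Everything downstream consumes the types defined here: in-frame coding
sequences, protein similarity hits (BLAST outfmt-6 style), strain trait
tables, and two-cluster protein alignments with a rooted tree.

Sequence parsing is case-insensitive and maps U to T. A codon containing any
symbol outside {A,C,G,T} is kept in the sequence but excluded from every
downstream count (GC, dinucleotide, RSCU, CAI); the junction dinucleotide
spanning such a codon is excluded as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS

_VALID_BASES = frozenset("ACGTN")
_MISSING_TOKENS = ("", "ND", "NA", "nd", "na")


class ValidationError(ValueError):
    """An input record violated a structural requirement."""


# ---------------------------------------------------------------------------
# Coding sequences


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame nucleotide CDS.

    ``nt_seq`` is an upper-case DNA string whose length is a positive
    multiple of 3; ``codon_count`` counts all codons including ambiguous
    ones (those are skipped at analysis time, not at parse time).
    """

    gene_id: str
    genome_id: str
    nt_seq: str

    def __post_init__(self) -> None:
        n = len(self.nt_seq)
        if n == 0 or n % 3 != 0:
            raise ValidationError(
                f"CDS {self.gene_id!r}: length {n} is not a positive multiple of 3"
            )

    @property
    def codon_count(self) -> int:
        return len(self.nt_seq) // 3

    def codons(self) -> list[str]:
        s = self.nt_seq
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def countable_codons(self) -> list[str]:
        """Codons made only of unambiguous A/C/G/T bases."""
        return [c for c in self.codons() if set(c) <= set("ACGT")]


def _normalise_seq(raw: str) -> str:
    return raw.strip().upper().replace("U", "T")


def read_fasta_cds(
    path: str | Path, genome_id: str, strict: bool = False
) -> list[CodingSequence]:
    """Read a nucleotide-CDS FASTA into :class:`CodingSequence` records.

    Records whose length is not a multiple of 3, or that contain characters
    outside {A,C,G,T,N} (after U->T), are skipped with a warning; with
    ``strict=True`` they raise :class:`ValidationError` naming the record.
    Internal stop codons are reported as warnings but the record is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise_seq(str(rec.seq))
        problem = None
        if len(seq) == 0 or len(seq) % 3 != 0:
            problem = f"length {len(seq)} not a positive multiple of 3"
        elif not set(seq) <= _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            problem = f"invalid characters {bad}"
        if problem is not None:
            msg = f"record {rec.id!r}: {problem}"
            if strict:
                raise ValidationError(msg)
            warnings.warn(f"skipping {msg}", stacklevel=2)
            continue
        if rec.id in seen:
            raise ValidationError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        cds = CodingSequence(gene_id=rec.id, genome_id=genome_id, nt_seq=seq)
        internal = [c for c in cds.codons()[:-1] if c in STOP_CODONS]
        if internal:
            warnings.warn(
                f"record {rec.id!r}: {len(internal)} internal stop codon(s); kept",
                stacklevel=2,
            )
        out.append(cds)
    if not out:
        raise ValidationError(f"no valid CDS records in {path}")
    return out


def write_fasta_cds(genes: list[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.nt_seq}\n")


# ---------------------------------------------------------------------------
# Similarity hits


@dataclass(frozen=True)
class SimilarityHit:
    """One line of an all-against-all protein search (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}->{self.subject_id}: evalue < 0")
        if self.bitscore < 0:
            raise ValidationError(f"{self.query_id}->{self.subject_id}: bitscore < 0")


def read_similarity_table(path: str | Path) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular output (14-column with qlen/slen accepted).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [qlen slen].
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 14):
                raise ValidationError(
                    f"{path}:{lineno}: expected 12 or 14 columns, got {len(cols)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    query_length=int(cols[12]) if len(cols) == 14 else None,
                    subject_length=int(cols[13]) if len(cols) == 14 else None,
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Strain trait tables


@dataclass
class StrainTraitTable:
    """Strain-by-trait table with an in-family membership flag.

    ``data`` is indexed by strain id; ``membership`` is a boolean Series on
    the same index. Numeric columns are quantitative traits, everything else
    categorical; missing cells (empty or "ND") are NaN and excluded from
    tests.
    """

    data: pd.DataFrame
    membership: pd.Series
    categorical_traits: list[str] = field(default_factory=list)
    quantitative_traits: list[str] = field(default_factory=list)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_family(self) -> int:
        return int(self.membership.sum())


_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


def _parse_membership(col: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        s = str(v).strip().lower()
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        raise ValidationError(f"membership value {v!r} is not boolean-like")

    return col.map(one)


def read_trait_table(
    path: str | Path,
    membership_col: str = "in_family",
    strain_col: str | None = None,
) -> StrainTraitTable:
    """Read a TSV trait table (header row, one row per strain).

    The first column is the strain id unless ``strain_col`` names another.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=_MISSING_TOKENS
    )
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need at least strain id and membership columns")
    sid = strain_col or df.columns[0]
    if membership_col not in df.columns:
        raise ValidationError(f"{path}: missing membership column {membership_col!r}")
    if df[sid].duplicated().any():
        dups = df[sid][df[sid].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate strain ids {dups}")
    df = df.set_index(sid)
    membership = _parse_membership(df[membership_col])
    traits = df.drop(columns=[membership_col])
    categorical, quantitative = [], []
    for col in traits.columns:
        numeric = pd.to_numeric(traits[col], errors="coerce")
        nonmissing = traits[col].notna()
        if nonmissing.any() and numeric[nonmissing].notna().all():
            traits[col] = numeric
            quantitative.append(col)
        else:
            categorical.append(col)
    return StrainTraitTable(
        data=traits,
        membership=membership,
        categorical_traits=categorical,
        quantitative_traits=quantitative,
    )


def write_trait_table(
    table: StrainTraitTable, path: str | Path, membership_col: str = "in_family"
) -> None:
    out = table.data.copy()
    out[membership_col] = table.membership.map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index_label="strain_id", na_rep="ND")


# ---------------------------------------------------------------------------
# Clustered alignments (functional divergence input)

_MISSING_RESIDUES = frozenset("-.?X*")


@dataclass
class ClusteredAlignment:
    """A gapped protein alignment, a rooted tree, and a two-cluster split.

    Every tree leaf must carry a sequence and a cluster label in {1, 2}; each
    cluster's leaves must form a monophyletic group (a connected subtree).
    """

    sequences: dict[str, str]
    tree: dendropy.Tree
    clusters: dict[str, int]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal alignment lengths: {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise ValidationError("alignment has zero columns")
        leaves = {t.taxon.label for t in self.tree.leaf_node_iter()}
        missing = leaves - self.sequences.keys()
        if missing:
            raise ValidationError(f"tree leaves without sequences: {sorted(missing)}")
        unlabelled = leaves - self.clusters.keys()
        if unlabelled:
            raise ValidationError(f"tree leaves without cluster: {sorted(unlabelled)}")
        if set(self.clusters.values()) - {1, 2}:
            raise ValidationError("cluster labels must be 1 or 2")
        for k in (1, 2):
            members = {n for n, c in self.clusters.items() if c == k}
            if not members:
                raise ValidationError(f"cluster {k} is empty")
            if len(members) > 1 and not self._is_monophyletic(members):
                raise ValidationError(f"cluster {k} is not a connected subtree")

    def _is_monophyletic(self, members: set[str]) -> bool:
        self.tree.is_rooted = True
        taxa = [
            t.taxon
            for t in self.tree.leaf_node_iter()
            if t.taxon.label in members
        ]
        mrca = self.tree.mrca(taxa=taxa)
        below = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        return below == members

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    def cluster_members(self, k: int) -> list[str]:
        return sorted(n for n, c in self.clusters.items() if c == k)

    def site_states(self, k: int, site: int) -> dict[str, str | None]:
        """Residues of cluster-``k`` leaves at 0-based ``site``; None if missing."""
        out: dict[str, str | None] = {}
        for name in self.cluster_members(k):
            res = self.sequences[name][site].upper()
            out[name] = None if res in _MISSING_RESIDUES else res
        return out


def read_clustered_alignment(
    alignment_path: str | Path,
    tree_path: str | Path,
    cluster1: list[str],
    cluster2: list[str],
) -> ClusteredAlignment:
    """Load a protein alignment (FASTA) + rooted Newick tree + cluster lists."""
    seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(alignment_path), "fasta")
    }
    if not seqs:
        raise ValidationError(f"no sequences in {alignment_path}")
    tree = dendropy.Tree.get(
        path=str(tree_path),
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    overlap = set(cluster1) & set(cluster2)
    if overlap:
        raise ValidationError(f"leaves in both clusters: {sorted(overlap)}")
    clusters = {n: 1 for n in cluster1} | {n: 2 for n in cluster2}
    return ClusteredAlignment(sequences=seqs, tree=tree, clusters=clusters)


def is_missing_value(x: object) -> bool:
    """NaN-safe missingness check used across enrichment code."""
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)
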