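"""Ground-truth generators for every analysis stage.

The generators emulate the study conditions the screening battery is meant
for: bacterial genomes whose genes share one codon-usage model, donor genes
implanted with a tunable degree of amelioration, per-site substitution counts
under the two-state functional-divergence model, and strain trait tables with
a planted enrichment. All outputs are deterministic under a seed.

Amelioration is modelled as per-codon mixture sampling — an alien gene draws
each codon from the host model with probability alpha and from the donor
model otherwise — a single interpretable knob standing in for the slow
compositional decay of transferred genes. Host and donor share the same
amino-acid composition by default, so compositional contrasts come purely
from synonymous-codon and base-composition differences (an ``aa_freqs``
override exists for harder tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .funcdiv import SiteChangeCounts
from .genetic_code import CODON_TO_AA, synonymous_families
from .io import CodingSequence, StrainTraitTable

# Sense amino acids, including the non-degenerate Met and Trp (they carry GC
# signal even though they never enter RSCU/CAI).
_AMINO_ACIDS = tuple(sorted(set(CODON_TO_AA.values())))
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _CODONS_BY_AA.setdefault(_aa, ())
_CODONS_BY_AA = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in _AMINO_ACIDS
}


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}

#: Log-weight pattern for 3:1 junction preferences (rows: previous third base,
#: cols: next first base). CG and TA suppression with mild AA/TT/GC enrichment
#: — the classic shape of bacterial dinucleotide signatures. Scaled by the
#: ``dinuc_bias_strength`` knob of :func:`make_codon_model`.
DINUC_BIAS_PATTERN = np.array(
    [
        #  A     C     G     T
        [+0.3, 0.0, 0.0, -0.2],  # A.
        [0.0, 0.0, -1.0, 0.0],  # C.
        [0.0, +0.4, 0.0, 0.0],  # G.
        [-0.6, 0.0, 0.0, +0.3],  # T.
    ]
)


@dataclass(frozen=True)
class CodonModel:
    """Per-amino-acid codon probabilities plus an amino-acid frequency vector.

    ``junction_logits`` (4x4, previous third base x next first base) skew the
    codon choice given the preceding codon, creating a genome-wide 3:1
    dinucleotide signature; all zeros means junction-independent sampling.
    """

    codon_probs: dict[str, dict[str, float]]
    aa_freqs: dict[str, float]
    gc3_target: float
    junction_logits: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4))
    )

    def __post_init__(self) -> None:
        for aa, probs in self.codon_probs.items():
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9 or min(probs.values()) < 0:
                raise ValueError(f"codon probabilities of {aa} invalid (sum {s})")
        if np.asarray(self.junction_logits).shape != (4, 4):
            raise ValueError("junction_logits must be 4x4")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for generated objects."""

    seed: int
    alien_genes: dict[str, dict] = field(default_factory=dict)
    diverged_sites: list[int] = field(default_factory=list)
    theta: float | None = None
    enriched_trait: str | None = None
    enriched_category: str | None = None
    odds_ratio: float | None = None


def _expected_gc3(beta: float, aa_freqs: dict[str, float]) -> float:
    total = 0.0
    for aa, f in aa_freqs.items():
        codons = _CODONS_BY_AA[aa]
        w = np.array([np.exp(beta * (c[2] in "GC")) for c in codons])
        w /= w.sum()
        total += f * float(w[[c[2] in "GC" for c in codons]].sum())
    return total


def make_codon_model(
    gc3_target: float,
    bias_strength: float = 1.0,
    seed: int = 0,
    aa_freqs: dict[str, float] | None = None,
    dinuc_bias_strength: float = 1.0,
) -> CodonModel:
    """Codon model whose synonymous usage is tilted toward a GC3 target.

    Within each family, codon probability is proportional to
    exp(beta * [third base is G or C]); beta is solved by bisection so the
    expected GC3 over genes equals ``gc3_target``, then scaled by
    ``bias_strength`` (1 reaches the target, 0 gives uniform synonymous
    usage). Targets outside the code's reachable range are clamped with a
    warning. ``dinuc_bias_strength`` scales the model's junction pattern —
    the CG/TA-suppression base shape (:data:`DINUC_BIAS_PATTERN`) plus a
    seed-dependent perturbation, so models built with different seeds carry
    distinct 3:1 dinucleotide signatures, the way genomic signatures
    discriminate real organisms. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 < gc3_target < 1.0:
        raise ValueError("gc3_target must be in (0, 1)")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    if aa_freqs is None:
        aa_freqs = {aa: 1.0 / len(_AMINO_ACIDS) for aa in _AMINO_ACIDS}
    lo, hi = -30.0, 30.0
    reach_lo, reach_hi = _expected_gc3(lo, aa_freqs), _expected_gc3(hi, aa_freqs)
    target = gc3_target
    if not reach_lo <= target <= reach_hi:
        target = min(max(target, reach_lo), reach_hi)
        warnings.warn(
            f"gc3_target {gc3_target:.3f} outside reachable "
            f"[{reach_lo:.3f}, {reach_hi:.3f}]; clamped",
            stacklevel=2,
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _expected_gc3(mid, aa_freqs) < target:
            lo = mid
        else:
            hi = mid
    beta = bias_strength * 0.5 * (lo + hi)
    probs: dict[str, dict[str, float]] = {}
    for aa in _AMINO_ACIDS:
        codons = _CODONS_BY_AA[aa]
        w = np.array([np.exp(beta * (c[2] in "GC")) for c in codons])
        w /= w.sum()
        probs[aa] = dict(zip(codons, w.tolist()))
    pattern = DINUC_BIAS_PATTERN + rng.normal(0.0, 0.35, size=(4, 4))
    return CodonModel(
        codon_probs=probs,
        aa_freqs=dict(aa_freqs),
        gc3_target=gc3_target,
        junction_logits=dinuc_bias_strength * pattern,
    )


def _model_arrays(model: CodonModel):
    """Flat joint codon distribution plus first/third-base index arrays."""
    aas = sorted(model.aa_freqs)
    aa_p = np.array([model.aa_freqs[a] for a in aas], dtype=float)
    aa_p /= aa_p.sum()
    codons: list[str] = []
    joint: list[float] = []
    for a, pa in zip(aas, aa_p):
        for c in sorted(model.codon_probs[a]):
            codons.append(c)
            joint.append(pa * model.codon_probs[a][c])
    joint_arr = np.array(joint)
    joint_arr /= joint_arr.sum()
    first = np.array([_BASE_IDX[c[0]] for c in codons])
    third = np.array([_BASE_IDX[c[2]] for c in codons])
    # per previous-third-base conditional distributions, junction bias applied
    logits = np.asarray(model.junction_logits)
    conditional = np.empty((4, len(codons)))
    for p3 in range(4):
        w = joint_arr * np.exp(logits[p3, first])
        conditional[p3] = w / w.sum()
    return codons, joint_arr, conditional, third


def sample_gene(
    model: CodonModel,
    n_codons: int,
    rng: np.random.Generator,
    donor: CodonModel | None = None,
    amelioration: float = 1.0,
) -> str:
    """Draw one CDS codon-by-codon.

    With a ``donor`` model, each codon uses the host ``model`` with
    probability ``amelioration`` and the donor otherwise (amelioration 1 is
    fully host-like, 0 fully donor-like). Each step samples from the active
    model's joint (amino acid, codon) distribution, reweighted by its
    junction logits given the previous codon's third base — the mechanism
    that imprints a genome-wide 3:1 dinucleotide signature. With equal
    ``aa_freqs`` and zero junction bias, host/donor contrasts are purely
    synonymous.
    """
    host_arr = _model_arrays(model)
    donor_arr = _model_arrays(donor) if donor is not None else None
    out = []
    use_host = (
        np.ones(n_codons, dtype=bool)
        if donor is None
        else rng.random(n_codons) < amelioration
    )
    prev3: int | None = None
    for i in range(n_codons):
        codons, joint, conditional, third = host_arr if use_host[i] else donor_arr
        p = joint if prev3 is None else conditional[prev3]
        j = rng.choice(len(codons), p=p)
        prev3 = int(third[j])
        out.append(codons[j])
    return "".join(out)


def generate_genome_with_transfers(
    n_genes: int,
    host: CodonModel,
    donor: CodonModel | None = None,
    n_alien: int = 0,
    amelioration: float = 0.0,
    length_range: tuple[int, int] = (150, 450),
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[list[CodingSequence], SyntheticTruth]:
    """A genome of native genes plus implanted donor genes.

    Gene lengths (in codons) are uniform over ``length_range``; the alien
    subset is chosen at random. Stop codons are never generated, so the
    output FASTA parses with zero validation warnings.
    """
    if n_alien > n_genes or n_genes <= 0:
        raise ValueError("invalid n_genes / n_alien")
    if n_alien > 0 and donor is None:
        raise ValueError("n_alien > 0 requires a donor model")
    if not 0.0 <= amelioration <= 1.0:
        raise ValueError("amelioration must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alien_idx = set(rng.choice(n_genes, size=n_alien, replace=False).tolist())
    width = len(str(n_genes))
    genes = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_genes):
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1))
        gene_id = f"g{i + 1:0{width}d}"
        if i in alien_idx:
            seq = sample_gene(host, n_codons, rng, donor=donor, amelioration=amelioration)
            truth.alien_genes[gene_id] = {
                "donor_gc3": donor.gc3_target,
                "amelioration": amelioration,
            }
        else:
            seq = sample_gene(host, n_codons, rng)
        genes.append(CodingSequence(gene_id=gene_id, genome_id=genome_id, nt_seq=seq))
    return genes, truth


def simulate_site_counts(
    L: int,
    theta: float,
    a: float,
    b: float,
    d1: float = 1.0,
    d2: float = 1.0,
    seed: int = 0,
) -> tuple[SiteChangeCounts, SyntheticTruth]:
    """Per-site substitution counts under the two-state divergence model.

    With probability theta a site is diverged (independent Gamma(a, b) rates
    in the two clusters); otherwise both clusters share one rate. Counts are
    Poisson with mean rate x depth.
    """
    if not 0.0 <= theta <= 1.0 or min(a, b, d1, d2) <= 0 or L <= 0:
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    diverged = rng.random(L) < theta
    lam_shared = rng.gamma(shape=a, scale=1.0 / b, size=L)
    lam1 = np.where(diverged, rng.gamma(shape=a, scale=1.0 / b, size=L), lam_shared)
    lam2 = np.where(diverged, rng.gamma(shape=a, scale=1.0 / b, size=L), lam_shared)
    x1 = rng.poisson(lam1 * d1)
    x2 = rng.poisson(lam2 * d2)
    truth = SyntheticTruth(
        seed=seed,
        diverged_sites=[int(i) + 1 for i in np.nonzero(diverged)[0]],
        theta=theta,
    )
    return SiteChangeCounts(x1=x1, x2=x2, d1=d1, d2=d2), truth


#: NCBI organism-info-style categorical traits: name -> (categories, baseline probs).
DEFAULT_CATEGORICAL_TRAITS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "Habitat": (
        ("Host-associated", "Multiple", "Specialized", "Terrestrial", "Aquatic"),
        (0.30, 0.27, 0.13, 0.10, 0.20),
    ),
    "OxygenReq": (("Facultative", "Aerobic", "Anaerobic"), (0.36, 0.38, 0.26)),
    "TempRange": (("Mesophilic", "Thermophilic"), (0.90, 0.10)),
    "Motility": (("Yes", "No"), (0.60, 0.40)),
    "GramStain": (("Negative", "Positive"), (0.65, 0.35)),
}

#: Quantitative traits: name -> (mean, sd); identical in both groups (null).
DEFAULT_QUANTITATIVE_TRAITS: dict[str, tuple[float, float]] = {
    "GenomeSize": (3.6, 1.5),
    "GCContent": (48.5, 10.0),
    "OptimalTemp": (40.0, 12.0),
}


def generate_trait_table(
    n_strains: int = 1000,
    n_family: int = 50,
    planted_or: float = 1.0,
    planted: tuple[str, str] = ("Habitat", "Host-associated"),
    missingness: float = 0.0,
    seed: int = 0,
    categorical: dict | None = None,
    quantitative: dict | None = None,
) -> tuple[StrainTraitTable, SyntheticTruth]:
    """Strain trait table with one category planted at a given odds ratio.

    Family members draw the planted trait from a distribution whose planted
    category has odds ``planted_or`` times the baseline odds; every other
    trait (and all quantitative traits) is identically distributed in both
    groups. ``planted_or = 1`` yields a pure null table.
    """
    import pandas as pd

    if planted_or < 1.0:
        raise ValueError("planted odds ratio must be >= 1")
    if not 0 < n_family <= n_strains:
        raise ValueError("invalid n_family / n_strains")
    categorical = categorical or DEFAULT_CATEGORICAL_TRAITS
    quantitative = quantitative or DEFAULT_QUANTITATIVE_TRAITS
    trait, category = planted
    if trait not in categorical or category not in categorical[trait][0]:
        raise ValueError(f"planted category {planted} not in trait set")
    rng = np.random.default_rng(seed)
    member = np.zeros(n_strains, dtype=bool)
    member[rng.choice(n_strains, size=n_family, replace=False)] = True
    data: dict[str, list] = {}
    for name, (cats, probs) in categorical.items():
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        if name == trait and planted_or > 1.0:
            j = cats.index(category)
            p0 = probs[j]
            odds = planted_or * p0 / (1 - p0)
            p1 = odds / (1 + odds)
            fam_probs = probs * (1 - p1) / (1 - p0)
            fam_probs[j] = p1
        else:
            fam_probs = probs
        col = []
        for i in range(n_strains):
            p = fam_probs if member[i] else probs
            col.append(cats[rng.choice(len(cats), p=p)])
        data[name] = col
    for name, (mu, sd) in quantitative.items():
        data[name] = rng.normal(mu, sd, size=n_strains).tolist()
    df = pd.DataFrame(data, index=[f"strain_{i + 1:04d}" for i in range(n_strains)])
    if missingness > 0:
        mask = rng.random(df.shape) < missingness
        df = df.mask(mask)
    table = StrainTraitTable(
        data=df,
        membership=pd.Series(member, index=df.index),
        categorical_traits=list(categorical),
        quantitative_traits=list(quantitative),
    )
    truth = SyntheticTruth(
        seed=seed,
        enriched_trait=trait if planted_or > 1 else None,
        enriched_category=category if planted_or > 1 else None,
        odds_ratio=planted_or,
    )
    return table, truth


def simulate_clustered_alignment(
    L: int,
    theta: float,
    a: float,
    b: float,
    n1: int = 6,
    n2: int = 6,
    seed: int = 0,
):
    """Approximate sequence-level divergence simulator (thin wrapper).

    Simulates site counts, then realises them on two ladder subtrees by
    splitting each cluster's leaves into contiguous segments of distinct
    residues — the Fitch count on a ladder then equals the simulated count
    (capped at the leaves-minus-one / alphabet limits). Useful for
    end-to-end tests of the alignment pathway; not a substitution-process
    simulator.
    """
    from .io import ClusteredAlignment
    import dendropy

    rng = np.random.default_rng(seed)
    counts, truth = simulate_site_counts(L, theta, a, b, seed=seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"

    def ladder(names: list[str]) -> str:
        t = names[-1]
        for n in reversed(names[:-1]):
            t = f"({n},{t})"
        return t

    names1 = [f"c1_{i}" for i in range(n1)]
    names2 = [f"c2_{i}" for i in range(n2)]
    newick = f"({ladder(names1)},{ladder(names2)});"
    seqs = {n: [] for n in names1 + names2}
    for site in range(L):
        for names, x in ((names1, counts.x1[site]), (names2, counts.x2[site])):
            k = int(min(x, len(names) - 1, len(alphabet) - 1))
            cuts = sorted(rng.choice(np.arange(1, len(names)), size=k, replace=False))
            residues = rng.choice(len(alphabet), size=k + 1, replace=False)
            seg = 0
            for i, n in enumerate(names):
                if seg < k and i >= cuts[seg]:
                    seg += 1
                seqs[n].append(alphabet[residues[seg]])
    sequences = {n: "".join(s) for n, s in seqs.items()}
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    clusters = {n: 1 for n in names1} | {n: 2 for n in names2}
    ca = ClusteredAlignment(sequences=sequences, tree=tree, clusters=clusters)
    return ca, counts, truth
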