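# Methods

This note documents the statistical machinery, the defaults and the design
choices made where the underlying methodology leaves room. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compositional battery

All per-gene statistics are computed over in-frame coding sequences. Codons
containing any base outside {A,C,G,T} are excluded from every count, and a
3:1 junction spanning such a codon is excluded too; this avoids biasing
frequencies with ambiguity calls. Internal stop codons are reported as
warnings but the sequence is retained; stop codons never enter RSCU or CAI
counts.

### GC by codon position

`gc_profile` counts G+C at each codon position over the unambiguous codons;
GCt is the mean over all counted bases. Genome aggregates are *unweighted*
per-gene means — every gene counts once regardless of length — matching the
convention of comparing a gene to "the mean for all genes".

**Dispersion.** The deviation rule expresses a gene's departure in
"dispersion units". We interpret the dispersion as the standard deviation of
the per-gene GC distribution (config `dispersion="sd"`), not the standard
error of the mean: with thousands of genes SD/√n shrinks to a fraction of a
GC point and would flag essentially every gene, which contradicts the sparse
flagging the rule is meant to produce. `dispersion="sem"` is available for
comparison. The flag threshold defaults to 2.0 units and the two clauses are
(i) |ΔGCt| ≥ 2 and (ii) sign(ΔGC1) = sign(ΔGC3) with max(|ΔGC1|, |ΔGC3|) ≥ 2.

### 3:1 dinucleotide signature

Junctions are (third base of codon i, first base of codon i+1) strictly
within genes. The mononucleotide frequencies entering
ρ\*\_XY = f\_XY/(f\_X·f\_Y) are position-specific — the row and column
marginals of the 4×4 junction count matrix — because pooled base frequencies
would be inconsistent with the 3:1 restriction. Genome profiles pool
junction counts over all genes before forming frequencies; the gene's own
junctions stay inside the genome profile (with hundreds to thousands of
genes the leave-one-out correction is far below the sampling noise of a
single gene's profile). A dinucleotide whose marginal frequency is zero has
ρ\* reported as 0.

σ is the mean of exactly 16 absolute ρ\* differences. Rank covariation uses
Spearman's ρ and Kendall's τ-b with average ranks for ties and the standard
large-sample two-sided p-values; n = 16 makes exact permutation tests
feasible only by Monte Carlo, and the large-sample approximation is accurate
enough at the 0.05 level used here. A constant signature (degenerate) yields
undefined coefficients, reported as missing. A seeded Monte Carlo
permutation p-value is available (`n_permutations`) for users who prefer a
distribution-free reference at n = 16.

### RSCU, χ², CAI

RSCU is computed over the 59 degenerate sense codons (61 sense − ATG − TGG)
of the standard code; the counts of each amino-acid family are normalised so
equal usage gives exactly 1. The genome reference table is *count-pooled*
across genes (a per-gene-mean alternative exists); pooling weights genes by
length, which is the natural estimate of genome-wide codon frequencies.

The gene-vs-genome χ² statistic apportions the gene's per-amino-acid totals
by the reference's within-family proportions and sums (obs − exp)²/exp over
cells with positive expectation. The reported degrees of freedom are fixed
at the code-table value 41 = 59 − 18 for every test, computed from the
genetic-code table at runtime rather than hard-coded; the effective df
(cells contributing minus families present) is emitted alongside because
short genes do not use all 18 families and the fixed-df p-value is then
conservative.

CAI = CAI_obs/CAI_max with both means taken over the gene's own codon
occurrences; CAI_max averages each occurrence's family-maximum reference
RSCU. Weighting CAI_max by the gene's amino-acid composition makes CAI = 1
exactly attainable by a gene using only most-frequent codons. Arithmetic
means are the default (the form matching the RSCU-ratio definition used
here); the classic geometric-mean variant is available (`mean="geometric"`,
with zero reference RSCU floored at 0.01 inside the logs), as is an
unweighted genome-level CAImax (`max_weighting="genome"`). The CAI flag
fires beyond 1.5 dispersion units from the genome mean; the genome CAI
dispersion is the per-gene SD, as for GC.

### Evidence aggregation

`screen_gene` runs the four lines and records, as evidence: the GC flag; a
*covariation* flag raised when the gene-genome rank correlation is negative
or not significant at α = 0.05 (significant positive covariation is the
native expectation); the χ² flag at α = 0.05; and the CAI flag. A stage
whose statistic is undefined is recorded as missing and contributes nothing.
The verdict mapping (0 → no_signature, 1–2 → weak, 3–4 → strong) is an
output convention — all raw statistics are always emitted.

A gene is *called* a candidate at ≥ 2 evidence lines
(`ScreenConfig.min_evidence_candidate`). Single-line calls are too leaky to
act on: the 1.5-SD CAI rule alone has a ~13% marginal rate under a normal
CAI distribution, and the union of the four single-line rates reaches
15–25% on null genes, which is why one flag is labelled only a "weak"
signature. Two concordant lines bring the null call rate to ~2% while
unameliorated transfers from a donor 15 GC3 points away are called with
sensitivity ≈ 0.9 (both measured by the acceptance suite).

## Reciprocal best hits

Hits are filtered at E ≤ 1e-5 and bitscore ≥ 50; the "full-length" criterion
is implemented as mutual alignment coverage ≥ 0.8 (alignment length over
each sequence length), active only when the 14-column tabular dialect
supplies lengths. Duplicate query–subject pairs keep the best-scoring hit.
Best hits maximise bitscore with ties broken by lower E-value, then
lexicographically smaller subject id, making output deterministic. A pair is
emitted iff each gene is the other's best surviving hit.

## Type-I functional divergence

Site counts are minimum substitution counts by Fitch small parsimony within
each cluster's subtree (clusters must be monophyletic in the supplied rooted
tree). Gap/unknown residues are missing data: the count is taken over the
induced subtree of non-missing leaves; sites missing in more than half of a
cluster are masked from the likelihood. Multifurcations are folded
pairwise.

The model: each site carries a rate λ ~ Gamma(a, b); substitution counts are
Poisson(λ·d_k) in cluster k with depths d₁ = d₂ = 1 by default (the overall
scale is absorbed into b; depths can be supplied when branch-length
information exists). With probability θ the two clusters draw independent
rates (a diverged site), otherwise they share one rate. Both marginals have
closed forms (negative-binomial type), so the likelihood is exact — no
quadrature at fit time; the test suite verifies the closed forms against
numerical integration to 1e-8.

Estimation maximises lnL over (θ, log a, log b) by bounded L-BFGS-B from a
deterministic 10-point multi-start grid (θ ∈ {0.05, 0.1, 0.5, 0.9} crossed
with a ∈ {0.5, 1, 2}, b initialised by moment matching); the null refits
(a, b) at θ = 0. The LRT 2ΔlnL is clipped at zero and referred to χ²(1).
Because θ = 0 lies on the boundary of [0, 1], the plain χ²(1) reference is
conservative — the true asymptotic null is the 50:50 mixture ½χ²₀ + ½χ²₁,
giving a rejection rate near 0.025 at nominal 0.05. The mixture correction
is available (`boundary_correction=True`) but off by default, plain χ²(1)
being the convention for this test. θ's standard error comes from the
inverse observed information (3×3 numeric Hessian); it is undefined (NaN)
at the boundary. Posteriors Q_k = θP₁P₁ / ((1−θ)P₀ + θP₁P₁) are evaluated
at the ML estimates and thresholded at 0.7 and 0.95 (the 0.95 list is
nested by construction).

Fewer than ~20 usable sites triggers a warning; θ is weakly identified
there. Type-II divergence (physicochemical shifts at ancestrally conserved
sites) is out of scope.

## Trait enrichment

For each categorical trait, each category with at least `min_count = 5`
in-family strains gets a one-vs-rest 2×2 Fisher exact test restricted to
strains with a non-missing value; sparser categories are marked not-tested
rather than tested-and-unreliable. Quantitative traits get the classic
pooled-variance two-sample t-test (df = n₁ + n₂ − 2). Headline p-values are
uncorrected; Bonferroni and Benjamini–Hochberg columns are emitted for
information only.

## Synthetic data: what it emulates and what it does not

`make_codon_model` builds a codon model in three parts: (i) uniform amino
acid frequencies over the 20 sense amino acids (overridable); (ii) within
each synonymous family, codon probabilities tilted as
exp(β·[third base ∈ {G,C}]) with β solved by bisection so the expected GC3
hits the target (`bias_strength` scales the solved tilt; 0 gives uniform
synonymous usage); (iii) a 4×4 junction-logit pattern — CG/TA suppression
with mild AA/TT/GC enrichment, plus a seed-dependent perturbation
(SD 0.35) — that reweights the joint (amino acid, codon) choice of each
codon given the previous codon's third base. The junction term is what
gives generated genomes a nontrivial 3:1 dinucleotide signature, and the
per-seed perturbation makes different models carry distinct signatures, the
way genomic signatures discriminate real organisms.

`generate_genome_with_transfers` draws gene lengths uniformly on 150–450
codons (mean ≈ 300, matching typical bacterial CDS) and samples each alien
codon from the host model with probability α (the amelioration degree) and
from the donor otherwise. Amelioration as a per-codon mixture is a single
interpretable knob standing in for the real process — a slow substitutional
decay toward host composition — and reproduces its observable consequence
(signal strength decreasing in α) without simulating time explicitly. Stop
codons are never generated, so output FASTA parses without warnings.

Default study conditions used by the analysis scripts and acceptance suite:
200 genes, 10 implanted aliens, host GC3 55%, donor GC3 70% (a 15-point
contrast, the scale seen between distantly related bacterial donors and
hosts), α = 0 for the detection scenario. The trait generator uses 1000
strains with 50 family members (roughly the family-to-survey proportion of
a genus-scale comparative study), five categorical traits modelled on
microbial organism-information categories, three null quantitative traits,
and one category planted at odds ratio 3.

What the generators do **not** emulate: operon and intergenic structure,
replication-strand skew, expression-driven codon-bias heterogeneity between
highly and lowly expressed genes, amino-acid composition differences between
donor and host (off by default so compositional contrasts are purely
synonymous — an `aa_freqs` override exists), and genuine substitution
processes on trees (the alignment-level divergence simulator realises
simulated counts on ladder subtrees and is documented as approximate).
Passing tests therefore demonstrate the statistical machinery under
controlled composition, not performance on real genomes, where
within-genome heterogeneity makes single-line flags even less reliable and
multi-line agreement correspondingly more important.

## Numerical choices

- Degenerate inputs raise rather than silently return: zero countable
  codons, zero dispersion, empty junction sets, all-zero site counts.
- Fisher tests on tables with an empty margin return p = 1 with a warning.
- Identical t-test groups return t = 0, p = 1 (the 0/0 limit).
- Optimiser tolerance is L-BFGS-B default on a bounded problem with log-scale
  shape/scale parameters clamped to [1e-4, 1e4]; the alternative fit is
  floored at the null fit (the models are nested, so lnL₁ < lnL₀ can only be
  numerical).
- All generators take integer seeds into `numpy.random.default_rng`; every
  output is byte-reproducible given the seed.

## Problem sizes

The test and acceptance suites run at deliberately moderate sizes chosen to
keep Monte Carlo error well inside the asserted bands: 120–200-gene genomes
for screening (10 seeds for operating characteristics), 1000 replicates of
L = 300 for the null LRT calibration and 50 replicates of L = 500 for θ
recovery, 50 + 30 seeds of 1000-strain trait tables for enrichment recovery
and null calibration, and exhaustive Fisher enumeration up to table total
40.
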