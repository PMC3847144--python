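# xenosig

Compositional "alien signature" screening for horizontal gene transfer (HGT)
in bacterial genomes, with the companion analyses a comparative-genomics
study of a patchily distributed gene family needs: reciprocal-best-hit
orthology, type-I functional divergence between protein subfamilies, and
phenotype enrichment — all exercisable end to end on synthetic genomes with
known ground truth.

## The scientific problem

A gene family found in a few scattered bacterial lineages can be explained
two ways: repeated horizontal transfer into those lineages, or an ancient
origin followed by repeated loss everywhere else. A recently transferred
gene betrays its foreign origin compositionally — it still looks like its
donor. `xenosig` implements the standard per-gene battery for that test,
comparing each candidate gene against all genes of its host genome:

1. **GC content by codon position** (GC1, GC2, GC3, GCt). A gene is flagged
   when its total GC deviates from the genome mean by ≥ 2 dispersion units,
   or when its GC1 and GC3 deviations share a sign and at least one reaches
   2 units. GC3 carries most of the signal because third positions are
   mostly synonymous.
2. **3:1 dinucleotide signature.** For the dinucleotide formed by a codon's
   third base and the next codon's first base — the least constrained
   context — the relative abundance ρ\*\_XY = f\_XY / (f\_X·f\_Y) over the 16
   dinucleotides is a genomic signature. Genes are compared to their genome
   by the σ difference (mean |Δρ\*| over the 16 values) and by Spearman/
   Kendall rank covariation; native genes covary positively, transferred
   genes need not.
3. **Codon usage (RSCU).** Relative synonymous codon usage
   RSCU_i = n·X_i / ΣX over each n-fold degenerate family (start, stop and
   Trp codons excluded), compared gene-vs-genome by a χ² test with
   41 = 59 − 18 degrees of freedom.
4. **Codon adaptation index.** CAI = CAI_obs / CAI_max, where CAI_obs is the
   gene's mean reference RSCU and CAI_max the mean attainable using only
   each amino acid's most frequent codon; deviations beyond 1.5 dispersion
   units from the genome mean are flagged.

Flags are aggregated per gene (0 → no signature, 1–2 → weak, 3–4 → strong);
a gene is called an HGT *candidate* when at least two independent lines
agree.

Around the screen, the package provides:

- **`orthology`** — best-reciprocal-hit ortholog pairs from all-against-all
  protein searches (E ≤ 1e-5, bitscore ≥ 50, mutual coverage ≥ 0.8).
- **`funcdiv`** — type-I functional divergence between two protein
  subfamilies: per-site minimum substitution counts (Fitch parsimony),
  maximum-likelihood estimation of the divergence coefficient θ ∈ [0, 1]
  under a two-state Poisson–gamma mixture, the LRT of θ = 0 against
  χ²(df = 1), and per-site posteriors Q_k with critical sites at
  Q_k > 0.7 / > 0.95.
- **`enrichment`** — Fisher exact tests (categorical traits) and pooled
  two-sample t-tests (quantitative traits) between family-containing and
  other strains.
- **`simulate`** — generators with ground truth: codon models with
  controlled GC3 and dinucleotide signatures, genomes with implanted donor
  genes and a tunable amelioration degree, two-cluster site counts under
  the divergence model, and trait tables with planted enrichment.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(outputs land in `results/`):

```sh
python analysis/01_simulate_genome.py --seed 1
python analysis/02_screen_hgt.py
python analysis/03_functional_divergence.py --seed 1
python analysis/04_trait_enrichment.py --seed 1
```

which prints (seed 1):

```
wrote 200 genes (10 alien) to results
alien gene ids: g007, g029, g050, g063, g091, g099, g146, g163, g185, g188
screened 200 genes; 11 HGT candidates
sensitivity on implanted aliens: 1.00
false-call rate on natives:      0.005
theta = 0.299 +- 0.059 (true 0.4); LRT = 61.44, p = 4.56e-15
critical sites: 22 at Q_k>0.7 (6 at Q_k>0.95); precision 0.86, recall 0.09
top hit: Habitat / Host-associated (p = 1.12e-02, family 24/50, others 285/950)
planted category (Habitat/Host-associated) recovered
```

All ten genes implanted from a GC3-70% donor into a GC3-55% host are
recovered as candidates (with one native false call among 190); the
functional-divergence fit detects rate-shifted sites decisively (LRT far
beyond the χ²(1) threshold) and the sites it names at Q_k > 0.7 are 86%
correct; the planted habitat enrichment is the scan's top hit.

The same operations are available as a CLI (`xenosig screen`, `xenosig rbh`,
`xenosig funcdiv`, `xenosig enrich`, `xenosig simulate ...`); run
`xenosig --help`.

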