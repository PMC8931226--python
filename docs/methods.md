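# Methods

This note documents the models and procedures implemented in `phoscycle`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data validation does and does not demonstrate.

## Trait model

Phosphonate biosynthesis is marked by a single gene, *pepM*
(phosphoenolpyruvate mutase), which catalyzes the initial C–P bond
formation. Because *pepM* homologs include non-functional relatives, a
producer call requires both an above-cutoff homology hit to the *pepM*
family **and** the catalytic motif EDK(X)₅NS — glutamate, aspartate,
lysine, five arbitrary residues, asparagine, serine, contiguous anywhere in
the protein — in the encoded protein. Downstream pathway genes (*ppd*,
*pdh*, *mpnS*) and cassette-associated glycosylation genes (*pglC*, *pglL*,
*wzx*) are recorded when adjacent to *pepM* (same contig, within 5 gene
ranks or 10 kb) but are never required: partial assemblies routinely break
cassettes across contigs, and a flag records biosynthesis genes found on
other contigs without changing the verdict.

Consumption requires co-occurring genes of one of four catabolic pathways
within a single 10-kb window on one contig:

| pathway | rule (default) |
|---|---|
| C–P lyase | *phnJ* plus ≥ 2 of *phnG,H,I,K,L,M* |
| 2-AEP (PhnWX) | *phnW* and *phnX* |
| PhnYZ | *phnY* and *phnZ* |
| phosphonatase | *phnX* (standalone above-cutoff hit accepted) |

Rules are `PathwayRule` objects, so stricter interpretations are a
configuration change, not a code change. The operon span used downstream
(`p` in the prevalence correction) is the gap-inclusive distance from the
first to the last cassette member on the *pepM* contig.

Homology scoring itself is out of scope: hit tables (query, family, score,
above-cutoff flag) are inputs. For synthetic genomes the generator emits
the hit table implied by its ground-truth family labels; for peptide reads
a deliberately simple shared amino-acid 5-mer scorer is built in, and
external aligner tables are accepted in its place.

## Completeness correction

Single-cell assemblies recover a fraction `c` of each genome, so a cassette
is visible only if its contig survived. With per-genome cassette span
`p_i` (0 if none detected), assembly length `g_i` and completeness `c_i`,
the corrected per-clade prevalence is

    (Σ p_i / Σ g_i) · Σ(g_i / c_i) · p̄⁻¹ · n⁻¹

with `p̄` the mean span over detected carriers and `n` the clade size. At
`c ≡ 1` this is algebraically the naive carrier fraction (fuzz-tested to
1e−12); lowering any `c_i` raises the estimate. The estimator is unbounded
above: values over 1 are reported with a flag, never clipped, since
clipping would hide miscalibration. Clades with fewer than two detected
carriers fall back to the global mean span with a warning. No completeness
cutoff is applied by default; a threshold argument exists for sensitivity
checks.

## Beta-binomial regression

Per-sample producer counts `y_i` of `m_i` genomes are modeled as
beta-binomial with mean `μ_i = logistic(x_iᵀβ)` and intra-class correlation
`ρ = φ/(1+φ)`; per-observation beta parameters follow `a_i = μ_i/φ`,
`b_i = (1−μ_i)/φ`, so `φ → 0` recovers the binomial and the variance is
`m μ(1−μ)(1+(m−1)ρ)`. `φ` is optimized on the log scale (equivalently a log
link on `ρ/(1−ρ)`).

Numerics: BFGS from a Newton–Raphson logistic warm start with three
jittered restarts. Because the log-`φ` parameterization cannot reach the
`φ = 0` boundary, a binomial-limit candidate (β re-optimized at the
numerical floor) is always evaluated and wins when its likelihood is at
least as high — without this the optimizer can stall just short of the
boundary. `fix_phi=0` fits the binomial submodel outright. Standard errors
come from the numerically differentiated observed information (β-block only
at the boundary, where the likelihood is flat in log `φ`); `t = Est/Err`
with two-sided p-values on `n − k − 1` residual degrees of freedom (the
dispersion counts as a parameter when free). For a 28-sample survey with
intercept, depth, basin and dispersion this gives df = 4, residual df = 24.

Validation: at fixed `φ = 0` the coefficients reproduce an independent IRLS
logistic fit to ≤ 1e−4; with `φ = 0.05` at the survey design scale
(28 samples × 241 genomes), 500 replicate fits recover a depth slope of
0.004 per meter with Wald-t 95% CI coverage within 0.95 ± 0.03. A −1.0
logit basin offset is recovered with the correct sign essentially always;
its Wald power at this design size is ≈ 0.87 (the per-group standard error
under variance inflation 1+(m−1)ρ ≈ 12.4 is ≈ 0.3), so significance is
reached in the large majority, not ≥ 90%, of surveys.

## Metagenome profiling

Reads are peptides (six-frame translation of nucleotide reads is out of
scope). "Reciprocal best hit" is operationalized for short reads as
**best-hit-with-decoys**: a read belongs to family F iff its single best
reference over targets ∪ decoys is F's and the score clears F's cutoff;
ties break lexicographically. True bidirectional search is ill-defined at
read length, and the decoy competition supplies the specificity the reverse
search would.

The per-genome unit comes from ten single-copy marker families: producer
fraction = (pepM count / pepM length) / median over the ten markers of
(count / length). The ratio is a rational identity in the counts, hence
exactly invariant to sequencing depth; the even-count median is the mean of
the two central values, and absent markers contribute zero. Fractions above
100% (multi-copy artifacts, noise) are flagged, not capped.

## Tree discordance (Mutual Clustering Information)

Each nontrivial split of an unrooted tree is a two-class leaf clustering.
For a split pair (one per tree) the shared information is the mutual
information of the 2×2 joint leaf-count table, in bits; the score of a tree
pair is the maximum total over injective split matchings, solved as a
rectangular linear assignment problem with pair scores below 1e−12 zeroed
so noise is never matched. The normalized distance is
`1 − shared / mean(H₁, H₂)` where `H_k` is a tree's total split entropy —
the arithmetic-mean normalizer is one of the standard choices and is stated
in the output so alternatives remain comparable. Identical trees give 0;
conflicting quartets give 1. Leaf-set mismatches are pruned to the
intersection (count logged), never an error, since gene presence/absence
differs between trees by the premise of the analysis.

The null model is the uniform random binary topology, generated by
sequential random pairwise joining (verified uniform on 4- and 5-leaf
trees). Horizontal transfer is emulated by subtree-prune–regraft (SPR)
moves: a 20-move gene tree versus 1-move "conserved" trees on 32 leaves
yields a gene/conserved distance ratio above 2 in ≥ 90% of replicates,
with the gene tree inside the random baseline's range.

## ³¹P spectra

Spectra are sums of Lorentzians `A·(γ/π)/((x−c)² + γ²)` (area `A`,
half-width γ, default 0.3 ppm) plus Gaussian noise, on an ascending-ppm
axis; descending instrument-convention input is auto-reversed. Region
integrals are trapezoidal over phosphonate esters (18–27 ppm) and pooled
phosphate/pyrophosphate esters (−12 to 12 ppm); pyrophosphate is not
separated. Two baseline modes are reported: none, and linear-endpoints
(the line through the mean of the 5 points flanking each boundary). The
endpoint baseline also removes the true peak-tail level at the region
edges — a known, small negative bias (~4% for a γ=0.3 peak centered 1 ppm
inside the region) that both modes being reported makes visible. A
diagnostic 14–20 ppm region (cyclic-phosphate ambiguity) can be added
without altering the standard regions; the pre/post base-hydrolysis
comparison flags any region changing by more than 10% relative (default).

Allocation fraction = ratio/(1+ratio): 0.72 → 0.419 (≈ 40%), 2.4 → 0.706.

## Budget arithmetic

Per-group phosphonate-P stock = cells × producer fraction × P quota ×
phosphonate share of cellular P, in mol (also reported in Tg). Inventories
are either a direct cell count or density × volume — a density without an
explicit volume is a hard error. Shares require an explicit denominator or
"sum" mode (total exactly 100%); no default global denominator is shipped
because its derivation needs inputs beyond this package's scope. The SAR11
reference scenario (9.9×10²⁶ producer cells, 0.16×10⁻¹⁶ mol P/cell, 10%
phosphonate share) gives 1.584×10⁹ mol phosphonate-P; stock is exactly
linear in each factor, which `sensitivity` exposes over parameter grids.

## Synthetic data: what it does and does not show

The generator emulates: single-cell collections with clade-structured trait
frequencies and contiguous planted cassettes; assembly incompleteness as
whole-contig dropout (SAG assembly loss is contig-grained), making cassette
survival Bernoulli(completeness) because cassettes are placed uniformly;
motif-less *pepM* decoys to exercise rejection; error-free peptide reads
drawn ∝ abundance × reference length; beta-binomial trait counts over a
logit-linear depth/basin field (28 samples × 241 genomes by default, the
survey's design scale); Lorentzian spectra with configured areas.

It does **not** emulate: sequencing error or chimeric assembly, real
homolog sequence divergence (proteins are random strings with or without
the motif, so classifier accuracy here bounds nothing about real HMM
sensitivity), taxonomy beyond clade labels, genuine phylogenetic signal
(trees are random topologies plus SPR moves), or NMR phasing/baseline-roll
artifacts. Passing tests therefore validate the *estimators and their
bias corrections* — not the upstream homology search, whose cutoffs must be
recalibrated on real data.

Problem sizes used by the tests and the acceptance script — 2,000 genomes
for prevalence recovery, 100,000 reads for the metagenome estimator, 500
replicate regression fits, 100 tree replicates — were chosen as the
smallest sizes at which sampling error is well inside each check's
tolerance.

## Known limitations

- The trait caller trusts the hit table; it has no notion of score
  calibration across families.
- The corrected-prevalence estimator assumes cassette loss is driven by
  assembly incompleteness alone (no assembly bias against cassette loci).
- The beta-binomial Wald intervals are first-order; near-boundary `φ̂` or
  small samples would warrant profile-likelihood intervals.
- Marker-median normalization presumes the ten markers are genuinely
  single-copy in the taxon scope; multi-copy contamination inflates the
  denominator.
- The MCI distance compares topologies only; branch lengths and support
  values are ignored.
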