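# Methods

This note records the models, parameter choices and numerical decisions
behind each stage of the pipeline, and what the synthetic-data generator
does and does not emulate.

## Synthetic study model

The generator (`tribescan.synthetic_data`) produces every input the
analyses consume. Its defaults describe the emulated study: a cohort of
**15 diploid samples** genotyped at **5,000 biallelic SNPs**, compared
against **four continental panels of 100 diploids each** (AFR, AMR, ASN,
EUR; allele-count denominators 2 × sample size, constant across SNPs).

- **Ancestral frequencies** are Beta(1, 3) draws clamped to [0.01, 0.99]
  — a spectrum skewed toward low-frequency alleles, as in real site
  frequency spectra, without attempting to match any specific demography.
- **Panel frequencies** are Balding–Nichols draws around the ancestral
  frequency: p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with dispersion
  **F = 0.005**. The scan's binomial null takes the panel frequency as the
  cohort's null frequency, so the generator's null condition must keep
  panel frequencies close to the shared ancestral frequency; F is
  therefore kept small — a perturbation, not the differentiation signal.
  Differentiation is injected explicitly instead:
- **Planted markers**: a configurable fraction of SNPs (0 by default; 0.10
  in the mixed simulations) have the study frequency shifted additively by
  `planted_shift` (0.4 default), directed away from the nearer frequency
  boundary and clamped to [0.01, 0.99]. The truth table records them.
- **Genotypes** are i.i.d. Hardy–Weinberg draws (dosage ~ Binomial(2, p))
  with 1% missingness; study allele counts are taken over non-missing
  alleles only.
- **Reference catalog**: each site included independently with probability
  0.92 (a dbSNP-like coverage level); optionally the recorded allele set
  omits the observed alternate allele at a configurable fraction of sites,
  exercising the allele-subset novelty rule.
- **SV call sets**: 300 true events (DEL/DUP/INV) with lengths drawn from
  three regimes (300–400 bp, 6–7 kb, 500 bp–5 kb — echoing the
  short-interspersed- and long-interspersed-element deletion modes); four
  pseudo-callers each report an event with probability 0.9 and jitter both
  endpoints uniformly in ±30 bp. With ≤10% jitter relative to length, all
  same-event call pairs retain reciprocal overlap ≥ 0.5 by construction.
- **Sequences** evolve along a user-supplied tree under the Kimura
  two-parameter model (transition/transversion rate ratio κ = 2), matching
  the K2P distance used downstream. Branch lengths are expected
  substitutions per site; the per-branch substitution probabilities use
  the closed-form K2P transition matrix.

Everything is a pure function of (config, seed).

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs (every
SNP is independent, so the effective number of tests is the nominal one),
shared demographic history between the cohort and the panels (the binomial
null is exactly correct here up to drift F, whereas real cohort-vs-panel
comparisons violate it through relatedness and ancestry structure),
sequencing/genotyping error, allele-frequency-dependent missingness, and
read-level artifacts in SV calls.

## Differentiation scan

- **F_ST**: two-population Weir–Cockerham variance-components estimator in
  its sample-frequency form (the panel provides frequencies, not
  genotypes): MSP = Σ nᵢ(pᵢ − p̄)², MSG = Σ nᵢpᵢ(1−pᵢ) / Σ(nᵢ−1),
  n_c = n − Σnᵢ²/n, F_ST = (MSP − MSG)/(MSP + (n_c−1)MSG). Negative
  estimates are reported raw by default (a clamp is available); a SNP
  monomorphic for the same allele in both populations yields 0 (no
  variance to partition). Denominators below 2 alleles are rejected.
- **Binomial two-one-sided test**: p_upper = P(X ≥ k), p_lower = P(X ≤ k)
  under Binomial(n, p₀), combined as min(1, 2·min(p_lower, p_upper)).
  Both tails include P(X = k), so p_lower + p_upper ≥ 1; the doubled-tail
  combination is conservative for discrete nulls. Degenerate p₀ ∈ {0, 1}
  is handled exactly.
- **FDR**: Benjamini–Hochberg step-up with monotonicity enforcement
  (equivalent to Storey's q-values at π₀ = 1) is the default, one family
  per comparison population; Storey's λ-smoother π₀ estimate (median over
  λ ∈ {0.05, …, 0.90}, capped at 1) is behind a switch. BH was chosen as
  the default because it never anti-conservatively undercuts the plain
  step-up and keeps the two-tail combination's FDR semantics; with one
  combined p-value per marker there is a single list per population.
- **Allele harmonization**: the cohort's alternate allele is fixed as the
  tested allele; a panel frequency reported for the cohort's reference
  allele is complemented; markers whose panel allele matches neither
  cohort allele are dropped and logged. Only markers covered by every
  comparison population enter the test families. Triallelic SNPs are
  excluded (the estimator and the null are biallelic).
- **Thresholds**: F_ST ≥ 0.25 and q ≤ 0.05, both configurable. The Venn
  partition groups significant markers by the subset of populations
  involved; the headline set requires significance against all.

## Phylogenetics

- **Shared-variant distance**: D = (N_s − shared)/N_s over (chrom, pos)
  keys. Allele-agnostic by design; ties in set size are harmless (the
  formula is symmetric under ties). An empty smaller set is an error; a
  contig with an empty set for any genome is skipped with a warning.
  D is a premetric (nonnegative, zero on self, symmetric); the triangle
  inequality is not implied and not asserted.
- **Disease-gene restriction**: for each pair, locations kept iff flagged
  and present in either genome; distances are genome-wide (not
  per-autosome), with bootstrap over the flagged locations — the
  restricted sets are small enough that per-autosome matrices would often
  be empty, and resampling locations propagates that sparsity into the
  supports honestly. This is configurable in the analysis driver.
- **K2P distance**: d = −½ln(1−2P−Q) − ¼ln(1−2Q) with pairwise deletion
  of non-ACGT sites. Saturated pairs (log argument ≤ 0) return a
  configured large value (default 10) with a warning rather than raising,
  so one bad replicate cannot abort a bootstrap.
- **Neighbor joining**: Saitou–Nei with the Q-criterion; ties broken by
  the lowest (row, column) index pair so results are deterministic for a
  given label order (and empirically invariant to label order up to
  relabeling); negative branch lengths are retained. The returned tree is
  unrooted (basal trifurcation); the final three lineages use the
  three-point formulas.
- **Consensus**: majority-rule extended, as in PHYLIP's Consense default —
  all bipartitions above 50%, then remaining bipartitions in decreasing
  frequency order when compatible with everything already included (ties
  broken lexicographically); support is the occurrence count (autosomes or
  replicates). Bipartitions are keyed by the side excluding the
  lexicographically smallest leaf.
- **Bootstrap**: column resampling with replacement; each replicate tree
  has zero-length internal edges collapsed before consensus, since NJ
  resolves exact ties arbitrarily and such edges carry no grouping signal.

## Cataloguing

- Known/novel: novel iff site absent from the catalog or observed
  alternate alleles ⊄ catalogued alleles; monotone in catalog growth.
- Annotation classes: per-transcript effects reduced by precedence
  Coding,Splicing > Coding > Splicing > UTR (3′,5′ combination, then 5′,
  then 3′) > NCSplicing > NCExonic > Intronic > Downstream,Upstream
  combination > Upstream > Downstream > Intergenic. Up/downstream windows
  are 1,000 bp from the strand-aware transcript start/stop; the splice
  window is 2 bp beyond each internal exon boundary (the canonical splice
  dinucleotides). Combination labels require two distinct transcripts
  contributing both effects with nothing higher applying. Variants on
  contigs absent from the gene models are Intergenic.
- Ti:Tv is computed on the union variant set (not per-sample averaged),
  over biallelic SNPs; no transversions yields NaN with a warning.
- MAF bins are closed on the left (<5%, 5–10%, >10% by default); MAF uses
  non-missing allele counts; all-missing sites are excluded and tallied.
  Stratum means are compared by Welch's unequal-variance t-test.
- The Mantel test permutes row/column labels of one matrix simultaneously;
  p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), default 9,999 permutations,
  seeded. Deleteriousness is consumed as an input flag (the
  damaging-prediction OR rule applied upstream), never predicted here.

## SV merging

Single-linkage merging (connected components of the reciprocal-overlap
graph at t = 0.5) was chosen because pairwise merge rules do not define
multi-call behavior; it matches chained interval merging, and a strict
clique mode is available. Same type and chromosome are required. Point-like
insertions merge by breakpoint distance (default window 100 bp), and
translocations require both breakpoints (including the partner locus) to
match within the window — interval overlap is meaningless for them.
Known/novel for deletions uses the one-directional ≥ 50% covered-fraction
rule against the catalog, with overlaps unioned before measuring, which
makes the classification monotone in catalog growth.

## Saturation

Accumulation curves use 48 random sample-addition orders (mean ± sd), with
variants keyed by (site, alternate allele) so a new allele at a known site
counts as discovery. The "power series" is the two-parameter law y = c·xᵏ,
fitted by nonlinear least squares initialized from the log–log regression,
with R² on the original scale. The fit is exact on noiseless power-law
input and idempotent on its own predictions.

## Problem sizes and tolerances

The simulations used by the test suite and `scripts/acceptance.py` run at
the study scale stated above (5,000 SNPs × 15 samples × 4 panels; 50 seeds
for the calibration and FDR summaries; 100-replicate bootstraps on 2,000 bp
alignments; ~2,000 jittered SV calls), which keeps the whole verification
under a few minutes on one core. Oracle-agreement checks (F_ST arithmetic,
binomial tails) are asserted to 1e-12; stochastic checks use 3-standard-
error bands around their analytic expectations.

## Known limitations

Single-linkage SV clusters can chain across events closer than half their
length; the generator spaces events far apart, so synthetic truth recovery
does not probe that regime. The Storey π₀ option is a plain λ-median
smoother, not the spline estimator. The consensus tree carries supports but
no branch lengths. The scan assumes panel frequencies are estimated from
many more alleles than the cohort's; with very small panels the binomial
null (which ignores panel sampling noise) becomes anticonservative.
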