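# Methods

This note documents the statistical models implemented in `annofine`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Distinct association signals

Loci are intervals of ± `window_bp` (default 500,000 bp) around each lead
variant with p < 5×10⁻⁸, merged per chromosome when they overlap or abut,
and clipped at position 1. Within a locus, distinct signals come from greedy
stepwise selection on reconstructed joint models.

**Joint-model reconstruction.** Only marginal statistics are observed; the
joint regression is rebuilt from sufficient statistics. For model variants
with marginal effect bⱼ, standard error seⱼ, sample size Nⱼ and reference
dosage variance vⱼ:

```
SSxⱼ  = Nⱼ vⱼ                         genotype sum of squares
X'yⱼ  = SSxⱼ bⱼ                       implied cross-product
X'Xⱼₖ = rⱼₖ √(SSxⱼ SSxₖ)              reference LD
SSy   = medianⱼ SSxⱼ (bⱼ² + (Nⱼ−2) seⱼ²)
```

Joint coefficients are (X'X)⁻¹X'y, with covariance
σ̂² (X'X)⁻¹ where σ̂² = (SSy − B'X'y)/(N − m − 1) and N is the median
per-variant sample size. The median-based SSy makes the implied phenotypic
variance robust to per-variant N heterogeneity. When the marginal statistics
and LD derive from the same genotype sample, this algebra reproduces
full-data least squares to numerical precision — the property the test
suite asserts at 10⁻⁶ relative against an OLS oracle.

**Selection.** The locus' smallest-p variant seeds the model; at each step
the variant with the smallest conditional p < `p_enter` (default 5×10⁻⁸)
enters, after which any selected variant whose joint p rises above the
threshold is dropped (backward step). Variants with |r| ≥ √0.9 against the
model are rejected (collinearity cap r² = 0.9, a GCTA-COJO-class default),
and a MAF floor of 0.01 stabilises the scaled LD matrix. Both are
configurable; the upstream tools' exact settings are not published, so
these are package defaults. Signals are labelled `locus_ordinal` by entry
order. Conditional summary statistics for secondary signals reuse the same
algebra: each candidate variant is added alone to the conditioning set and
its joint coefficient reported.

## Annotation enrichment

With at most one causal variant per block, a block is causal with
probability Π and, within a causal block, variant j is causal with weight
wⱼ ∝ exp(Σₖ βₖ zⱼₖ). Marginalising the configuration gives the block
likelihood ratio (1 − Π) + Π Σⱼ wⱼ Λⱼ, where Λⱼ is the variant's Wakefield
approximate Bayes factor

```
ln Λ = ½ ln(V/(V+W)) + z² W / (2 (V+W)),   V = se², z = beta/se.
```

`W` defaults to 0.04 (prior standard deviation 0.2 on the standardised
effect), the conventional choice; it is a parameter everywhere. The summed
log-likelihood is maximised by L-BFGS-B on (logit Π, β) from (logit 0.01, 0)
with a 10⁻¹² function tolerance; per-coefficient 95% intervals come from the
profile likelihood (drop of χ²₀.₉₅,₁/2, solved by bracketed bisection). An
annotation that is constant within every block cancels from the weights and
raises an identifiability error.

**Forward selection.** Annotations enter one at a time, each step taking
the candidate that maximises the joint log-likelihood and accepting it only
if the 1-df likelihood-ratio p-value is below α/K (Bonferroni over the K
annotations tested; K = 253 at α = 0.05 gives p < 0.00020). Ties break by
annotation name for determinism. The stopping rule operationalises
"penalised likelihood" as the explicit Bonferroni LRT stop — the only
quantitative rule stated for the analysis this follows; fGWAS's
cross-validated penalty path is out of scope.

## Fine-mapping

Each signal is assumed to contain exactly one causal variant among the
locus variants assigned to it (the same assumption the block model makes).
The posterior is πᵢⱼ = γⱼΛᵢⱼ / Σₗ γₗΛᵢₗ with γⱼ = exp(Σₖ β̂ₖ zⱼₖ);
secondary signals use conditional rather than marginal statistics when
computing Λ. Everything is computed in log space — ln Λ routinely exceeds
700, far past double overflow in linear space. Posteriors are normalised
over all variants of the locus assigned to the signal (locus-wide
normalisation; whether a sub-window is used upstream is unstated, so the
simpler convention is the default). Variants absent from the annotation
matrix receive γ = 1 with a logged count.

The 99% credible set is the minimal prefix of the descending-π ranking
whose cumulative posterior reaches the level; ties break by (position,
variant id). Because the ranking is by posterior mass, the prefix is also
the smallest subset reaching the level — the test suite checks this against
a brute-force subset search on signals of ≤ 10 variants. A signal is
high-confidence when its top posterior strictly exceeds 0.75.

Under the multivariate-normal model of marginal z-scores (z ~ N(R·ncp, R)),
the likelihood ratio for "variant j causal" depends on zⱼ alone, so
single-causal fine-mapping with Wakefield factors is exactly Bayesian when
W matches the causal-effect prior — which is why the simulated 99% sets
attain ≥ 99% coverage (the acceptance suite measures this at 1,000
signals with a ≥ 97% pass bound to absorb binomial noise).

## Colocalisation

Colocalisation with a gene-tissue QTL dataset is *triggered* only when the
QTL's lead significant variant (smallest p below a supplied threshold,
default 5×10⁻⁸) is a member of the signal's 99% credible set, mirroring the
lead-QTL lookup that precedes the formal test. The test enumerates the five
single-causal hypotheses over shared variants with the standard priors
p1 = p2 = 10⁻⁴ (single-trait causal) and p12 = 10⁻⁵ (shared causal) —
field-standard values, configurable because the original analysis does not
print its own. The trait side uses the annotation-informed Bayes factors
γⱼΛⱼ restricted to credible-set members (falling back to the signal's full
ranking when the set is a singleton, since the test needs ≥ 2 shared
variants); the QTL side uses annotation-blind Wakefield factors. "Convincing
support" is PP(H4) ≥ 0.8, flagged in the output and configurable. All sums
are log-space; S1·S2 − S12 ≥ 0 holds identically (cross-terms), and the
log-difference is guarded against cancellation.

## Consequence filtering

VEP-style tables are consumed, never generated. PolyPhen and SIFT strings
are normalised case-insensitively with or without scores in parentheses.
"Damaging" means PolyPhen probably- or possibly-damaging; "deleterious"
means SIFT deleterious with low-confidence calls excluded — the reading
under which the packaged 22-variant worked example splits 7 = 4 + 3 exactly.
A variant with unknown PolyPhen and missing SIFT counts in no
deleteriousness class.

## Hi-C target mapping

Interactions arrive pre-called (bias- and distance-corrected upstream);
anchor 1 is the distal fragment and anchor 2 the promoter fragment of a
named gene. A credible-set variant hits a gene when it is non-coding, meets
an optional posterior floor (default 0 — all members count, a permissive
choice logged as such because the upstream criterion is unstated), and its
0-based position falls in the half-open distal anchor. Variants inside the
promoter anchor itself do not count by default. Hits aggregate to
(signal, gene) with tissue sets, independent of input row order.

## Evidence integration

A gene is a candidate effector gene when any core line supports it:
high-confidence missense, eQTL colocalisation, pQTL colocalisation, or a
Hi-C hit. Mouse/human-phenotype and differential-expression evidence is
ingested from a user-supplied table only (those lookups are manual
curation, never fetched). The "additional functional evidence" tier is
candidate AND (mouse OR human phenotype) AND differential expression.
Percentages are recomputed from raw counts and rounded to one decimal, half
away from zero — the convention that reproduces 90/442 → 20.4% and
74/262 → 28.2%. Gene-set enrichment is a hypergeometric upper tail per set
with Benjamini–Hochberg adjustment across sets.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:

* **LD** — haplotypes are thresholded latent AR(1) Gaussians; one allele
  frequency per block (drawn from `maf_range`, default 0.05–0.5) and a
  tetrachoric calibration make the *adjacent-variant allele correlation*
  equal the requested `rho` (default 0.9). Blocks are independent. The
  shared per-block frequency is a deliberate simplification: with unequal
  frequencies a binary pair cannot reach high correlation, and a single
  tunable adjacent-r is the property the tests need.
* **Causal architecture** — each block causal with probability
  `block_prior`; within a block, placement probability ∝ exp(Σ true_beta·z),
  the generative inverse of the fine-mapping prior; at most one causal per
  block, matching the enrichment model. Effects are N(0, effect_sd²) in
  trait units per allele.
* **Summary statistics** — genotype mode simulates a phenotype with
  unit-variance noise on the panel and runs per-variant OLS; direct mode
  draws block z-scores from N(R·ncp, R) with ncp = √n·β·sd(dosage) and
  converts via SE = 1/√(2f(1−f)n), the standard large-sample approximation
  that keeps the two modes comparable (the tests verify the causal z-score
  means agree). Non-positive-definite R is repaired by eigenvalue clipping
  with a warning.
* **QTLs** — shared (same causal, independent effect), distinct (causal on
  the farthest variant of the block, minimising LD with the GWAS causal) and
  null scenarios per gene-tissue.
* **Hi-C** — deterministic promoter/distal anchor pairs at a configurable
  bin size per gene and tissue.

Default study conditions: GWAS n = 40,000, reference panel n = 1,000,
blocks of 20 variants, adjacent r = 0.9, effect sd 0.15 per allele (about
0.1 trait-SD after standardisation). Calibration experiments use effect sd
0.02–0.03 so credible sets are non-trivial in size; enrichment-recovery
experiments use 2,000 blocks with annotation coverage 0.2 and log-fold
enrichment ln 4.

Not emulated: realistic human LD maps (block-AR(1) only), imputation
uncertainty, rare-variant architectures, binary traits, per-variant
frequency variation within a block, sample overlap between GWAS and QTL
datasets. Passing tests therefore demonstrate correctness of the algebra and
calibration under the model's own assumptions — not robustness to LD-panel
mismatch or trait misspecification on real data.

## Numerical choices and degenerate inputs

* Log-sum-exp throughout fine-mapping, enrichment and colocalisation.
* Optimiser: L-BFGS-B on (logit Π, β), tolerance 10⁻¹² on the objective.
* Monomorphic simulated blocks are redrawn up to 10 times, then raise.
* Summary-statistics rows violating row invariants (se ≤ 0, eaf ∉ (0,1),
  invalid p) are dropped with a logged count; duplicate (chrom, pos,
  alleles) keys raise.
* Harmonisation drops strand-ambiguous A/T and C/G pairs with eaf in
  (0.4, 0.6) and any variant whose frequency disagrees with the panel by
  more than 0.2 (reference-mismatch guard).
* Internal coordinates are 1-based inclusive; BED/BEDPE convert at the
  boundary, and the boundary cases are unit-tested in both directions.
* Ties: credible-set ranking by (−posterior, position, id); forward
  selection by annotation name; Hi-C output sorted by (signal, gene).

## Problem sizes

The test suite and acceptance script use scaled simulation sizes chosen to
make the statistical assertions sharp while staying quick on one CPU:
1,000 signals for coverage, 2,000 blocks × 100 (tests) or 40 (script)
replicates for enrichment recovery, 100–200 replicates for the
colocalisation scenarios and stepwise recovery, and exhaustive brute-force
oracles only on signals of ≤ 10 variants.

## Known limitations

* One causal variant per signal; allelic series within a signal are split
  by conditioning, not modelled jointly (no SuSiE-style multi-causal sets).
* The enrichment model ignores LD within blocks (as fGWAS does); strong LD
  between annotated and unannotated variants dilutes β̂ toward zero.
* Colocalisation assumes a single causal per trait per region and shared
  variant coverage between datasets.
* The joint-model algebra inherits COJO's sensitivity to LD-reference
  mismatch; the frequency guard catches gross errors only.
* Cross-ancestry fine-mapping is out of scope by design.
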