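# annofine

Annotation-informed fine-mapping and effector-gene prioritisation for GWAS
summary statistics, built around the analysis style used for large
quantitative-trait studies such as resting heart rate (RHR) in UK Biobank.

Genome-wide association studies report hundreds of loci for traits like
resting heart rate, but each locus typically contains dozens of variants in
linkage disequilibrium (LD) and the causal variant — and the gene it acts
through — is usually unknown. `annofine` implements the statistical pipeline
that narrows a locus down to a credible set of causal candidates and then to
candidate *effector genes*:

1. **Distinct signals** — loci are defined as ±500 kb windows around
   genome-wide-significant leads (merged when they overlap) and split into
   independent association signals by stepwise conditional analysis on
   summary statistics with a reference LD panel (conditional-and-joint,
   COJO-style, algebra).
2. **Annotation enrichment** — a block hierarchical model estimates the
   log-fold enrichment β̂ₖ of association signals in genomic annotations,
   selecting a joint model by forward selection under a Bonferroni-corrected
   likelihood-ratio stop (for 253 annotations at α = 0.05, p < 0.00020).
3. **Fine-mapping** — each variant j of signal i receives an
   annotation-informed prior γⱼ = exp(Σₖ β̂ₖ zⱼₖ) and a Wakefield approximate
   Bayes factor Λᵢⱼ, with ln Λ = ½ ln(V/(V+W)) + z²W/(2(V+W)); the posterior
   probability of causality is πᵢⱼ ∝ γⱼ Λᵢⱼ. Ranking variants by πᵢⱼ and
   accumulating to 99% gives the credible set; a signal is *high-confidence*
   when one variant carries > 75% of the posterior.
4. **Evidence lines** — credible sets are joined to consequence predictions
   (missense, PolyPhen/SIFT), colocalised with eQTL/pQTL summary statistics
   (five-hypothesis Bayesian colocalisation of the annotation-informed Bayes
   factors, triggered by a lead-QTL lookup in the credible set), and mapped
   to target genes through pre-called promoter-capture Hi-C interactions.
5. **Prioritisation** — genes with at least one line of evidence become
   candidate effector genes; summaries and a hypergeometric gene-set
   enrichment (Benjamini–Hochberg across sets) follow.

A first-class synthetic-data module (`annofine.simulate`) generates LD
panels, annotation-tilted causal architectures, LD-consistent GWAS and
cis-QTL summary statistics and Hi-C fixtures with known ground truth, so the
whole pipeline is testable offline.

## Worked example

The `examples/` directory contains one short script per capability. For
instance, `examples/02_annotation_enrichment.py` simulates 2,000 LD blocks in
which causal variants are four-fold enriched in one of four annotations,
then recovers the enrichment by forward selection:

```
Bonferroni stop for 4 annotations at alpha 0.05: p < 0.013
selected annotations: ['ann0']
  ann0: log-fold enrichment 1.351 (95% CI 1.196 to 1.507); truth ln 4 = 1.386
block prior estimate: 0.482 (truth 0.5)
```

Only the truly enriched annotation enters the joint model; its estimated
log-fold enrichment sits near the simulated ln 4 with the profile-likelihood
interval covering it, and the estimated probability that a block harbours a
causal variant matches the generating value. `examples/01_simulate_and_finemap.py`
runs the signal-detection and fine-mapping steps end to end:

```
2 loci from 6 genome-wide-significant leads
signal 1_1: index rs3_15 (joint p = 5.57e-16), 99% set of 1 variants, top posterior 0.999, high-confidence: True, true causal ['rs3_15'] IN set
signal 2_1: index rs4_15 (joint p = 2.49e-08), 99% set of 3 variants, top posterior 0.915, high-confidence: True, true causal ['rs4_15'] IN set
```

`examples/04_effector_genes.py` walks the packaged table of 22
high-confidence RHR missense variants (22 variants in 21 genes, 7 of them
damaging by PolyPhen and deleterious by SIFT) through evidence integration.

## Layout

```
src/annofine/
  io.py           summary-stats/BED readers, allele harmonisation, LD panel
  simulate.py     synthetic panels, architectures, GWAS/QTL stats, Hi-C fixtures
  signals.py      locus definition, joint/conditional models, stepwise selection
  enrichment.py   Wakefield ABFs, block likelihood, forward selection
  finemap.py      annotation-informed posteriors, 99% credible sets
  coloc.py        lead-QTL trigger and five-hypothesis colocalisation
  consequence.py  PolyPhen/SIFT parsing and missense filtering
  hic.py          promoter-capture interaction target mapping
  prioritise.py   evidence matrix, summaries, gene-set enrichment
```

See `docs/methods.md` for the model details, default parameters and the
design decisions behind them.
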