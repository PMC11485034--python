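"""Estimate annotation log-fold enrichment by forward selection.

Simulates 2,000 LD blocks where causal variants preferentially land in the
first of four annotations (true log-fold enrichment ln 4 = 1.386), computes
Wakefield Bayes factors, and selects a joint enrichment model under the
Bonferroni-corrected likelihood-ratio stop.
"""

import numpy as np

import annofine as af

cfg = af.SimConfig(
    seed=3, n_blocks=2000, n_variants=8, rho=0.0,
    n_annotations=4, annotation_coverage=0.2,
    true_beta=(np.log(4), 0.0, 0.0, 0.0),
    block_prior=0.5, effect_sd=0.15, gwas_n=40_000,
)
panel = af.analytic_panel(cfg)
ann = af.simulate_annotations(cfg, panel, seed=21)
truth = af.simulate_causal_architecture(cfg, ann, panel, seed=22)
sumstats = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=23)

ln_bf = af.wakefield_abf(sumstats["beta"].to_numpy(), sumstats["se"].to_numpy(), 0.04)
blocks = panel.variants["block"].to_numpy()

print(f"Bonferroni stop for {cfg.n_annotations} annotations at alpha 0.05: "
      f"p < {af.bonferroni_threshold(0.05, cfg.n_annotations):.2g}")
model = af.forward_select(ln_bf, blocks, ann, alpha=0.05)
print(f"selected annotations: {model.selected}")
for name, beta, (lo, hi) in zip(model.selected, model.beta_hat, model.ci95):
    print(f"  {name}: log-fold enrichment {beta:.3f} (95% CI {lo:.3f} to {hi:.3f}); "
          f"truth ln 4 = {np.log(4):.3f}")
print(f"block prior estimate: {model.block_prior_hat:.3f} (truth {cfg.block_prior})")

# Only the truly enriched annotation should enter the joint model; its
# estimate should sit near ln 4 with the 95% interval covering the truth.
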