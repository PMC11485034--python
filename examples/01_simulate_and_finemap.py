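"""Simulate a small GWAS, find distinct signals, and fine-map them.

Builds a 5-block LD reference with one annotation, plants causal variants,
draws marginal summary statistics, then runs locus definition, stepwise
conditional selection and annotation-informed fine-mapping.
"""

import numpy as np
import pandas as pd

import annofine as af

cfg = af.SimConfig(
    seed=1, n_blocks=5, n_variants=20, rho=0.9, block_prior=1.0,
    n_annotations=1, annotation_coverage=0.2, true_beta=(np.log(4),),
    effect_sd=0.1, gwas_n=40_000,
)
panel = af.analytic_panel(cfg)
ann = af.simulate_annotations(cfg, panel)
truth = af.simulate_causal_architecture(cfg, ann, panel)
sumstats = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct")

leads = sumstats[sumstats["pvalue"] < 5e-8].nsmallest(10, "pvalue")
loci = af.define_loci(leads[["variant_id", "chrom", "pos", "pvalue"]])
print(f"{len(loci)} loci from {len(leads)} genome-wide-significant leads")

for locus in loci:
    for signal in af.stepwise_select(sumstats, panel, locus):
        sub = af.signals.locus_variants(sumstats, locus)
        cs = af.fine_map_signal(signal.signal_id, sub, ann, model=None,
                                prior_var=cfg.effect_sd**2)
        causal = [v for v in truth.causal_ids
                  if truth.block_of[v] == truth.block_of[signal.index_variant_id]]
        print(
            f"signal {signal.signal_id}: index {signal.index_variant_id} "
            f"(joint p = {signal.joint_p:.2e}), 99% set of {cs.n_members} variants, "
            f"top posterior {cs.top_posterior:.3f}, "
            f"high-confidence: {cs.high_confidence}, true causal {causal} "
            f"{'IN' if causal and causal[0] in cs else 'NOT IN'} set"
        )

# Each line reports one distinct association signal: the index variant from
# the joint model, how many variants the 99% credible set needs, and whether
# the simulated causal variant was captured.
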