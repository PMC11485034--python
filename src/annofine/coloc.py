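"""Bayesian colocalisation of a fine-mapped signal with QTL associations.

Colocalisation is attempted only when triggered: the QTL's lead
(significant, smallest-p) variant must be a member of the signal's 99%
credible set. The test itself enumerates the five standard single-causal
hypotheses over the shared variants:

    H0 neither trait associated        L0 = 1
    H1 trait only                      L1 = p1  * S1
    H2 QTL only                        L2 = p2  * S2
    H3 both, distinct causal variants  L3 = p1 * p2 * (S1 * S2 - S12)
    H4 both, one shared causal         L4 = p12 * S12

with S1 = sum_j BF1_j, S2 = sum_j BF2_j, S12 = sum_j BF1_j * BF2_j. The
trait-side Bayes factor is annotation-informed (gamma_j * Lambda_j); the
QTL side uses annotation-blind Wakefield Bayes factors. Posteriors are the
normalised likelihoods, computed in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .enrichment import DEFAULT_W, wakefield_abf
from .finemap import CredibleSet

logger = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
#: conventional cut-off for calling "convincing" support for a shared causal
H4_SUPPORT_THRESHOLD = 0.8
HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocResult:
    signal_id: str
    gene: str
    tissue: str
    pp: dict[str, float]
    n_overlap: int
    triggered_by: str = ""

    def __post_init__(self):
        total = sum(self.pp.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"colocalisation posteriors sum to {total}, not 1")
        if any(v < 0 for v in self.pp.values()):
            raise ValueError("negative posterior probability")

    @property
    def supported(self) -> bool:
        return self.pp["H4"] >= H4_SUPPORT_THRESHOLD


def lead_qtl_in_credset(
    credset: CredibleSet,
    qtl: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> bool:
    """True iff the QTL's smallest-p *significant* variant is a set member."""
    if qtl.empty:
        raise ValueError("empty QTL table")
    shared = qtl[qtl["variant_id"].isin(credset.table["variant_id"])]
    if shared.empty:
        warnings.warn(
            f"signal {credset.signal_id}: no QTL variants overlap the signal", stacklevel=2
        )
        return False
    sig = qtl[qtl["pvalue"] < p_threshold]
    if sig.empty:
        return False
    lead = sig.loc[sig["pvalue"].idxmin(), "variant_id"]
    return lead in credset


def colocalise_bf(
    trait_ln_bf: pd.Series,
    qtl: pd.DataFrame,
    *,
    signal_id: str = "",
    gene: str = "",
    tissue: str = "",
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    qtl_prior_var: float = DEFAULT_W,
    triggered_by: str = "",
) -> ColocResult:
    """Five-hypothesis colocalisation posteriors (see module docstring).

    Parameters
    ----------
    trait_ln_bf
        Natural-log annotation-informed Bayes factors (``ln gamma_j +
        ln Lambda_j``) indexed by variant_id.
    qtl
        Summary statistics for one gene-tissue; Bayes factors are computed
        from ``beta``/``se`` at *qtl_prior_var*.
    """
    if min(p1, p2, p12) <= 0:
        raise ValueError("priors must be positive")
    if p12 > min(p1, p2):
        raise ValueError("p12 must not exceed min(p1, p2)")
    qtl = qtl.drop_duplicates("variant_id").set_index("variant_id")
    shared = trait_ln_bf.index.intersection(qtl.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared variant(s); need at least 2")
    lbf1 = trait_ln_bf.loc[shared].to_numpy(dtype=float)
    lbf2 = np.atleast_1d(
        wakefield_abf(
            qtl.loc[shared, "beta"].to_numpy(), qtl.loc[shared, "se"].to_numpy(), qtl_prior_var
        )
    )
    ls1 = logsumexp(lbf1)
    ls2 = logsumexp(lbf2)
    ls12 = logsumexp(lbf1 + lbf2)

    ln_l = np.empty(5)
    ln_l[0] = 0.0
    ln_l[1] = np.log(p1) + ls1
    ln_l[2] = np.log(p2) + ls2
    # S1*S2 - S12 >= 0 always (cross terms); guard the log of the difference
    diff = ls12 - (ls1 + ls2)
    if diff >= -1e-14:
        ln_l[3] = -np.inf
    else:
        ln_l[3] = np.log(p1) + np.log(p2) + ls1 + ls2 + np.log1p(-np.exp(diff))
    ln_l[4] = np.log(p12) + ls12
    pp = np.exp(ln_l - logsumexp(ln_l))
    pp /= pp.sum()
    return ColocResult(
        signal_id=signal_id,
        gene=gene,
        tissue=tissue,
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        n_overlap=int(len(shared)),
        triggered_by=triggered_by,
    )


def run_coloc(
    credset: CredibleSet,
    qtl_tables: dict[tuple[str, str], pd.DataFrame],
    *,
    qtl_kind: str = "eqtl",
    p_threshold: float = 5e-8,
    **kwargs,
) -> list[ColocResult]:
    """Trigger-then-test over a collection of gene-tissue QTL tables.

    *qtl_tables* maps (gene, tissue) to a summary-statistics table. Only
    pairs whose lead QTL variant lies in the credible set are tested.
    """
    trait_ln_bf = pd.Series(
        (credset.table["ln_prior"] + credset.table["ln_bf"]).to_numpy(),
        index=credset.table["variant_id"].to_numpy(),
    )
    # colocalise over the credible-set variants; a singleton set falls back
    # to the signal's full ranking (the test needs >= 2 shared variants)
    members = credset.members
    member_bf = trait_ln_bf if len(members) < 2 else trait_ln_bf.loc[members]
    results = []
    for (gene, tissue), qtl in sorted(qtl_tables.items()):
        try:
            triggered = lead_qtl_in_credset(credset, qtl, p_threshold)
        except ValueError:
            continue
        if not triggered:
            continue
        results.append(
            colocalise_bf(
                member_bf,
                qtl,
                signal_id=credset.signal_id,
                gene=gene,
                tissue=tissue,
                triggered_by=f"lead_{qtl_kind}_in_credset",
                **kwargs,
            )
        )
    return results


def coloc_table(results: list[ColocResult]) -> pd.DataFrame:
    rows = [
        {
            "signal_id": r.signal_id,
            "gene": r.gene,
            "tissue": r.tissue,
            **{f"pp_{h.lower()}": r.pp[h] for h in HYPOTHESES},
            "n_overlap": r.n_overlap,
            "triggered_by": r.triggered_by,
            "supported": r.supported,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "signal_id", "gene", "tissue", "pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4",
            "n_overlap", "triggered_by", "supported",
        ],
    )
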