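"""Locus definition and summary-statistics conditional analysis.

Loci are +/- ``window_bp`` intervals around genome-wide-significant lead
variants, merged when they overlap. Within a locus, distinct association
signals are found by greedy stepwise selection on approximate joint models
reconstructed from marginal statistics and a reference LD panel — the
conditional-and-joint (COJO) algebra.

Joint-model reconstruction
--------------------------
For model variants with marginal effects ``b_j``, standard errors ``se_j``,
per-variant sample sizes ``N_j`` and panel dosage variances ``v_j``, the
sufficient statistics of the (unobserved) multiple regression are
approximated as::

    SSx_j  = N_j * v_j                      (genotype sum of squares)
    X'y_j  = SSx_j * b_j                    (from the marginal fit)
    X'X_jk = r_jk * sqrt(SSx_j * SSx_k)     (panel LD)
    SSy    = median_j SSx_j * (b_j^2 + (N_j - 2) * se_j^2)

Joint coefficients are ``(X'X)^{-1} X'y``; their covariance uses the
residual variance ``(SSy - B'X'y) / (N - m - 1)``. On genotype-backed data
whose marginal statistics and LD come from the same sample this reproduces
full-data least squares to numerical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import LDPanel

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8
DEFAULT_WINDOW_BP = 500_000
COLLINEARITY_R2 = 0.9
MAF_FLOOR = 0.01


@dataclass
class Locus:
    locus_id: int
    chrom: str
    start: int
    end: int
    lead_ids: list[str]

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("locus end < start")


@dataclass
class Signal:
    """One distinct association signal (index variant of a joint model)."""

    signal_id: str  # "<locus>_<ordinal>"
    locus_id: int
    index_variant_id: str
    joint_beta: float
    joint_se: float
    joint_p: float
    conditioning_set: list[str] = field(default_factory=list)


def define_loci(leads: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP) -> list[Locus]:
    """Merge +/- *window_bp* intervals around lead variants into loci.

    Overlapping or abutting intervals on one chromosome are combined; locus
    ids are assigned in (chrom, start) order, starting at 1.
    """
    if leads.empty:
        return []
    bad = leads["pvalue"] >= GWS_THRESHOLD
    if bad.any():
        raise ValueError(f"{int(bad.sum())} lead(s) are not genome-wide significant")
    loci: list[Locus] = []
    df = leads.sort_values(["chrom", "pos"], kind="stable")
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_leads: list[str] = []
        for _, row in grp.iterrows():
            start = max(1, int(row["pos"]) - window_bp)
            end = int(row["pos"]) + window_bp
            if cur_end is None or start > cur_end + 1:
                if cur_end is not None:
                    loci.append(Locus(0, str(chrom), cur_start, cur_end, cur_leads))
                cur_start, cur_end, cur_leads = start, end, [row["variant_id"]]
            else:
                cur_end = max(cur_end, end)
                cur_leads.append(row["variant_id"])
        loci.append(Locus(0, str(chrom), cur_start, cur_end, cur_leads))
    loci.sort(key=lambda l: (l.chrom, l.start))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = i
    return loci


def locus_variants(stats_df: pd.DataFrame, locus: Locus) -> pd.DataFrame:
    mask = (
        (stats_df["chrom"].astype(str) == locus.chrom)
        & (stats_df["pos"] >= locus.start)
        & (stats_df["pos"] <= locus.end)
    )
    return stats_df.loc[mask]


# ---------------------------------------------------------------------------
# Joint-model algebra
# ---------------------------------------------------------------------------

def _sufficient_stats(stats_df: pd.DataFrame, panel: LDPanel, ids: list[str]):
    sub = stats_df.set_index("variant_id").loc[ids]
    n = sub["n"].to_numpy(dtype=float)
    b = sub["beta"].to_numpy(dtype=float)
    se = sub["se"].to_numpy(dtype=float)
    vx = panel.dosage_var(ids)
    ssx = n * vx
    xty = ssx * b
    ssy = np.median(ssx * (b**2 + (n - 2) * se**2))
    return n, ssx, xty, ssy


def joint_model(
    stats_df: pd.DataFrame,
    panel: LDPanel,
    model_ids: list[str],
    collinearity_r2: float = COLLINEARITY_R2,
) -> pd.DataFrame:
    """Approximate joint regression estimates for *model_ids*.

    Returns a frame (variant_id, joint_beta, joint_se, joint_p) in model
    order. Later-added variants in near-perfect LD (r^2 >= cap) with an
    earlier one raise; callers performing selection should prune first.
    """
    if not model_ids:
        raise ValueError("empty model")
    R = panel.corr(model_ids)
    m = len(model_ids)
    for j in range(1, m):
        worst = np.max(R[j, :j] ** 2)
        if worst >= collinearity_r2:
            raise CollinearityError(model_ids[j])
    n, ssx, xty, ssy = _sufficient_stats(stats_df, panel, model_ids)
    scale = np.sqrt(ssx)
    xtx = R * np.outer(scale, scale)
    try:
        coef = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular joint-model matrix after pruning") from None
    n_eff = float(np.median(n))
    dof = max(n_eff - m - 1, 1.0)
    sigma2 = max(ssy - coef @ xty, 0.0) / dof
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), np.finfo(float).tiny, None))
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "variant_id": model_ids,
            "joint_beta": coef,
            "joint_se": se,
            "joint_p": np.clip(p, np.finfo(float).tiny, 1.0),
        }
    )


class CollinearityError(ValueError):
    def __init__(self, variant_id: str):
        super().__init__(f"variant {variant_id} collinear with the existing model")
        self.variant_id = variant_id


def conditional_sumstats(
    stats_df: pd.DataFrame,
    panel: LDPanel,
    conditioning_ids: list[str],
    candidate_ids: list[str] | None = None,
    collinearity_r2: float = COLLINEARITY_R2,
) -> pd.DataFrame:
    """Marginal statistics adjusted for a conditioning set.

    Each non-conditioning variant is added, alone, to the conditioning
    model; its joint coefficient and SE are the conditional estimates.
    Variants collinear with the conditioning set are excluded (logged).
    Conditioning variants never appear in the output.
    """
    if not conditioning_ids:
        raise ValueError("empty conditioning set")
    if candidate_ids is None:
        candidate_ids = [v for v in stats_df["variant_id"] if v not in set(conditioning_ids)]
    rows, n_skip = [], 0
    for vid in candidate_ids:
        if vid in conditioning_ids or vid not in panel:
            continue
        try:
            fit = joint_model(stats_df, panel, conditioning_ids + [vid], collinearity_r2)
        except CollinearityError:
            n_skip += 1
            continue
        rows.append(fit.iloc[-1])
    if n_skip:
        logger.info("conditional analysis skipped %d collinear variant(s)", n_skip)
    if not rows:
        return stats_df.iloc[0:0].copy()
    fit = pd.DataFrame(rows).reset_index(drop=True)
    out = (
        stats_df.set_index("variant_id")
        .loc[fit["variant_id"]]
        .reset_index()
        .assign(
            beta=fit["joint_beta"].to_numpy(),
            se=fit["joint_se"].to_numpy(),
            pvalue=fit["joint_p"].to_numpy(),
        )
    )
    return out


def stepwise_select(
    stats_df: pd.DataFrame,
    panel: LDPanel,
    locus: Locus,
    p_enter: float = GWS_THRESHOLD,
    collinearity_r2: float = COLLINEARITY_R2,
    maf_floor: float = MAF_FLOOR,
    max_signals: int = 20,
) -> list[Signal]:
    """Greedy forward selection of distinct signals at one locus.

    Seeds with the locus' smallest-p variant; repeatedly adds the variant
    with the smallest conditional p below *p_enter*, then re-checks the
    joint model and drops any selected variant whose joint p rises above
    the threshold (backward step). Signals are numbered by entry order.
    """
    sub = locus_variants(stats_df, locus)
    sub = sub[[v in panel for v in sub["variant_id"]]]
    if not sub.empty:
        freq = panel.freq(sub["variant_id"].tolist())
        maf = np.minimum(freq, 1 - freq)
        sub = sub.loc[np.asarray(maf) >= maf_floor]
    if sub.empty or sub["pvalue"].min() >= p_enter:
        return []

    selected = [sub.loc[sub["pvalue"].idxmin(), "variant_id"]]
    seen = {tuple(selected)}
    for _ in range(max_signals * 4):
        cand = [v for v in sub["variant_id"] if v not in selected]
        cond = conditional_sumstats(stats_df, panel, selected, cand, collinearity_r2)
        best = None
        if not cond.empty and cond["pvalue"].min() < p_enter:
            best = cond.loc[cond["pvalue"].idxmin(), "variant_id"]
            selected = selected + [best]
        # backward step: prune non-significant members of the joint model
        while len(selected) > 1:
            fit = joint_model(stats_df, panel, selected, collinearity_r2)
            worst = fit["joint_p"].idxmax()
            if fit.loc[worst, "joint_p"] < p_enter:
                break
            selected = [v for v in selected if v != fit.loc[worst, "variant_id"]]
        if best is None:
            break
        key = tuple(sorted(selected))
        if key in seen or len(selected) >= max_signals:
            break
        seen.add(key)

    fit = joint_model(stats_df, panel, selected, collinearity_r2)
    fit = fit[fit["joint_p"] < p_enter]
    signals = []
    for ordinal, (_, row) in enumerate(fit.iterrows(), start=1):
        others = [v for v in fit["variant_id"] if v != row["variant_id"]]
        signals.append(
            Signal(
                signal_id=f"{locus.locus_id}_{ordinal}",
                locus_id=locus.locus_id,
                index_variant_id=row["variant_id"],
                joint_beta=float(row["joint_beta"]),
                joint_se=float(row["joint_se"]),
                joint_p=float(row["joint_p"]),
                conditioning_set=others,
            )
        )
    return signals


def signals_table(signals: list[Signal]) -> pd.DataFrame:
    """Flatten a list of signals into the TSV layout used on disk."""
    return pd.DataFrame(
        {
            "signal_id": [s.signal_id for s in signals],
            "locus_id": [s.locus_id for s in signals],
            "index_variant_id": [s.index_variant_id for s in signals],
            "joint_beta": [s.joint_beta for s in signals],
            "joint_se": [s.joint_se for s in signals],
            "joint_p": [s.joint_p for s in signals],
            "conditioning_set": [",".join(s.conditioning_set) for s in signals],
        }
    )
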