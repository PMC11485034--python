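"""Synthetic GWAS/QTL data with block LD and annotation-driven causal placement.

The generator produces every input the fine-mapping pipeline consumes —
an LD reference panel, binary annotations, a causal architecture, GWAS and
cis-QTL summary statistics, and promoter-capture interaction fixtures — with
known ground truth, so each stage can be validated offline.

LD model
--------
Haplotypes are drawn by thresholding a latent AR(1) Gaussian process: within
a block every variant shares one allele frequency, and the latent
autocorrelation is calibrated (via the tetrachoric relation) so that the
*allele-level* correlation of adjacent variants equals the requested ``rho``.
Blocks are mutually independent. Genotypes are sums of two independent
haplotypes, so adjacent-dosage correlation has expectation ``rho`` as well.

Causal architecture
-------------------
Each block independently harbours a causal variant with probability
``block_prior``; within a causal block, variant *j* is causal with
probability proportional to ``exp(sum_k true_beta[k] * z[j, k])`` — the
generative counterpart of the annotation-informed prior used in
fine-mapping. Effect sizes are N(0, effect_sd^2) on the trait-per-allele
scale. At most one causal per block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SUMSTAT_COLUMNS, AnnotationMatrix, LDPanel

logger = logging.getLogger(__name__)

_BLOCK_SPACING = 2_000_000  # bp between block starts (keeps loci separate by default)
_POS_STEP = 1_000  # bp between adjacent variants in a block
_MONOMORPHIC_RETRIES = 10


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults describe a mid-size quantitative-trait GWAS: 40,000 phenotyped
    individuals, an LD reference of 1,000, common variants (MAF 0.05-0.5),
    strong local LD (adjacent r = 0.9), and causal effects of ~0.05
    trait-SD per allele after standardisation.
    """

    n_samples: int = 1_000
    n_variants: int = 20
    n_blocks: int = 10
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_annotations: int = 1
    annotation_coverage: float | tuple[float, ...] = 0.2
    true_beta: tuple[float, ...] = (0.0,)
    block_prior: float = 0.5
    effect_sd: float = 0.15
    gwas_n: int = 40_000
    seed: int = 1

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.block_prior <= 1):
            raise ValueError("block_prior must be a probability")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")
        if self.gwas_n <= 0 or self.n_samples <= 0:
            raise ValueError("sample sizes must be positive")
        cov = self.coverage_vector()
        if np.any((cov < 0) | (cov > 1)):
            raise ValueError("annotation_coverage must be probabilities")
        if len(self.beta_vector()) != self.n_annotations:
            raise ValueError("true_beta length must equal n_annotations")

    def coverage_vector(self) -> np.ndarray:
        cov = np.atleast_1d(np.asarray(self.annotation_coverage, dtype=float))
        if cov.size == 1:
            cov = np.repeat(cov, self.n_annotations)
        return cov

    def beta_vector(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.true_beta, dtype=float))


@dataclass
class SimTruth:
    """Ground-truth causal architecture of one simulation."""

    causal_ids: list[str]
    causal_effects: np.ndarray  # aligned with causal_ids, trait units per allele
    block_of: pd.Series  # variant_id -> block index

    def __post_init__(self):
        if len(self.causal_ids) != len(self.causal_effects):
            raise ValueError("causal_ids and causal_effects length mismatch")
        missing = [v for v in self.causal_ids if v not in self.block_of.index]
        if missing:
            raise ValueError(f"causal id(s) not in panel: {missing[:5]}")
        blocks = [self.block_of[v] for v in self.causal_ids]
        if len(set(blocks)) != len(blocks):
            raise ValueError("more than one causal in a block")

    def effect_of(self, variant_id: str) -> float:
        try:
            return float(self.causal_effects[self.causal_ids.index(variant_id)])
        except ValueError:
            return 0.0


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

def _latent_rho_for(target: float, p: float) -> float:
    """Latent Gaussian correlation giving allele-level correlation *target*.

    Inverts the tetrachoric relation corr = (P11 - p^2) / (p(1-p)) where
    P11 is the bivariate-normal orthant mass below (t, t), t = Phi^{-1}(p).
    """
    if target <= 0:
        return 0.0
    t = stats.norm.ppf(p)

    def gap(r):
        p11 = stats.multivariate_normal([0, 0], [[1, r], [r, 1]], allow_singular=True).cdf([t, t])
        return (p11 - p * p) / (p * (1 - p)) - target

    return float(optimize.brentq(gap, 0.0, 0.999999, xtol=1e-10))


def _block_haplotypes(rng, n_hap: int, m: int, p: float, rho: float) -> np.ndarray:
    lat = _latent_rho_for(rho, p)
    t = stats.norm.ppf(p)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1 - lat**2)
        for j in range(1, m):
            z[:, j] = lat * z[:, j - 1] + innov[:, j - 1]
    return (z < t).astype(np.int8)


def simulate_reference_panel(cfg: SimConfig, seed: int | None = None) -> LDPanel:
    """Draw a genotype reference panel with block-AR(1) LD.

    One allele frequency per block is drawn uniformly from ``maf_range``.
    Monomorphic blocks are redrawn up to a retry cap, then raise.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    geno_blocks, rows = [], []
    for b in range(cfg.n_blocks):
        p = rng.uniform(*cfg.maf_range)
        for attempt in range(_MONOMORPHIC_RETRIES + 1):
            hap = _block_haplotypes(rng, 2 * cfg.n_samples, cfg.n_variants, p, cfg.rho)
            g = hap[: cfg.n_samples] + hap[cfg.n_samples :]
            if (g.min(axis=0) != g.max(axis=0)).all():
                break
        else:
            raise RuntimeError(f"block {b}: monomorphic variant after {_MONOMORPHIC_RETRIES} retries")
        geno_blocks.append(g)
        start = b * _BLOCK_SPACING + 1
        for j in range(cfg.n_variants):
            rows.append((f"rs{b}_{j}", "1", start + j * _POS_STEP, "A", "G", b))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "block"])
    return LDPanel.from_genotypes(np.concatenate(geno_blocks, axis=1), variants)


def analytic_panel(cfg: SimConfig, seed: int | None = None) -> LDPanel:
    """Panel with exact AR(1) block correlation matrices (no genotypes).

    Useful for large direct-mode simulations where empirical LD noise is
    unwanted; frequencies are drawn per block as in the genotype panel.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    idx = np.arange(cfg.n_variants)
    R = cfg.rho ** np.abs(idx[:, None] - idx[None, :])
    block_corr = {}
    for b in range(cfg.n_blocks):
        p = rng.uniform(*cfg.maf_range)
        start = b * _BLOCK_SPACING + 1
        for j in range(cfg.n_variants):
            rows.append((f"rs{b}_{j}", "1", start + j * _POS_STEP, "A", "G", p, b))
        block_corr[b] = R
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "freq", "block"]
    )
    return LDPanel.from_block_corr(variants, block_corr)


# ---------------------------------------------------------------------------
# Annotations and causal architecture
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig, panel: LDPanel, seed: int | None = None) -> AnnotationMatrix:
    """Independent Bernoulli(coverage_k) indicators per variant and annotation."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cov = cfg.coverage_vector()
    mat = (rng.random((len(panel.variants), cfg.n_annotations)) < cov).astype(np.int8)
    frame = pd.DataFrame(
        mat,
        index=panel.variants["variant_id"].to_numpy(),
        columns=[f"ann{k}" for k in range(cfg.n_annotations)],
    )
    return AnnotationMatrix(frame)


def simulate_causal_architecture(
    cfg: SimConfig, annotations: AnnotationMatrix, panel: LDPanel, seed: int | None = None
) -> SimTruth:
    """Place at most one causal variant per block, tilted by annotations."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    z = annotations.subset(panel.variants["variant_id"].tolist())
    score = z @ cfg.beta_vector()
    blocks = panel.variants["block"].to_numpy()
    vids = panel.variants["variant_id"].to_numpy()
    causal_ids, effects = [], []
    for b in np.unique(blocks):
        if rng.random() >= cfg.block_prior:
            continue
        mask = blocks == b
        w = np.exp(score[mask] - score[mask].max())
        w /= w.sum()
        j = rng.choice(np.flatnonzero(mask), p=w)
        causal_ids.append(vids[j])
        effects.append(rng.normal(0.0, cfg.effect_sd))
    block_of = pd.Series(blocks, index=vids)
    return SimTruth(causal_ids, np.asarray(effects, dtype=float), block_of)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _nearest_pd(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() > 1e-10:
        return R
    warnings.warn("correlation matrix not positive definite; clipping eigenvalues", stacklevel=3)
    vals = np.clip(vals, 1e-8, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def simulate_gwas_sumstats(
    panel: LDPanel,
    truth: SimTruth,
    cfg: SimConfig,
    mode: str = "direct",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-variant marginal association statistics for the simulated trait.

    ``mode="genotype"`` simulates a phenotype on the panel individuals
    (causal effects plus unit-variance noise) and runs single-variant OLS;
    ``mode="direct"`` draws per-block z-scores from N(R @ ncp, R) — the
    standard LD-aware sampling distribution of marginal z-scores — with
    non-centralities ``sqrt(gwas_n) * beta * sd(dosage)`` and converts them
    to beta/SE via ``SE = 1 / sqrt(2 f (1-f) gwas_n)``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    v = panel.variants
    vids = v["variant_id"].to_numpy()

    if mode == "genotype":
        if panel.genotypes is None:
            raise ValueError("genotype mode requires a genotype-backed panel")
        G = panel.genotypes.astype(float)
        n = G.shape[0]
        y = rng.standard_normal(n)
        for vid, eff in zip(truth.causal_ids, truth.causal_effects):
            y = y + eff * G[:, panel.indices([vid])[0]]
        Gc = G - G.mean(axis=0)
        yc = y - y.mean()
        ssx = (Gc**2).sum(axis=0)
        beta = Gc.T @ yc / ssx
        rss = (yc**2).sum() - 2 * beta * (Gc.T @ yc) + beta**2 * ssx
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / ssx)
        zscores = beta / se
        n_col = np.full(len(vids), n)
    elif mode == "direct":
        freq = v["freq"].to_numpy()
        sd_x = np.sqrt(v["var"].to_numpy())
        b_per_allele = np.zeros(len(vids))
        for vid, eff in zip(truth.causal_ids, truth.causal_effects):
            b_per_allele[panel.indices([vid])[0]] = eff
        ncp = np.sqrt(cfg.gwas_n) * b_per_allele * sd_x
        zscores = np.empty(len(vids))
        blocks = v["block"].to_numpy()
        for b in np.unique(blocks):
            mask = blocks == b
            R = panel.corr(vids[mask])
            try:
                L = np.linalg.cholesky(R)
            except np.linalg.LinAlgError:
                R = _nearest_pd(R)
                L = np.linalg.cholesky(R)  # raises if repair failed
            zscores[mask] = R @ ncp[mask] + L @ rng.standard_normal(mask.sum())
        se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * cfg.gwas_n)
        beta = zscores * se
        n_col = np.full(len(vids), cfg.gwas_n)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pvals = 2.0 * stats.norm.sf(np.abs(zscores))
    out = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "effect_allele": v["effect_allele"].to_numpy(),
            "other_allele": v["other_allele"].to_numpy(),
            "eaf": v["freq"].to_numpy(),
            "beta": beta,
            "se": se,
            "pvalue": np.clip(pvals, np.finfo(float).tiny, 1.0),
            "n": n_col,
        }
    )
    return out[SUMSTAT_COLUMNS]


def simulate_qtl_sumstats(
    panel: LDPanel,
    truth: SimTruth,
    scenario: str,
    cfg: SimConfig,
    block: int,
    gene: str = "GENE1",
    tissue: str = "tissue1",
    effect: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """cis-QTL summary statistics for one gene-tissue over one block.

    ``shared`` reuses the block's GWAS causal variant with an independent
    effect size; ``distinct`` places the QTL causal on a different variant
    of the block; ``null`` has no QTL effect.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    blocks = panel.variants["block"].to_numpy()
    vids = panel.variants["variant_id"].to_numpy()[blocks == block]
    if scenario not in {"shared", "distinct", "null"}:
        raise ValueError(f"unknown scenario {scenario!r}")

    gwas_causal = [v for v in truth.causal_ids if truth.block_of[v] == block]
    qtl_ids: list[str] = []
    if scenario in {"shared", "distinct"}:
        if not gwas_causal:
            raise ValueError(f"block {block} has no GWAS causal variant")
        if scenario == "shared":
            qtl_ids = [gwas_causal[0]]
        else:
            others = [v for v in vids if v != gwas_causal[0]]
            if not others:
                raise ValueError("single-variant block cannot host a distinct QTL causal")
            # farthest variant: minimises LD with the GWAS causal
            qtl_ids = [others[-1] if gwas_causal[0] != others[-1] else others[0]]
    eff = cfg.effect_sd if effect is None else effect
    qtl_truth = SimTruth(
        qtl_ids,
        np.array([rng.normal(0.0, eff) if effect is None else eff] * len(qtl_ids)),
        truth.block_of,
    )
    sub = LDPanel(
        panel.variants.loc[blocks == block].reset_index(drop=True),
        genotypes=None if panel.genotypes is None else panel.genotypes[:, blocks == block],
        block_corr=None if panel.genotypes is not None else {block: panel._block_corr[block]},
    )
    out = simulate_gwas_sumstats(sub, qtl_truth, cfg, mode="direct", seed=rng.integers(2**31 - 1))
    out["gene"] = gene
    out["tissue"] = tissue
    return out


# ---------------------------------------------------------------------------
# Promoter-capture interaction fixtures
# ---------------------------------------------------------------------------

def simulate_hic_fixture(
    gene_models: pd.DataFrame,
    tissues: list[str],
    bin_size: int = 10_000,
    distal_offset: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic promoter-capture interaction fixture.

    *gene_models* needs columns gene, chrom, promoter_start, promoter_end
    (0-based half-open). For each gene x tissue one interaction joins a
    distal bin (``distal_offset`` bp upstream of the promoter bin) to the
    bin containing the promoter. Returns (interactions, promoter BED table),
    both sorted; a promoter anchor that covers no promoter is rejected with
    a warning.
    """
    rows = []
    for _, g in gene_models.iterrows():
        pstart = int(g["promoter_start"])
        prom_bin = (pstart // bin_size) * bin_size
        distal_start = prom_bin - distal_offset
        if distal_start < 0:
            warnings.warn(f"gene {g['gene']}: distal anchor before position 0; row rejected")
            continue
        if not (prom_bin <= pstart < prom_bin + bin_size):
            warnings.warn(f"gene {g['gene']}: promoter anchor misses promoter; row rejected")
            continue
        for tissue in tissues:
            rows.append(
                (
                    str(g["chrom"]), distal_start, distal_start + bin_size,
                    str(g["chrom"]), prom_bin, prom_bin + bin_size,
                    g["gene"], tissue, 0.01,
                )
            )
    interactions = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "target_gene", "tissue", "qvalue"],
    ).sort_values(["tissue", "chrom1", "start1", "target_gene"], kind="stable").reset_index(drop=True)
    promoters = (
        gene_models[["chrom", "promoter_start", "promoter_end", "gene"]]
        .rename(columns={"promoter_start": "start", "promoter_end": "end", "gene": "name"})
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    return interactions, promoters
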