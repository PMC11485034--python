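"""Evidence integration, candidate-gene summaries and gene-set enrichment.

A gene becomes a candidate effector gene when at least one core line of
evidence supports it: a high-confidence missense variant, an eQTL or pQTL
colocalisation, or a promoter-capture interaction. Externally curated
evidence (mouse/human phenotypes, differential expression) is ingested
from a user-supplied table — it is never fetched — and feeds the
"additional functional evidence" tier: candidate AND (mouse OR human
phenotype) AND differential expression.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CORE_COLUMNS = ["missense_hc", "eqtl_coloc", "pqtl_coloc", "hic"]
EXTRA_COLUMNS = ["mouse_phenotype", "human_phenotype", "differential_expression"]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded to *decimals*, half away from zero. 0 when denominator is 0."""
    if denominator == 0:
        logger.warning("percentage with zero denominator reported as 0")
        return 0.0
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.copy_abs().quantize(exp, rounding=ROUND_HALF_UP) * (1 if q >= 0 else -1))


def _normalise_genes(frame: pd.DataFrame, col: str) -> pd.DataFrame:
    """Collapse case-variant duplicates of gene symbols, warn once each."""
    frame = frame.copy()
    canon: dict[str, str] = {}
    out = []
    for g in frame[col].astype(str):
        key = g.upper()
        if key in canon and canon[key] != g:
            logger.warning("gene symbol case collision: %s vs %s; using %s", g, canon[key], canon[key])
        canon.setdefault(key, g)
        out.append(canon[key])
    frame[col] = out
    return frame


def build_evidence_matrix(
    missense_genes: pd.DataFrame | None = None,
    coloc_results: pd.DataFrame | None = None,
    hic_hits: pd.DataFrame | None = None,
    extra_evidence: pd.DataFrame | None = None,
    h4_threshold: float = 0.8,
) -> pd.DataFrame:
    """Gene x evidence-line boolean matrix with provenance.

    Parameters
    ----------
    missense_genes
        Frame with gene_symbol and signal_id (high-confidence missense rows).
    coloc_results
        :func:`annofine.coloc.coloc_table` output with a ``qtl_kind``-style
        ``triggered_by`` column; rows with pp_h4 >= *h4_threshold* count.
    hic_hits
        :func:`annofine.hic.map_credset_to_targets` output.
    extra_evidence
        Long table (gene, evidence_type, source) with evidence_type among
        mouse_phenotype / human_phenotype / differential_expression.

    Returns a frame indexed by gene with boolean evidence columns, a
    ``candidate`` column (any core line true), and per-line provenance
    strings (signal ids / tissues / sources).
    """
    cells: dict[str, dict[str, object]] = {}

    def mark(gene: str, column: str, provenance: str):
        slot = cells.setdefault(gene, {c: set() for c in CORE_COLUMNS + EXTRA_COLUMNS})
        slot[column].add(provenance)

    if missense_genes is not None and not missense_genes.empty:
        mg = _normalise_genes(missense_genes, "gene_symbol")
        for _, r in mg.iterrows():
            mark(r["gene_symbol"], "missense_hc", str(r.get("signal_id", r["variant_id"])))
    if coloc_results is not None and not coloc_results.empty:
        cr = _normalise_genes(coloc_results, "gene")
        cr = cr[cr["pp_h4"] >= h4_threshold]
        for _, r in cr.iterrows():
            col = "pqtl_coloc" if "pqtl" in str(r.get("triggered_by", "")) else "eqtl_coloc"
            mark(r["gene"], col, f"{r['signal_id']}:{r['tissue']}")
    if hic_hits is not None and not hic_hits.empty:
        hh = _normalise_genes(hic_hits, "gene")
        for _, r in hh.iterrows():
            mark(r["gene"], "hic", f"{r['signal_id']}:{r['tissues']}")
    if extra_evidence is not None and not extra_evidence.empty:
        ex = _normalise_genes(extra_evidence, "gene")
        bad = set(ex["evidence_type"]) - set(EXTRA_COLUMNS)
        if bad:
            raise ValueError(f"unknown evidence_type value(s): {sorted(bad)}")
        for _, r in ex.iterrows():
            mark(r["gene"], r["evidence_type"], str(r.get("source", "user")))

    rows = []
    for gene in sorted(cells):
        slot = cells[gene]
        row = {"gene": gene}
        for col in CORE_COLUMNS + EXTRA_COLUMNS:
            row[col] = bool(slot[col])
            row[f"{col}_provenance"] = ";".join(sorted(slot[col]))
        row["candidate"] = any(row[c] for c in CORE_COLUMNS)
        rows.append(row)
    cols = (
        ["gene"]
        + CORE_COLUMNS
        + EXTRA_COLUMNS
        + ["candidate"]
        + [f"{c}_provenance" for c in CORE_COLUMNS + EXTRA_COLUMNS]
    )
    out = pd.DataFrame(rows, columns=cols)
    return out.set_index("gene")


def summarize_candidates(
    matrix: pd.DataFrame,
    n_signals: int,
    n_high_confidence: int,
) -> dict:
    """Counts and percentages of the evidence integration.

    Percentages are recomputed from raw counts (one decimal, half away
    from zero); nothing is carried over pre-rounded.
    """
    candidates = matrix[matrix["candidate"]]
    n_candidates = int(len(candidates))
    report = {
        "n_signals": int(n_signals),
        "n_high_confidence_signals": int(n_high_confidence),
        "pct_high_confidence_signals": percent(n_high_confidence, n_signals),
        "n_candidate_genes": n_candidates,
    }
    for col in CORE_COLUMNS + EXTRA_COLUMNS:
        if col in matrix.columns:
            n = int(candidates[col].sum())
            report[f"n_{col}"] = n
            report[f"pct_{col}"] = percent(n, n_candidates)
    if all(c in matrix.columns for c in EXTRA_COLUMNS):
        both = candidates[
            (candidates["mouse_phenotype"] | candidates["human_phenotype"])
            & candidates["differential_expression"]
        ]
        report["n_additional_functional_evidence"] = int(len(both))
        report["pct_additional_functional_evidence"] = percent(len(both), n_candidates)
    return report


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(filter(None, parts[2:]))
    return sets


def gene_set_enrichment(
    candidates: set[str],
    background: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per set, BH-adjusted across sets.

    ``p = P(X >= k)`` with X hypergeometric(M=len(background),
    K=len(set & background), n=len(candidates)). Sets disjoint from the
    background are skipped with a log message.
    """
    candidates = set(candidates)
    background = set(background)
    if not candidates:
        raise ValueError("empty candidate list")
    stray = candidates - background
    if stray:
        raise ValueError(f"candidates not in background: {sorted(stray)[:5]}")
    rows = []
    M, n = len(background), len(candidates)
    for name in sorted(gene_sets):
        members = gene_sets[name] & background
        if not members:
            logger.info("gene set %s disjoint from background; skipped", name)
            continue
        k = len(candidates & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n))
        rows.append({"gene_set": name, "k": k, "set_size": len(members), "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["gene_set", "k", "set_size", "pvalue"])
    if not out.empty:
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    else:
        out["qvalue"] = pd.Series(dtype=float)
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
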