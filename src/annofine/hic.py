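"""Target-gene assignment from pre-called promoter-capture interactions.

Interactions arrive pre-normalised and pre-thresholded (BEDPE-like TSV, one
table per tissue or a combined table with a ``tissue`` column): anchor 1 is
the distal fragment, anchor 2 the promoter fragment of ``target_gene``.
A credible-set variant scores a hit for a gene when it is non-coding, meets
the posterior floor, and falls inside the distal anchor; hits are
aggregated to (signal, gene) with the set of supporting tissues.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "target_gene", "tissue", "qvalue"]


def read_interactions(path: str | Path, tissue: str | None = None) -> pd.DataFrame:
    """Read a BEDPE-like interaction TSV; *tissue* overrides or supplies the column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    missing = [c for c in BEDPE_COLUMNS if c not in df.columns and c != "tissue"]
    if missing:
        raise ValueError(f"{path}: missing interaction column(s) {missing}")
    if tissue is not None:
        df["tissue"] = tissue
    elif "tissue" not in df.columns:
        raise ValueError(f"{path}: no tissue column and none supplied")
    return df[BEDPE_COLUMNS]


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", index=False)


def map_credset_to_targets(
    credset_members: pd.DataFrame,
    interactions: pd.DataFrame,
    coding_mask: set[str] | None = None,
    posterior_floor: float = 0.0,
    include_promoter_anchor: bool = False,
    gene_models: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate interaction hits to a (signal, gene) table.

    Parameters
    ----------
    credset_members
        Long credible-set table (signal_id, variant_id, chrom, pos,
        posterior), e.g. from :func:`annofine.finemap.credsets_table`.
    interactions
        BEDPE-like table with 0-based half-open anchors, anchor 1 distal.
    coding_mask
        Variant ids annotated as coding; they never produce hits.
    posterior_floor
        Minimum posterior for a variant to count (default 0: all members).
    include_promoter_anchor
        Also count variants falling inside the promoter anchor.
    gene_models
        Optional table with a ``gene`` column; interactions whose target is
        absent are kept but logged.

    Returns a frame (signal_id, gene, variant_ids, tissues, n_tissues),
    deterministically ordered and invariant under input row order.
    """
    coding_mask = coding_mask or set()
    if gene_models is not None:
        known = set(gene_models["gene"])
        unknown = sorted(set(interactions["target_gene"]) - known)
        if unknown:
            logger.info("%d interaction target gene(s) absent from gene models: %s",
                        len(unknown), ", ".join(unknown[:5]))

    anchors = [("chrom1", "start1", "end1")]
    if include_promoter_anchor:
        anchors.append(("chrom2", "start2", "end2"))
    trees: dict[str, IntervalTree] = {}
    for chrom_col, start_col, end_col in anchors:
        for row_idx, row in interactions.iterrows():
            chrom = str(row[chrom_col])
            trees.setdefault(chrom, IntervalTree())
            if row[end_col] > row[start_col]:
                trees[chrom].addi(int(row[start_col]), int(row[end_col]), row_idx)

    members = credset_members
    if posterior_floor > 0:
        members = members[members["posterior"] >= posterior_floor]
    members = members[~members["variant_id"].isin(coding_mask)]

    hits: dict[tuple[str, str], dict[str, set]] = {}
    for _, m in members.iterrows():
        tree = trees.get(str(m["chrom"]))
        if tree is None:
            continue
        for iv in tree[int(m["pos"]) - 1]:  # 1-based position -> 0-based point
            rec = interactions.loc[iv.data]
            key = (str(m["signal_id"]), str(rec["target_gene"]))
            slot = hits.setdefault(key, {"tissues": set(), "variants": set()})
            slot["tissues"].add(str(rec["tissue"]))
            slot["variants"].add(str(m["variant_id"]))

    rows = [
        {
            "signal_id": sig,
            "gene": gene,
            "variant_ids": ",".join(sorted(slot["variants"])),
            "tissues": ",".join(sorted(slot["tissues"])),
            "n_tissues": len(slot["tissues"]),
        }
        for (sig, gene), slot in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["signal_id", "gene", "variant_ids", "tissues", "n_tissues"])
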