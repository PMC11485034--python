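"""Predicted-consequence filtering of high-confidence variants.

Consequence prediction itself (VEP) is consumed as tabular output, never
run. The module normalises PolyPhen/SIFT category strings into controlled
vocabularies, restricts to missense variants that are high-confidence
causal, and classifies them by deleteriousness:

* "damaging" means PolyPhen *probably* or *possibly* damaging;
* "deleterious" means SIFT deleterious — low-confidence deleterious calls
  do **not** count.

A curated table of the 22 high-confidence missense variants reported for
resting heart rate ships with the package as a worked example
(:func:`load_missense_reference`).
"""

from __future__ import annotations

import logging
import re
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

POLYPHEN_CATEGORIES = ("benign", "possibly_damaging", "probably_damaging", "unknown", "missing")
SIFT_CATEGORIES = (
    "tolerated",
    "tolerated_low_confidence",
    "deleterious",
    "deleterious_low_confidence",
    "missing",
)
DAMAGING_RULES = ("damaging_and_deleterious", "probably_and_deleterious", "possibly_and_deleterious")

_PAREN = re.compile(r"\(.*?\)")


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = _PAREN.sub("", str(value)).strip().lower().replace("_", " ")
    return re.sub(r"\s+", " ", s)


def parse_polyphen(value) -> str:
    """Normalise a PolyPhen string ('Prob Dam', 'benign(0.01)', ...) to a category."""
    s = _clean(value)
    if s in ("", "-", "nan", "na"):
        return "missing"
    if s.startswith("ben"):
        return "benign"
    if s.startswith("poss"):
        return "possibly_damaging"
    if s.startswith("prob"):
        return "probably_damaging"
    if s.startswith("unknown"):
        return "unknown"
    logger.warning("unrecognised PolyPhen value %r treated as missing", value)
    return "missing"


def parse_sift(value) -> str:
    """Normalise a SIFT string ('Tol low conf', 'deleterious(0)', ...) to a category."""
    s = _clean(value)
    if s in ("", "-", "nan", "na"):
        return "missing"
    low_conf = "low conf" in s
    if s.startswith("tol"):
        return "tolerated_low_confidence" if low_conf else "tolerated"
    if s.startswith("del"):
        return "deleterious_low_confidence" if low_conf else "deleterious"
    logger.warning("unrecognised SIFT value %r treated as missing", value)
    return "missing"


def read_consequence_table(path_or_df, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a VEP-style TSV and normalise prediction categories.

    Required logical columns: variant_id, gene_symbol, consequence (or, as
    in the packaged reference table, an implicit missense consequence),
    polyphen, sift. *column_map* maps logical names to file columns.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "consequence" not in df.columns:
        df["consequence"] = "missense_variant"
    df["polyphen"] = df.get("polyphen", pd.Series(index=df.index, dtype=object)).map(parse_polyphen)
    df["sift"] = df.get("sift", pd.Series(index=df.index, dtype=object)).map(parse_sift)
    return df


def load_missense_reference() -> pd.DataFrame:
    """The packaged 22-row reference table of high-confidence RHR missense variants."""
    with resources.files("annofine.data").joinpath("missense_high_confidence.tsv").open() as fh:
        return read_consequence_table(pd.read_csv(fh, sep="\t", dtype={"chrom": str}))


def filter_missense_high_confidence(records: pd.DataFrame, credsets: pd.DataFrame) -> pd.DataFrame:
    """Rows whose variant is a high-confidence causal annotated as missense.

    *credsets* needs columns ``variant_id`` and ``high_confidence`` (e.g.
    from :func:`annofine.finemap.credsets_table`). One row is kept per
    (variant, canonical transcript); a variant with several canonical
    transcripts keeps all of them (logged).
    """
    if credsets.empty:
        return records.iloc[0:0]
    hc = set(credsets.loc[credsets["high_confidence"].astype(bool), "variant_id"])
    out = records[
        records["variant_id"].isin(hc)
        & records["consequence"].str.lower().str.startswith("missense")
    ].copy()
    multi = out.groupby("variant_id").size()
    for vid, k in multi[multi > 1].items():
        logger.info("variant %s has %d canonical transcripts; keeping all", vid, k)
    return out.reset_index(drop=True)


def classify_damaging(records: pd.DataFrame, rule: str = "damaging_and_deleterious"):
    """Subset and count by a PolyPhen x SIFT deleteriousness rule.

    Returns (subset, count). Missing or unknown categories never match.
    """
    if rule not in DAMAGING_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {DAMAGING_RULES}")
    polyphen = {
        "damaging_and_deleterious": {"probably_damaging", "possibly_damaging"},
        "probably_and_deleterious": {"probably_damaging"},
        "possibly_and_deleterious": {"possibly_damaging"},
    }[rule]
    mask = records["polyphen"].isin(polyphen) & (records["sift"] == "deleterious")
    subset = records[mask].reset_index(drop=True)
    return subset, int(mask.sum())


def summarize_missense_genes(records: pd.DataFrame) -> tuple[int, pd.Series]:
    """Distinct gene count and per-gene variant multiplicities."""
    if records.empty:
        return 0, pd.Series(dtype=int)
    counts = records.groupby("gene_symbol")["variant_id"].nunique().sort_index()
    return int(len(counts)), counts
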