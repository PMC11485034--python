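"""Readers, writers and the variant-level data model.

Summary statistics travel as plain :class:`pandas.DataFrame` objects with a
fixed column schema (one row per variant); annotations are binary indicator
matrices built from BED files; LD information is held in :class:`LDPanel`,
which wraps either raw genotype dosages or per-block correlation matrices.

Coordinates are 1-based inclusive internally (the GWAS summary-statistics
convention); BED intervals are converted at the boundary.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: canonical column order for a summary-statistics table
SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class SumstatsError(ValueError):
    """Raised for malformed or empty summary-statistics input."""


def validate_sumstats(df: pd.DataFrame, *, drop_invalid: bool = True) -> pd.DataFrame:
    """Type and validate a summary-statistics table.

    Rows violating row-level invariants (``se > 0``, ``eaf`` in (0,1),
    ``pvalue`` in (0,1], non-empty distinct alleles) are dropped with a
    logged count when *drop_invalid* is true, otherwise raise.
    Duplicate (chrom, pos, alleles) keys always raise.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"missing required column(s): {', '.join(missing)}")
    out = df.loc[:, SUMSTAT_COLUMNS].copy()
    out["variant_id"] = out["variant_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for col in ("eaf", "beta", "se", "pvalue"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["pos"] = pd.to_numeric(out["pos"], errors="coerce")
    out["n"] = pd.to_numeric(out["n"], errors="coerce")
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()

    ok = (
        out[["pos", "eaf", "beta", "se", "pvalue", "n"]].notna().all(axis=1)
        & (out["se"] > 0)
        & (out["eaf"] > 0)
        & (out["eaf"] < 1)
        & (out["pvalue"] > 0)
        & (out["pvalue"] <= 1)
        & (out["n"] > 0)
        & (out["effect_allele"] != "")
        & (out["other_allele"] != "")
        & (out["effect_allele"] != out["other_allele"])
    )
    n_bad = int((~ok).sum())
    if n_bad:
        if not drop_invalid:
            raise SumstatsError(f"{n_bad} row(s) violate summary-statistics invariants")
        logger.warning("dropped %d row(s) failing summary-statistics invariants", n_bad)
        out = out.loc[ok]
    if out.empty:
        raise SumstatsError("no valid summary-statistics rows")
    out["pos"] = out["pos"].astype(np.int64)

    key = out["chrom"].str.cat(
        [
            out["pos"].astype(str),
            np.minimum(out["effect_allele"], out["other_allele"]),
            np.maximum(out["effect_allele"], out["other_allele"]),
        ],
        sep=":",
    )
    if key.duplicated().any():
        dups = key[key.duplicated()].unique()[:5]
        raise SumstatsError(f"duplicate variant keys: {', '.join(dups)}")
    return out.reset_index(drop=True)


def read_gwas_sumstats(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a (possibly gzipped) summary-statistics TSV into the canonical schema.

    Parameters
    ----------
    path
        Tab-separated file with one row per variant.
    column_map
        Maps each canonical column name (see :data:`SUMSTAT_COLUMNS`) to the
        column name used in the file. Omitted entries default to the
        canonical name itself.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in SUMSTAT_COLUMNS}
    raw = pd.read_csv(path, sep="\t", dtype={column_map.get("chrom", "chrom"): str})
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SumstatsError(f"missing required column(s) in {path.name}: {', '.join(missing)}")
    return validate_sumstats(raw.rename(columns=rename))


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table as TSV (gzip if the path ends in .gz)."""
    cols = SUMSTAT_COLUMNS + [c for c in df.columns if c not in SUMSTAT_COLUMNS]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / annotation handling
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3(+) file (0-based half-open) into (chrom, start, end, *rest)."""
    rows = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from None
            if end < start:
                raise ValueError(f"{path}: malformed BED line {lineno}: end < start")
            rows.append((parts[0], start, end, *parts[3:4]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"][: max((len(r) for r in rows), default=4)])


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", index=False, header=False)


class AnnotationMatrix:
    """Binary variant x annotation indicator matrix.

    A variant absent from an annotation carries an explicit 0; requesting a
    variant unknown to the matrix also yields a zero row (with the number of
    such variants available to callers who want to log it).
    """

    def __init__(self, frame: pd.DataFrame):
        vals = frame.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("annotation indicators must be 0/1")
        self._frame = frame.astype(np.int8)
        self._index = {v: i for i, v in enumerate(frame.index)}

    @property
    def variant_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def names(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def subset(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Indicator rows for *variant_ids*; unknown variants get all-zero rows."""
        out = np.zeros((len(variant_ids), len(self._frame.columns)), dtype=np.int8)
        n_missing = 0
        vals = self._frame.to_numpy()
        for i, vid in enumerate(variant_ids):
            j = self._index.get(vid)
            if j is None:
                n_missing += 1
            else:
                out[i] = vals[j]
        if n_missing:
            logger.info("%d variant(s) absent from annotation matrix; indicators set to 0", n_missing)
        return out

    @classmethod
    def from_bed_files(
        cls,
        paths: Sequence[str | Path],
        variants: pd.DataFrame,
        names: Sequence[str] | None = None,
    ) -> "AnnotationMatrix":
        """Build indicators from one BED file per annotation.

        ``z[j, k] = 1`` iff the variant's (1-based) position, converted to
        0-based, falls inside any interval of annotation *k* on the same
        chromosome.
        """
        if names is None:
            names = [Path(p).name.removesuffix(".gz").removesuffix(".bed") for p in paths]
        if len(names) != len(paths):
            raise ValueError("names and paths length mismatch")
        mat = np.zeros((len(variants), len(paths)), dtype=np.int8)
        chroms = variants["chrom"].astype(str).to_numpy()
        pos0 = variants["pos"].to_numpy() - 1  # 1-based -> 0-based
        for k, path in enumerate(paths):
            bed = read_bed(path)
            trees: dict[str, IntervalTree] = {}
            for chrom, grp in bed.groupby("chrom"):
                ivs = grp.loc[grp["end"] > grp["start"]]
                trees[str(chrom)] = IntervalTree.from_tuples(zip(ivs["start"], ivs["end"]))
            for j in range(len(variants)):
                tree = trees.get(chroms[j])
                if tree is not None and tree.overlaps_point(int(pos0[j])):
                    mat[j, k] = 1
        frame = pd.DataFrame(mat, index=variants["variant_id"].astype(str).to_numpy(), columns=list(names))
        return cls(frame)


# ---------------------------------------------------------------------------
# LD reference panel
# ---------------------------------------------------------------------------

class LDPanel:
    """LD reference: per-variant frequencies plus correlations.

    Backed either by a raw genotype-dosage matrix (empirical correlations) or
    by analytic per-block correlation matrices (zero correlation across
    blocks). The ``variants`` table carries id, chrom, pos, alleles, the
    effect-allele frequency and the dosage variance used by the joint-model
    algebra.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        genotypes: np.ndarray | None = None,
        block_corr: dict[int, np.ndarray] | None = None,
    ):
        required = {"variant_id", "chrom", "pos", "effect_allele", "other_allele", "freq", "var", "block"}
        if not required.issubset(variants.columns):
            raise ValueError(f"panel variants table missing {required - set(variants.columns)}")
        if genotypes is None and block_corr is None:
            raise ValueError("panel needs genotypes or per-block correlation matrices")
        self.variants = variants.reset_index(drop=True)
        self.genotypes = genotypes
        self._block_corr = block_corr
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray, variants: pd.DataFrame) -> "LDPanel":
        variants = variants.copy()
        variants["freq"] = genotypes.mean(axis=0) / 2.0
        variants["var"] = genotypes.var(axis=0)
        return cls(variants, genotypes=genotypes)

    @classmethod
    def from_block_corr(cls, variants: pd.DataFrame, block_corr: dict[int, np.ndarray]) -> "LDPanel":
        variants = variants.copy()
        if "var" not in variants.columns:
            variants["var"] = 2.0 * variants["freq"] * (1.0 - variants["freq"])
        return cls(variants, block_corr=block_corr)

    # -- lookups ----------------------------------------------------------
    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def indices(self, variant_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[v] for v in variant_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} not in LD panel") from None

    def freq(self, variant_ids: Sequence[str]) -> np.ndarray:
        return self.variants["freq"].to_numpy()[self.indices(variant_ids)]

    def dosage_var(self, variant_ids: Sequence[str]) -> np.ndarray:
        return self.variants["var"].to_numpy()[self.indices(variant_ids)]

    def corr(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Correlation matrix R for the given variants (cross-block r = 0)."""
        idx = self.indices(variant_ids)
        if self.genotypes is not None:
            sub = self.genotypes[:, idx].astype(float)
            sd = sub.std(axis=0)
            if np.any(sd == 0):
                bad = np.asarray(variant_ids)[sd == 0]
                raise ValueError(f"monomorphic variant(s) in panel: {', '.join(map(str, bad[:5]))}")
            centred = (sub - sub.mean(axis=0)) / sd
            R = centred.T @ centred / sub.shape[0]
        else:
            blocks = self.variants["block"].to_numpy()[idx]
            R = np.zeros((len(idx), len(idx)))
            for b in np.unique(blocks):
                mask = blocks == b
                block_ids = np.flatnonzero(self.variants["block"].to_numpy() == b)
                local = {g: i for i, g in enumerate(block_ids)}
                sub_idx = [local[i] for i in idx[mask]]
                R[np.ix_(mask, mask)] = self._block_corr[int(b)][np.ix_(sub_idx, sub_idx)]
        np.fill_diagonal(R, 1.0)
        return R


# ---------------------------------------------------------------------------
# Allele harmonisation
# ---------------------------------------------------------------------------

def _is_ambiguous(ea: str, oa: str) -> bool:
    return {ea, oa} in _AMBIGUOUS_PAIRS


def harmonise_alleles(
    a: pd.DataFrame,
    b: pd.DataFrame | LDPanel,
    *,
    freq_tol: float = 0.2,
    drop_ambiguous_band: tuple[float, float] = (0.4, 0.6),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Align two variant tables on (chrom, pos) and allele identity.

    Rules, applied per shared position:

    * same allele pair, same orientation: kept as is;
    * same pair, swapped orientation: *b*'s ``beta`` sign is flipped and its
      ``eaf`` complemented;
    * strand-ambiguous A/T or C/G pairs whose *a*-side eaf lies inside
      *drop_ambiguous_band*: dropped;
    * allele-frequency mismatch ``|a.eaf - b.eaf| > freq_tol`` after
      alignment: dropped (reference-mismatch guard);
    * anything else (allele mismatch): dropped.

    Returns (a_aligned, b_aligned, flip_log); the log has one row per
    modified or dropped variant with a ``action`` column.
    """
    if isinstance(b, LDPanel):
        b_df = b.variants.rename(columns={"freq": "eaf"}).copy()
    else:
        b_df = b.copy()
    a = a.copy()
    a["_key"] = a["chrom"].astype(str) + ":" + a["pos"].astype(str)
    b_df["_key"] = b_df["chrom"].astype(str) + ":" + b_df["pos"].astype(str)
    merged = a.merge(b_df, on="_key", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ValueError("no overlapping variants between the two tables")

    keep_a, keep_b, log_rows = [], [], []
    lo, hi = drop_ambiguous_band
    for _, row in merged.iterrows():
        ea_a, oa_a = row["effect_allele_a"], row["other_allele_a"]
        ea_b, oa_b = row["effect_allele_b"], row["other_allele_b"]
        vid = row["variant_id_a"]
        if _is_ambiguous(ea_a, oa_a) and lo < row["eaf_a"] < hi:
            log_rows.append((vid, "dropped_ambiguous"))
            continue
        if (ea_a, oa_a) == (ea_b, oa_b):
            flipped = False
        elif (ea_a, oa_a) == (oa_b, ea_b):
            flipped = True
        else:
            log_rows.append((vid, "dropped_allele_mismatch"))
            continue
        eaf_b = row.get("eaf_b", np.nan)
        if flipped and pd.notna(eaf_b):
            eaf_b = 1.0 - eaf_b
        if pd.notna(eaf_b) and abs(row["eaf_a"] - eaf_b) > freq_tol:
            log_rows.append((vid, "dropped_freq_mismatch"))
            continue
        if flipped:
            log_rows.append((vid, "flipped"))
        keep_a.append(row.name)
        keep_b.append((row.name, flipped))

    if not keep_a:
        raise ValueError("no variants remain after allele harmonisation")

    a_cols = [c for c in merged.columns if c.endswith("_a")]
    a_out = merged.loc[keep_a, a_cols].rename(columns=lambda c: c[:-2]).reset_index(drop=True)
    b_cols = [c for c in merged.columns if c.endswith("_b")]
    b_out = merged.loc[[i for i, _ in keep_b], b_cols].rename(columns=lambda c: c[:-2]).reset_index(drop=True)
    flips = np.array([f for _, f in keep_b])
    if "beta" in b_out.columns:
        b_out.loc[flips, "beta"] = -b_out.loc[flips, "beta"]
    if "eaf" in b_out.columns:
        b_out.loc[flips, "eaf"] = 1.0 - b_out.loc[flips, "eaf"]
    b_out.loc[flips, ["effect_allele", "other_allele"]] = b_out.loc[
        flips, ["other_allele", "effect_allele"]
    ].to_numpy()
    flip_log = pd.DataFrame(log_rows, columns=["variant_id", "action"])
    n_dropped = int((flip_log["action"] != "flipped").sum())
    if n_dropped:
        logger.info("harmonisation dropped %d variant(s)", n_dropped)
    return a_out, b_out, flip_log
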