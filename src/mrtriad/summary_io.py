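"""Reading, validating, and writing GWAS summary-statistic and result tables.

The canonical on-disk format is tab-separated text with a header, read and
written gzip-transparently.  Columns from arbitrary consortium dialects
(FinnGen, GWAS Catalog, ...) are renamed through an explicit ``column_map``.
Coordinates are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for a summary-statistics table
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

MANDATORY_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]


class SummaryStatsError(ValueError):
    """Raised when a summary-statistics table cannot be read or validated."""


@dataclasses.dataclass
class SummaryStats:
    """Per-SNP association table for one trait.

    ``table`` holds one row per SNP with the canonical columns: ``snp_id``,
    ``chrom``, ``pos`` (1-based), ``effect_allele``, ``other_allele``,
    ``eaf`` (may be NaN), ``beta``, ``se`` (> 0), ``pval`` (in (0, 1]) and
    ``n`` (may be NaN).
    """

    trait_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SummaryStatsError(f"missing canonical columns: {missing}")
        self.table = self.table[CANONICAL_COLUMNS].reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "SummaryStats":
        """Row-subset preserving order; returns a new SummaryStats."""
        return SummaryStats(self.trait_id, self.table.loc[mask].reset_index(drop=True))


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Drop rows violating the SummaryStats invariants.

    Returns the surviving rows (original order) and an audit Counter keyed by
    drop reason.  Counts plus survivors always add up to the input row count:
    each row is attributed to the first violated rule.
    """
    audit: Counter = Counter()
    df = df.copy()

    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    checks = [
        (
            "nonpositive_se",
            ~(df["se"] > 0),
        ),
        (
            "pval_out_of_range",
            ~((df["pval"] > 0) & (df["pval"] <= 1)),
        ),
        (
            "invalid_alleles",
            ~(
                df["effect_allele"].isin(VALID_ALLELES)
                & df["other_allele"].isin(VALID_ALLELES)
                & (df["effect_allele"] != df["other_allele"])
            ),
        ),
        (
            "eaf_out_of_range",
            df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)),
        ),
        (
            "missing_beta",
            df["beta"].isna(),
        ),
        (
            "missing_position",
            df["pos"].isna(),
        ),
        (
            "duplicate_snp_id",
            df["snp_id"].duplicated(keep="first"),
        ),
    ]

    dropped = pd.Series(False, index=df.index)
    for reason, bad in checks:
        newly = bad & ~dropped
        n_bad = int(newly.sum())
        if n_bad:
            audit[reason] += n_bad
        dropped |= bad

    clean = df.loc[~dropped].reset_index(drop=True)
    if "eaf" not in clean.columns:
        clean["eaf"] = np.nan
    if "n" not in clean.columns:
        clean["n"] = np.nan
    clean["pos"] = clean["pos"].astype(np.int64)
    return clean, audit


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    sep: str = "\t",
) -> tuple[SummaryStats, Counter]:
    """Read a delimited (plain or gzip) summary-statistics file.

    Parameters
    ----------
    path:
        Delimited text file; ``.gz`` suffix handled transparently.
    column_map:
        Mapping of source column name -> canonical name; source columns that
        do not appear in the mapping are ignored.  ``None`` means the file is
        already canonically named.
    trait_id:
        Label for the trait; defaults to the file stem.

    Returns
    -------
    (SummaryStats, Counter)
        The validated table plus an audit log of dropped rows.

    Raises
    ------
    SummaryStatsError
        If a mandatory column is absent or no row survives validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, compression="infer", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    clean, audit = validate_rows(df)
    if clean.empty:
        raise SummaryStatsError(f"{path}: no rows survive validation ({dict(audit)})")
    if trait_id is None:
        trait_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return SummaryStats(trait_id, clean), audit


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a SummaryStats table in canonical TSV form (gzip by suffix)."""
    _write_table(stats.table, path)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic layout.

    Column order is taken from the frame; floats are serialized with 6
    significant digits so that a read-back reproduces values to that
    precision.  An empty table is an error.
    """
    if table is None or len(table) == 0:
        raise ValueError(f"refusing to write empty result table to {path}")
    _write_table(table, path)


def _write_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", compression="infer")


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write the JSON run-manifest (thresholds, seeds, input digests)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
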