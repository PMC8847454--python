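"""Reading, validating and filtering GWAS summary-statistic tables.

A summary table holds one row per variant with the standard fields
``SNP, effect_allele, other_allele, eaf, beta, se, pval, n``; arbitrary
column names in the source file are supported through a ``column_map``.
Collections of records are plain :class:`pandas.DataFrame` objects with
those canonical column names (lower-case ``snp``), which is what the
harmonization and estimator layers consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "MANDATORY",
    "RowReject",
    "ReadResult",
    "DuplicateVariantError",
    "validate_records",
    "read_summary_table",
    "write_summary_table",
    "filter_genome_wide",
    "InstrumentStrength",
    "f_statistic",
]

#: Canonical column order of an in-memory summary table.
COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
#: Fields that must be present and parseable; eaf and n may be missing.
MANDATORY = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class DuplicateVariantError(ValueError):
    """Duplicate variant identifiers in one table (upstream clumping failure)."""


class RowReject(NamedTuple):
    """A rejected input row: 1-based data-row number, variant id, reason."""

    row: int
    snp: str
    reason: str


class ReadResult(NamedTuple):
    """Validated records plus the rows rejected with reasons."""

    records: pd.DataFrame
    rejected: list[RowReject]


def _standardize(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename source columns to the canonical schema via ``column_map``
    (standard field -> source column name)."""
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise KeyError(f"column_map refers to absent columns: {missing}")
        df = df.rename(columns={src: std for std, src in column_map.items()})
    # accept the standard header spelled with SNP upper-case
    df = df.rename(columns={"SNP": "snp"})
    absent = [c for c in MANDATORY if c not in df.columns]
    if absent:
        raise KeyError(f"mandatory columns missing from summary table: {absent}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[COLUMNS]


def validate_records(df: pd.DataFrame) -> ReadResult:
    """Enforce per-record invariants, splitting rows into kept and rejected.

    Invariants: finite beta; se > 0; p in (0, 1]; eaf, when present, in
    [0, 1]; alleles upper-case A/C/G/T strings with effect != other.
    Duplicate variant ids raise :class:`DuplicateVariantError` rather than
    being silently deduplicated.
    """
    df = df.copy()
    for c in ("eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("snp", "effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.strip().str.upper()
    df["snp"] = df["snp"].str.replace("RS", "rs", regex=False)

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    flag(~np.isfinite(df["beta"]), "non-finite beta")
    flag(~(df["se"] > 0) | ~np.isfinite(df["se"]), "non-positive SE")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "p-value outside (0,1]")
    flag(df["eaf"].notna() & ~df["eaf"].between(0, 1), "EAF outside [0,1]")
    ok_alleles = df["effect_allele"].str.match(_ALLELE_RE) & df[
        "other_allele"
    ].str.match(_ALLELE_RE)
    flag(~ok_alleles, "invalid allele code")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")

    bad = reasons != ""
    rejected = [
        RowReject(int(i) + 1, str(df.at[i, "snp"]), str(reasons[i]))
        for i in df.index[bad]
    ]
    kept = df.loc[~bad].reset_index(drop=True)

    dup = kept["snp"][kept["snp"].duplicated()]
    if len(dup):
        raise DuplicateVariantError(
            f"duplicate variant ids in table: {sorted(set(dup))}; "
            "inputs must be clumped to independent variants"
        )
    return ReadResult(kept, rejected)


def read_summary_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ReadResult:
    """Read a tab-delimited GWAS summary table into validated records.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Mapping of standard field name (``snp``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to
        the column name used in the file.  Omit for files already using
        the standard header.

    Returns
    -------
    ReadResult
        ``records`` (canonical columns, row order preserved) and the
        ``rejected`` rows with 1-based row numbers and reasons.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    return validate_records(_standardize(raw, column_map))


def write_summary_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the standard TSV schema (header ``SNP`` upper-case)."""
    out = records[COLUMNS].rename(columns={"snp": "SNP"})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_genome_wide(records: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Keep variants reaching genome-wide significance, p strictly < threshold.

    Order is preserved; the default threshold is the conventional
    5 x 10^-8.
    """
    if not (0.0 < threshold < 1.0) and threshold != 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return records.loc[records["pval"] < threshold].reset_index(drop=True)


@dataclass(frozen=True)
class InstrumentStrength:
    """Joint instrument strength of K variants explaining R^2 of an exposure.

    F = R^2 (N - 1 - K) / ((1 - R^2) K); values well above 10 indicate
    weak-instrument bias is negligible in two-sample MR.
    """

    r_squared: float
    n_gwas: int
    k: int
    f_stat: float


def f_statistic(r_squared: float, n_gwas: int, k: int) -> InstrumentStrength:
    """F-statistic for K instruments jointly explaining ``r_squared`` of the
    exposure variance in a discovery GWAS of ``n_gwas`` individuals."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError(f"r_squared must lie in [0, 1), got {r_squared}")
    if k < 1 or n_gwas <= k + 1:
        raise ValueError(f"need n_gwas > k + 1 >= 2, got n_gwas={n_gwas}, k={k}")
    f = r_squared * (n_gwas - 1 - k) / ((1.0 - r_squared) * k)
    return InstrumentStrength(r_squared, n_gwas, k, f)
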