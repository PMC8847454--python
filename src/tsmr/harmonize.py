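"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs the per-variant exposure effect gamma_hat and outcome
effect Gamma_hat expressed for the *same* effect allele.  Summary tables
from different consortia may report the opposite allele (sign flip),
the opposite strand (allele complement), or both; palindromic variants
(A/T, G/C) cannot be resolved from allele codes alone and are handled by
an explicit policy using effect-allele frequencies.

After alignment every instrument is additionally oriented so that
gamma_hat >= 0 (flipping both effects together) — the sign convention
MR-Egger requires; all estimators' point estimates are invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COMPLEMENT",
    "HARMONIZED_COLUMNS",
    "InstrumentSet",
    "is_palindromic",
    "complement_allele",
    "read_proxy_map",
    "harmonize",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "snp",
    "gamma_hat",
    "sigma_x",
    "Gamma_hat",
    "sigma_y",
    "aligned_allele",
    "other_allele",
    "eaf_exposure",
    "eaf_outcome",
    "flipped",
    "reoriented",
    "palindromic",
]


def complement_allele(allele: str) -> str:
    """Reverse complement (plain complement for single bases)."""
    return "".join(COMPLEMENT[b] for b in reversed(allele))


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or G/C variant: strand orientation is ambiguous in summary data."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class InstrumentSet:
    """Analysis-ready harmonized instruments for one exposure-outcome pair.

    ``table`` has one row per retained instrument (HARMONIZED_COLUMNS);
    ``dropped`` records every excluded exposure variant with its reason,
    so that |table| + |dropped| equals the number of exposure variants.
    ``flipped`` marks instruments whose outcome effect sign was inverted
    during allele alignment; ``reoriented`` marks the subsequent joint
    sign flip enforcing gamma_hat >= 0.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    ancestry_label: str = ""
    dropped: list[tuple[str, str]] = field(default_factory=list)
    proxies_used: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def require_instruments(self) -> "InstrumentSet":
        if len(self.table) == 0:
            raise ValueError(
                f"no usable instruments for {self.exposure_name} -> "
                f"{self.outcome_name}: {self.dropped}"
            )
        return self

    def write(self, table_path: str | Path, drop_path: str | Path | None = None) -> None:
        """Write the instrument table (TSV) and optional drop log (TSV)."""
        self.table.to_csv(table_path, sep="\t", index=False)
        if drop_path is not None:
            pd.DataFrame(self.dropped, columns=["snp", "reason"]).to_csv(
                drop_path, sep="\t", index=False
            )


def read_proxy_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (query_snp, proxy_snp) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("proxy map needs two columns: query_snp, proxy_snp")
    q, p = df.columns[:2]
    return dict(zip(df[q].str.strip(), df[p].str.strip()))


def _align_one(erow, orow, policy: str, eaf_tolerance: float):
    """Align one outcome record to the exposure orientation.

    Returns (Gamma, eaf_outcome, flipped, palindromic) or raises
    ValueError with the drop reason.
    """
    ea, oa = erow.effect_allele, erow.other_allele
    b_ea, b_oa = orow.effect_allele, orow.other_allele
    beta = float(orow.beta)
    eaf = float(orow.eaf) if np.isfinite(orow.eaf) else np.nan

    if is_palindromic(ea, oa):
        if policy == "drop":
            raise ValueError("palindromic")
        if policy != "strict":
            raise ValueError(f"unknown palindrome policy {policy!r}")
        # allele codes cannot resolve strand; orient by allele frequency
        if {b_ea, b_oa} != {ea, oa}:
            raise ValueError("allele mismatch")
        e_eaf = float(erow.eaf) if np.isfinite(erow.eaf) else np.nan
        o_eaf = eaf if b_ea == ea else (1.0 - eaf if np.isfinite(eaf) else np.nan)
        if (
            not np.isfinite(e_eaf)
            or not np.isfinite(o_eaf)
            or abs(e_eaf - 0.5) <= eaf_tolerance
            or abs(o_eaf - 0.5) <= eaf_tolerance
        ):
            raise ValueError("palindromic, ambiguous frequency")
        same_side = (e_eaf - 0.5) * (o_eaf - 0.5) > 0
        if b_ea != ea:  # re-express for the exposure's allele labelling
            beta = -beta
        if same_side:
            return beta, o_eaf, b_ea != ea, True
        return -beta, 1.0 - o_eaf, b_ea == ea, True

    for flip_strand in (False, True):
        cea = complement_allele(b_ea) if flip_strand else b_ea
        coa = complement_allele(b_oa) if flip_strand else b_oa
        if (cea, coa) == (ea, oa):
            return beta, eaf, False, False
        if (cea, coa) == (oa, ea):
            return -beta, (1.0 - eaf if np.isfinite(eaf) else np.nan), True, False
    raise ValueError("allele mismatch")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    policy: str = "strict",
    eaf_tolerance: float = 0.08,
    proxy_map: Mapping[str, str] | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    ancestry_label: str = "",
) -> InstrumentSet:
    """Harmonize exposure and outcome summary records into an InstrumentSet.

    For each exposure variant found in the outcome table (after applying
    the optional pre-computed proxy mapping), alleles are aligned by
    direct match, sign flip (swapped alleles; outcome beta negated and
    EAF reflected), or strand complement; irreconcilable pairs are
    dropped with reason ``allele mismatch`` and absent variants with
    ``not found``.  Palindromic variants follow ``policy``:

    ``strict``
        dropped when either study's EAF is missing or within
        ``eaf_tolerance`` of 0.5, otherwise oriented by frequency;
    ``drop``
        always dropped.

    Finally each instrument is oriented so gamma_hat >= 0 by flipping
    both effects together (the MR-Egger sign convention).
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["snp"].duplicated().any():
            raise ValueError(f"duplicate variant ids in {name} table")

    out = outcome
    proxies_used: list[tuple[str, str]] = []
    if proxy_map:
        present = set(out["snp"])
        renames = {
            proxy: query
            for query, proxy in proxy_map.items()
            if query not in present and proxy in present
        }
        if renames:
            out = out.copy()
            out["snp"] = out["snp"].map(lambda s: renames.get(s, s))
            proxies_used = [(q, p) for p, q in renames.items()]
    out_by_snp = {row.snp: row for row in out.itertuples(index=False)}

    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for erow in exposure.itertuples(index=False):
        orow = out_by_snp.get(erow.snp)
        if orow is None:
            dropped.append((erow.snp, "not found"))
            continue
        try:
            Gamma, o_eaf, flipped, palin = _align_one(erow, orow, policy, eaf_tolerance)
        except ValueError as exc:
            dropped.append((erow.snp, str(exc)))
            continue
        gamma = float(erow.beta)
        e_eaf = float(erow.eaf) if np.isfinite(erow.eaf) else np.nan
        ea, oa = erow.effect_allele, erow.other_allele
        reoriented = gamma < 0
        if reoriented:
            gamma, Gamma = -gamma, -Gamma
            ea, oa = oa, ea
            e_eaf = 1.0 - e_eaf if np.isfinite(e_eaf) else np.nan
            o_eaf = 1.0 - o_eaf if np.isfinite(o_eaf) else np.nan
        rows.append(
            {
                "snp": erow.snp,
                "gamma_hat": gamma,
                "sigma_x": float(erow.se),
                "Gamma_hat": Gamma,
                "sigma_y": float(orow.se),
                "aligned_allele": ea,
                "other_allele": oa,
                "eaf_exposure": e_eaf,
                "eaf_outcome": o_eaf,
                "flipped": bool(flipped),
                "reoriented": bool(reoriented),
                "palindromic": bool(palin),
            }
        )
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        ancestry_label=ancestry_label,
        table=table,
        dropped=dropped,
        proxies_used=proxies_used,
    )
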