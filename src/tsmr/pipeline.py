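"""Orchestration of a full two-sample MR run from a YAML configuration.

A run covers one ancestry stratum: several exposures (e.g. T2D plus
glycaemic and anthropometric traits) against one outcome, each passed
through instrument filtering, harmonization, every requested estimator,
and pleiotropy diagnostics.  Outputs are plain TSV/JSON under a run
directory, plus a machine-readable manifest and a timestamped text log;
result tables are byte-identical across reruns with the same config and
seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import estimators, sumstats
from .harmonize import harmonize as _harmonize, read_proxy_map

__all__ = ["TraitSource", "AnalysisConfig", "load_config", "run_mr_analysis"]

#: Below this many usable instruments a (reverse-direction) analysis is
#: flagged as underpowered; ratio tables are still produced.
MIN_INSTRUMENTS_WARN = 4


@dataclass(frozen=True)
class TraitSource:
    """One summary-statistics table: trait name, path, optional column map."""

    name: str
    path: str
    column_map: Mapping[str, str] | None = None


@dataclass
class AnalysisConfig:
    """Configuration of one MR run (one ancestry stratum)."""

    exposures: list[TraitSource]
    outcome: TraitSource
    ancestry_label: str = ""
    methods: tuple[str, ...] = ("ivw", "simple_median", "weighted_median", "egger")
    n_boot: int = 10_000
    seed: int | None = None
    gwas_threshold: float = 5e-8
    palindrome_policy: str = "strict"
    eaf_tolerance: float = 0.08
    proxy_map: str | None = None
    reverse_direction: bool = False
    out_dir: str = "mr_run"

    def __post_init__(self) -> None:
        boot_methods = {"simple_median", "weighted_median"} & set(self.methods)
        if boot_methods and self.seed is None:
            raise ValueError(
                f"seed is required when bootstrap methods {sorted(boot_methods)} "
                "are selected"
            )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def src(d: Mapping) -> TraitSource:
        return TraitSource(
            name=str(d["name"]),
            path=str((base / d["path"]).resolve()),
            column_map=d.get("column_map"),
        )

    kwargs = {k: v for k, v in raw.items() if k not in ("exposures", "outcome")}
    if "methods" in kwargs:
        kwargs["methods"] = tuple(kwargs["methods"])
    if kwargs.get("proxy_map"):
        kwargs["proxy_map"] = str((base / kwargs["proxy_map"]).resolve())
    return AnalysisConfig(
        exposures=[src(d) for d in raw["exposures"]],
        outcome=src(raw["outcome"]),
        **kwargs,
    )


def _load_trait(source: TraitSource, log: list[str]) -> pd.DataFrame:
    records, rejected = sumstats.read_summary_table(source.path, source.column_map)
    for rej in rejected:
        log.append(f"{source.name}: rejected row {rej.row} ({rej.snp}): {rej.reason}")
    return records


def run_mr_analysis(config: AnalysisConfig) -> dict:
    """Run the analysis matrix and write the result bundle to ``out_dir``.

    For each exposure: filter instruments at the genome-wide threshold,
    harmonize against the outcome, run every requested estimator, and
    write the per-variant ratio table and drop log.  An exposure with
    zero usable instruments yields an explicit failure record and the
    run continues.  ``reverse_direction`` swaps the roles of exposure
    and outcome tables (instruments are then selected from the original
    outcome study) and warns when fewer than 4 usable instruments
    remain.

    Returns the bundle: results DataFrame, per-exposure ratio tables,
    failures, and the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run started {datetime.datetime.now().isoformat()}"]
    proxy_map = read_proxy_map(config.proxy_map) if config.proxy_map else None

    outcome_records = _load_trait(config.outcome, log)
    result_rows: list[dict] = []
    failures: list[dict] = []
    ratio_tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, dict] = {}

    for exposure in config.exposures:
        exp_records = _load_trait(exposure, log)
        if config.reverse_direction:
            exp_tab, out_tab = outcome_records, exp_records
            pair = (config.outcome.name, exposure.name)
        else:
            exp_tab, out_tab = exp_records, outcome_records
            pair = (exposure.name, config.outcome.name)

        instruments_in = sumstats.filter_genome_wide(exp_tab, config.gwas_threshold)
        inst = _harmonize(
            instruments_in,
            out_tab,
            policy=config.palindrome_policy,
            eaf_tolerance=config.eaf_tolerance,
            proxy_map=proxy_map,
            exposure_name=pair[0],
            outcome_name=pair[1],
            ancestry_label=config.ancestry_label,
        )
        counts[exposure.name] = {
            "instruments_significant": int(len(instruments_in)),
            "instruments_used": len(inst),
            "dropped": inst.dropped,
            "proxies_used": inst.proxies_used,
        }
        log.append(
            f"{' -> '.join(pair)}: {len(inst)} instruments used, "
            f"{len(inst.dropped)} dropped"
        )
        if len(inst) == 0:
            failures.append(
                {"exposure": pair[0], "outcome": pair[1], "error": "no usable instruments"}
            )
            log.append(f"{pair[0]}: FAILED (no usable instruments)")
            continue
        if len(inst) < MIN_INSTRUMENTS_WARN:
            msg = (
                f"{pair[0]} -> {pair[1]}: only {len(inst)} usable instruments; "
                "estimates will be underpowered"
            )
            warnings.warn(msg, stacklevel=2)
            log.append(f"warning: {msg}")

        res = estimators.estimate_all(
            inst, methods=config.methods, n_boot=config.n_boot, seed=config.seed
        )
        res.insert(0, "outcome", pair[1])
        res.insert(0, "exposure", pair[0])
        res.insert(0, "ancestry", config.ancestry_label)
        result_rows.append(res)

        ratios = estimators.ratio_table(inst)
        ratio_tables[exposure.name] = ratios
        safe = exposure.name.replace(" ", "_")
        ratios.to_csv(out / f"ratios_{safe}.tsv", sep="\t", index=False)
        inst.write(out / f"instruments_{safe}.tsv", out / f"drops_{safe}.tsv")

    results = (
        pd.concat(result_rows, ignore_index=True) if result_rows else pd.DataFrame()
    )
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    results.to_json(out / "results.json", orient="records", indent=1)

    manifest = {
        "config": _config_dict(config),
        "counts": counts,
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.append("run finished")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {
        "results": results,
        "ratio_tables": ratio_tables,
        "failures": failures,
        "manifest": manifest,
    }


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    d["methods"] = list(config.methods)
    return d
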