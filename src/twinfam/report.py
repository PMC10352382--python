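"""Pipeline orchestration and publication-style table rendering.

`run_pipeline` ties the stages together — meta-analysis of the packaged
study table, cohort simulation, preprocessing, descriptives, the CTD fit and
the NTFD ladder — writing machine-readable JSON and CSV tables whose shapes
mirror the study's published tables.  Every output embeds the seed and a
hash of the configuration so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, meta
from .fit import FamilyData, fit_model, run_ladder
from .model import model_presets, standardize_components
from .preprocess import dyad_correlations, run_preprocess
from .simulate import SimConfig, default_config, simulate_population, summarize

log = logging.getLogger("twinfam")


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    out_dir: str = "results"
    seed: int = 0
    stages: tuple = ("meta", "simulate", "preprocess", "descriptives", "ctd", "ladder")
    n_mz_families: int = 498
    n_dz_families: int = 439
    nonadditive_mode: str = "dominance"
    ladder_starts: int = 2
    input_table: str | None = None  # optional pre-existing family CSV
    sim: SimConfig | None = None

    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in vars(self).items() if k != "sim"}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(obj: dict, config: PipelineConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed, **obj}


def render_meta_tables(out_dir: Path, config: PipelineConfig) -> dict:
    df = datasets.load_branigan_subgroups()
    table = meta.meta_table(df)
    table.to_csv(out_dir / "table1_replication.csv", index=False)
    grand = meta.grand_mean_report(df)
    payload = _stamp({"grand_means": grand}, config)
    (out_dir / "meta_grand_means.json").write_text(json.dumps(payload, indent=2))
    log.info("meta: %d subgroups, grand means %s", grand["n_studies"], grand)
    return payload


def render_dyads(table: pd.DataFrame, out_dir: Path, seed: int) -> pd.DataFrame:
    dyads = dyad_correlations(table, seed=seed)
    dyads.to_csv(out_dir / "dyad_correlations.csv", index=False)
    return dyads


def render_ladder(report, out_dir: Path) -> None:
    report.comparisons.to_csv(out_dir / "ladder.csv", index=False)
    rows = []
    for name, fit in {**report.baselines, **{f"{k} (pruned)": v for k, v in report.pruned.items()}}.items():
        comps = fit.components or {}
        rows.append({"model": name, "AIC": fit.AIC, "BIC": fit.BIC,
                     **{c: comps.get(c, np.nan) for c in ("A", "N", "S", "T", "P", "rGE", "E")}})
    pd.DataFrame(rows).to_csv(out_dir / "components.csv", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a manifest of written artifacts.

    Raises with a stage-tagged message on any failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "seed": config.seed, "artifacts": []}
    table = None
    stage = None
    try:
        if "meta" in config.stages:
            stage = "meta"
            render_meta_tables(out_dir, config)
            manifest["artifacts"] += ["table1_replication.csv", "meta_grand_means.json"]

        if "simulate" in config.stages:
            stage = "simulate"
            sim = config.sim or default_config(
                seed=config.seed,
                n_mz_families=config.n_mz_families,
                n_dz_families=config.n_dz_families,
            )
            table, provenance = simulate_population(sim)
            table.to_csv(out_dir / "families.csv", index=False)
            (out_dir / "simulation_provenance.json").write_text(
                json.dumps(_stamp(provenance, config), indent=2, default=float)
            )
            manifest["artifacts"] += ["families.csv", "simulation_provenance.json"]
        elif config.input_table is not None:
            stage = "load"
            path = Path(config.input_table)
            if not path.exists():
                raise FileNotFoundError(path)
            table = pd.read_csv(path)

        if table is not None and "preprocess" in config.stages:
            stage = "preprocess"
            n_before = len(table)
            table = run_preprocess(table)
            log.info("preprocess: %d -> %d records (%d siblings over the age gap)",
                     n_before, len(table), table.attrs.get("siblings_removed", 0))

        if table is not None and "descriptives" in config.stages:
            stage = "descriptives"
            summarize(table).to_csv(out_dir / "descriptives.csv", index=False)
            render_dyads(table, out_dir, seed=config.seed)
            manifest["artifacts"] += ["descriptives.csv", "dyad_correlations.csv"]

        data = FamilyData.from_table(table) if table is not None else None

        if data is not None and "ctd" in config.stages:
            stage = "ctd"
            spec = model_presets(config.nonadditive_mode)["CTD-ACE"]
            twins_only = table[table["role"].isin(("twin1", "twin2"))]
            fit = fit_model(FamilyData.from_table(twins_only), spec, n_starts=config.ladder_starts)
            comps = fit.components
            ctd = {"A": comps["A"], "C": comps["S"] + comps["T"] + comps["P"] + comps["rGE"],
                   "E": comps["E"], "minus2LL": fit.minus2LL, "AIC": fit.AIC}
            (out_dir / "ctd_fit.json").write_text(json.dumps(_stamp(ctd, config), indent=2))
            manifest["artifacts"].append("ctd_fit.json")

        if data is not None and "ladder" in config.stages:
            stage = "ladder"
            report = run_ladder(data, nonadditive_mode=config.nonadditive_mode,
                                n_starts=config.ladder_starts)
            render_ladder(report, out_dir)
            manifest["artifacts"] += ["ladder.csv", "components.csv"]
            manifest["best_model"] = report.best_name
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
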