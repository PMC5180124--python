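"""End-to-end orchestration: simulate/load -> associate -> interact ->
rank -> model, with one reproducible report.

The report mirrors the shape of the analyses it aggregates: per-bin
father/non-kin standardized-association means +/- s.e. for both
comparison approaches, observed-minus-expected interaction proportions
with permutation p-values, the same-sire model tests, and the
sample-size bookkeeping behind every filter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .association import (
    AssociationIndex,
    build_between_period_dataset,
    build_paternity_cases,
    build_within_period_dataset,
)
from .datamodel import KinCategory
from .dominance import EloHistory
from .interactions import run_interaction_analysis
from .io import config_hash, read_tables, write_frame
from .models import (
    fit_association_lmm,
    fit_paternity_model,
    paternity_case_summary,
    tukey_within_bin,
)
from .synthetic_data import SimConfig, simulate

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Everything one reproducible pipeline run depends on."""

    simulate: bool = True
    data_dir: Optional[str] = None
    sim: SimConfig = Field(default_factory=SimConfig)

    min_hours_association: float = 30.0
    min_hours_early: float = 10.0
    min_hours_late: float = 60.0
    min_hours_paternity: float = 90.0

    permutation_iterations: int = 10_000
    analysis_seed: int = 0

    elo_start_rating: float = 1000.0
    elo_k: float = 100.0

    approaches: tuple[str, ...] = ("within", "between")
    include_infant_sex: bool = False
    reference_anchor: str = "period_start"


def _bin_profile(table: pd.DataFrame) -> list[dict]:
    """Per-bin mean +/- s.e. standardized association by kin category."""
    out = []
    for (b, kin), grp in table.groupby(["age_bin", "kin"], sort=True):
        z = grp["z"].astype(float)
        out.append(
            dict(
                age_bin=int(b),
                kin=str(kin),
                n=int(len(z)),
                mean_z=float(z.mean()),
                se_z=float(z.std(ddof=1) / np.sqrt(len(z))) if len(z) > 1 else float("nan"),
            )
        )
    return out


def _sample_sizes(table: pd.DataFrame) -> list[dict]:
    """Counts of males and MI pairs per age bin (Table-1 shape)."""
    out = []
    for b, grp in table.groupby("age_bin", sort=True):
        out.append(
            dict(
                age_bin=int(b),
                n_males=int(grp["male_id"].nunique()),
                n_mi_pairs=int(grp["infant_id"].nunique()),
                n_rows=int(len(grp)),
            )
        )
    return out


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run every pipeline stage and return (optionally write) the report."""
    if config.simulate:
        bundle, _truth = simulate(config.sim)
    else:
        if not config.data_dir:
            raise ValueError("data_dir required when simulate is false")
        bundle = read_tables(config.data_dir)

    report: dict = {
        "pipeline_version": __version__,
        "config_hash": config_hash(config.model_dump(mode="json")),
        "config": config.model_dump(mode="json"),
    }

    index = AssociationIndex(bundle)

    # --- association models ------------------------------------------
    builders = {"within": build_within_period_dataset, "between": build_between_period_dataset}
    datasets: dict[str, pd.DataFrame] = {}
    assoc_block: dict[str, dict] = {}
    for approach in config.approaches:
        table, flog = builders[approach](
            bundle, min_hours=config.min_hours_association, index=index
        )
        datasets[approach] = table
        entry: dict = {
            "filter_log": vars(flog),
            "sample_sizes": _sample_sizes(table) if not table.empty else [],
            "bin_profile": _bin_profile(table) if not table.empty else [],
        }
        if not table.empty and table["kin"].nunique() == 2:
            fit = fit_association_lmm(table, include_sex=config.include_infant_sex)
            entry["model"] = fit.to_dict()
            entry["within_bin_contrasts"] = tukey_within_bin(fit).to_dict(orient="records")
        else:
            logger.warning("approach %s: empty or single-category table, model skipped", approach)
        assoc_block[approach] = entry
    report["association"] = assoc_block

    # --- interactions -------------------------------------------------
    inter = run_interaction_analysis(
        bundle,
        iterations=config.permutation_iterations,
        seed=config.analysis_seed,
        early_min_hours=config.min_hours_early,
        late_min_hours=config.min_hours_late,
        reference_anchor=config.reference_anchor,
    )
    report["interactions"] = {
        "n_infants": {
            per: int((inter.summaries["period"] == per).sum())
            if not inter.summaries.empty
            else 0
            for per in ("EARLY", "LATE")
        },
        "tests": inter.tests.to_dict(orient="records"),
    }

    # --- dominance + paternity ----------------------------------------
    elo = EloHistory.from_log(
        bundle.dominance, start_rating=config.elo_start_rating, k=config.elo_k
    )
    cases = build_paternity_cases(bundle, min_hours=config.min_hours_paternity, index=index)
    paternity_block: dict = dict(paternity_case_summary(cases))
    if len(cases):
        ranks = []
        for rec in cases.itertuples(index=False):
            try:
                ranks.append(
                    elo.ordinal_rank_at(rec.conception_date, bundle.roster).get(rec.father_id)
                )
            except Exception:
                ranks.append(None)
        cases = cases.assign(rank=ranks)
        usable = cases[cases["rank"].notna()]
        if usable["passes_filter"].sum() >= 3:
            fit = fit_paternity_model(usable)
            paternity_block["model"] = fit.to_dict()
        else:
            logger.warning("too few filtered paternity cases for a model")
    report["paternity"] = paternity_block

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, report, datasets, inter, elo, cases)
    return report


def _write_outputs(out_dir: Path, config, report, datasets, inter, elo, cases) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.model_dump(mode="json")
    for approach, table in datasets.items():
        write_frame(table, out_dir / f"association_{approach}.csv", cfg)
    write_frame(inter.summaries, out_dir / "interaction_summaries.csv", cfg)
    write_frame(inter.tests, out_dir / "permutation_results.csv", cfg)
    if isinstance(cases, pd.DataFrame) and len(cases):
        write_frame(cases, out_dir / "paternity_cases.csv", cfg)
    if not elo.events.empty:
        ev = elo.events.copy()
        ev["date"] = ev["date"].astype(str)
        write_frame(ev, out_dir / "elo_history.csv", cfg)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, KinCategory):
        return obj.value
    return str(obj)


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
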