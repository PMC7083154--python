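"""End-to-end pipeline: data -> metrics -> model grid -> comparison -> reports.

A run is driven by one RunConfig (loadable from YAML), executes every stage,
and writes a manifest recording the config hash, seed and checksums of all
outputs, so reruns with the same seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation, metrics, records as rec_mod, simulate
from .model import fit_all_models
from .records import (DEFAULT_PERIODS, build_count_panel,
                      exclude_single_island_endemics, load_islands,
                      load_records, write_islands, write_records)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    # data source: either both CSV paths, or synthetic=True
    records_path: str | None = None
    islands_path: str | None = None
    synthetic: bool = False

    periods: list[int] = field(default_factory=lambda: list(DEFAULT_PERIODS))
    count_basis: str = "earliest"
    covariates: tuple = ("age", "altitude", "area", "tri")
    n_draws: int = 1000
    n_chains: int = 2
    jitter: float = 0.01
    rescale_distances: bool = True
    log_area: bool = False
    lag_thresholds: tuple = (100,)
    top_k: int = 5
    focal_acronym: str = "tri.h"   # model used for correlation/curve exports
    save_draws: bool = False

    def __post_init__(self):
        if list(self.periods) != sorted(set(self.periods)):
            raise ValueError("periods must be strictly increasing")
        if not self.synthetic and not (self.records_path and self.islands_path):
            raise ValueError("either set synthetic=True or give both "
                             "records_path and islands_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.content_hash(),
                      "seed": config.seed, "stages": {}, "outputs": {},
                      "failures": []}
    t0 = time.time()

    # ---- stage 1: data ------------------------------------------------------
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    if config.synthetic:
        syn = simulate.SyntheticConfig(seed=config.seed)
        islands = simulate.generate_archipelago(syn)
        records = simulate.generate_records(syn, islands)
        write_islands(islands, data_dir / "islands.csv")
        write_records(records, data_dir / "records.csv")
    else:
        islands = load_islands(config.islands_path)
        records = load_records(config.records_path, islands=islands)
    manifest["stages"]["data"] = {"n_records": len(records),
                                  "n_islands": len(islands),
                                  "elapsed_s": round(time.time() - t0, 2)}

    # ---- stage 2: descriptive metrics --------------------------------------
    t = time.time()
    summary = metrics.write_metrics_report(
        records, islands, out / "metrics",
        thresholds=list(config.lag_thresholds), top_k=config.top_k)
    manifest["stages"]["metrics"] = {"mean_lag_years": summary["mean_lag_years"],
                                     "elapsed_s": round(time.time() - t, 2)}

    # ---- stage 3: model grid -----------------------------------------------
    t = time.time()
    modelled = exclude_single_island_endemics(records)
    panel = build_count_panel(modelled, islands, config.periods,
                              basis=config.count_basis)
    panel.to_frame().to_csv(out / "count_panel.csv")
    fits = fit_all_models(panel, islands, periods=config.periods,
                          covariates=tuple(config.covariates),
                          n_draws=config.n_draws, n_chains=config.n_chains,
                          seed=config.seed,
                          rescale_distances=config.rescale_distances,
                          log_area=config.log_area, jitter=config.jitter)
    expected = len(config.periods) * len(config.covariates) * 2
    if len(fits) < expected:
        manifest["failures"].append(
            f"{expected - len(fits)} of {expected} fits failed")
    diag = {f"{p}:{a}": r.diagnostics() for (p, a), r in fits.items()}
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    if config.save_draws:
        draws_dir = out / "draws"
        draws_dir.mkdir(exist_ok=True)
        for (p, a), r in fits.items():
            r.to_dataframe().to_csv(draws_dir / f"draws_{p}_{a}.csv",
                                    index=False)
    manifest["stages"]["fits"] = {"n_models": len(fits),
                                  "n_sie_excluded": len(records) - len(modelled),
                                  "elapsed_s": round(time.time() - t, 2)}

    # ---- stage 4: WAIC comparison ------------------------------------------
    t = time.time()
    comparisons = {}
    contrasts = {}
    for period in config.periods:
        ws = [r.waic() for (p, a), r in fits.items() if p == period]
        if len(ws) < 2:
            manifest["failures"].append(f"period {period}: too few fits "
                                        "for comparison")
            continue
        comp = evaluation.compare_models(ws)
        comparisons[period] = comp
        try:
            contrasts[str(period)] = round(evaluation.harbor_contrast(comp), 3)
        except ValueError:
            pass
    table = evaluation.comparison_report(comparisons)
    table.to_csv(out / "waic_comparison.csv", index=False)
    manifest["stages"]["comparison"] = {
        "best_model": {str(p): c.table["acronym"].iloc[0]
                       for p, c in comparisons.items()},
        "harbor_delta_waic": contrasts,
        "elapsed_s": round(time.time() - t, 2)}

    # ---- stage 5: posterior spatial structure and predictive curves --------
    t = time.time()
    corr_rows = []
    curve_rows = []
    for period in dict.fromkeys((config.periods[0], config.periods[-1])):
        key = (period, config.focal_acronym)
        if key not in fits:
            continue
        res = fits[key]
        corr = res.posterior_correlation()
        frame = corr.to_long_frame()
        frame.insert(0, "period", period)
        corr_rows.append(frame)
        grid = np.linspace(res.model.data.x.min(), res.model.data.x.max(), 25)
        for harbor in ((0, 1) if res.spec.include_harbor else (0,)):
            pc = res.predictive_curve(grid, harbor_value=harbor)
            df = pd.DataFrame({"period": period, "grid": pc.grid,
                               "median": pc.median, "lo80": pc.lower,
                               "hi80": pc.upper, "harbor": harbor})
            curve_rows.append(df)
    if corr_rows:
        pd.concat(corr_rows, ignore_index=True).to_csv(
            out / "island_correlation.csv", index=False)
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "predictive_curve.csv", index=False)
    manifest["stages"]["posterior_structure"] = {
        "elapsed_s": round(time.time() - t, 2)}

    # ---- manifest -----------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["complete"] = not manifest["failures"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


REQUIRED_STAGES = ("data", "metrics", "fits", "comparison")


def report(manifest: dict, out_dir: str | None = None) -> str:
    """Human-readable summary of a completed run.

    Prints the per-period best model, the harbor-vs-no-harbor WAIC contrast,
    the mean description lag and the top contributors per role.
    """
    missing = [s for s in REQUIRED_STAGES if s not in manifest.get("stages", {})]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {missing}")
    stages = manifest["stages"]
    lines = [f"run seed={manifest['seed']} config={manifest['config_hash']}",
             f"records: {stages['data']['n_records']} "
             f"({stages['fits']['n_sie_excluded']} single-island endemics "
             "excluded from the model)",
             f"mean description lag: "
             f"{stages['metrics']['mean_lag_years']:.1f} years"]
    lines.append("best model per period (lowest WAIC):")
    for period, acro in stages["comparison"]["best_model"].items():
        contrast = stages["comparison"]["harbor_delta_waic"].get(period)
        extra = (f"  harbor dWAIC advantage {contrast:+.2f}"
                 if contrast is not None else "")
        lines.append(f"  {period}: {acro}{extra}")
    if out_dir is not None:
        summary_path = pathlib.Path(out_dir) / "metrics" / "metrics_summary.json"
        if summary_path.exists():
            with open(summary_path) as fh:
                msum = json.load(fh)
            for role, info in msum["roles"].items():
                key = next(k for k in info if k.startswith("top_")
                           and k.endswith("_share"))
                namekey = key.rsplit("_share", 1)[0]
                lines.append(f"top {namekey.split('_')[1]} {role}: "
                             f"{', '.join(info[namekey])} "
                             f"(share {info[key]})")
    text = "\n".join(lines)
    return text
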