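"""CSV readers/writers and the end-to-end pipeline runner.

All dates are ISO-8601, timezone-naive local time; every interval in the
package is half-open ``(start, end]``.  `run_all` chains the stages
(chill accumulation -> phenology -> expression -> clustering ->
correlation) and writes each stage's outputs plus a run manifest echoing
every parameter, the seed and the package version, so a run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import build_feature_matrix, kmeans_best_of_n
from .correlate import build_covariates, correlate
from .expression import CT_COLUMNS, delta_delta_ct, qc_filter, summarize_profiles
from .phenology import FORCING_COLUMNS, derive_events
from .simulate import SimulationBundle, SimulationConfig, simulate_bundle
from .thermal import (
    HourlyTemperatureSeries,
    chill_portions,
    chilling_hours,
    growing_degree_hours,
)

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_ct_csv",
    "write_ct_csv",
    "read_forcing_csv",
    "write_bundle",
    "run_all",
]

log = logging.getLogger("budchill")


class IOError_(ValueError):
    pass


def read_temperature_csv(
    path, max_gap_hours: int = 6, permissive: bool = False
) -> HourlyTemperatureSeries:
    """Read a ``timestamp,temp_c`` CSV into a validated hourly series.

    Rows are sorted by timestamp; gaps up to ``max_gap_hours`` are linearly
    interpolated; duplicate timestamps and longer gaps raise.
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "temp_c"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing column {col!r}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["temp_c"] = pd.to_numeric(df["temp_c"])
    except (ValueError, TypeError) as exc:
        raise IOError_(f"{path}: unparseable row ({exc})") from exc
    return HourlyTemperatureSeries.from_frame(df, max_gap_hours=max_gap_hours,
                                              permissive=permissive)


def write_temperature_csv(series: HourlyTemperatureSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_ct_csv(path) -> pd.DataFrame:
    """Read a long-format Ct table; empty/NA Ct marks non-detected reactions."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df["quality"] = pd.to_numeric(df["quality"])
    bad_q = df[(df["quality"] < 0) | (df["quality"] > 1)]
    if not bad_q.empty:
        raise IOError_(
            f"{path}: quality {bad_q['quality'].iloc[0]} outside [0, 1] "
            f"(sample {bad_q['sample_id'].iloc[0]})"
        )
    detected = df["ct"].notna()
    if (df.loc[detected, "ct"] <= 0).any():
        raise IOError_(f"{path}: non-positive Ct value")
    return df


def write_ct_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_forcing_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    df["cutting_date"] = pd.to_datetime(df["cutting_date"])
    return df


def write_bundle(bundle: SimulationBundle, out_dir) -> dict[str, Path]:
    """Write a simulated bundle (temperature, Ct, forcing, ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": out / "temperature.csv",
        "ct": out / "ct_table.csv",
        "forcing": out / "forcing.csv",
        "truth": out / "ground_truth.json",
    }
    write_temperature_csv(bundle.temperature, paths["temperature"])
    write_ct_csv(bundle.ct_table, paths["ct"])
    forcing = bundle.forcing.copy()
    forcing["cutting_date"] = forcing["cutting_date"].dt.strftime("%Y-%m-%d")
    forcing.to_csv(paths["forcing"], index=False)
    truth = bundle.truth
    truth_json = {
        "transitions": {c: str(d.date()) for c, d in truth.transitions.items()},
        "budbreaks": {c: str(d.date()) for c, d in truth.budbreaks.items()},
        "cluster_labels": truth.cluster_labels.to_dict(),
        "coupling_slopes": truth.coupling_slopes,
        "calibrator_sample": truth.calibrator_sample,
        "bad_samples": list(truth.bad_samples),
        "bad_assays": list(truth.bad_assays),
        "seed": bundle.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    return paths


def _config_manifest(config: SimulationConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return encode(config)


def run_all(
    config: SimulationConfig | None = None,
    out_dir="budchill_run",
    reference_genes: tuple[str, ...] = ("REF1", "REF2", "REF3"),
    qc_threshold: float = 0.65,
    k: int = 6,
    n_starts: int = 25,
    window_days: int = 14,
    season_start=None,
) -> dict:
    """Simulate (or accept) a study bundle and run every analysis stage.

    Writes, under ``out_dir``: the simulated input files, chill/heat
    accumulation curves, the phenology report, QC exclusions, relative
    expression, the profile matrix, cluster assignments and centroids, the
    correlation report, and ``manifest.json``.  Returns the in-memory
    results keyed by stage.  Identical config (including seed) yields
    byte-identical outputs.
    """
    cfg = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: generating synthetic bundle (seed=%d)", cfg.seed)
    bundle = simulate_bundle(cfg)
    write_bundle(bundle, out)
    series = bundle.temperature

    log.info("stage chill: CH/CP/GDH accumulation")
    accs = {
        "CH": chilling_hours(series),
        "CP": chill_portions(series),
        "GDH": growing_degree_hours(series),
    }
    pd.concat([a.to_frame() for a in accs.values()]).to_csv(
        out / "accumulation.csv", index=False
    )

    log.info("stage phenology: transition dates and requirements")
    season_start = season_start or cfg.sampling_dates[0]
    events = derive_events(
        series,
        bundle.forcing,
        {c: bundle.truth.budbreak_windows[c] for c in cfg.cultivars},
        season_start=season_start,
    )
    phen_df = pd.DataFrame([e.to_dict() for e in events])
    phen_df.to_csv(out / "phenology.csv", index=False)

    log.info("stage express: QC, ddCt, profile summary")
    kept, exclusions = qc_filter(bundle.ct_table, threshold=qc_threshold)
    exclusions.to_csv(out / "qc_exclusions.csv", index=False)
    if exclusions.shape[0]:
        log.info("QC removed %d units", exclusions.shape[0])
    try:
        rel = delta_delta_ct(kept, list(reference_genes),
                             bundle.truth.calibrator_sample)
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted at stage 'express': {exc}") from exc
    rel_out = rel.copy()
    rel_out["date"] = rel_out["date"].dt.strftime("%Y-%m-%d")
    rel_out.to_csv(out / "relative_expression.csv", index=False)
    profiles = summarize_profiles(rel)
    profiles.to_frame().to_csv(out / "profiles.csv")

    log.info("stage cluster: k-means best of %d (k=%d)", n_starts, k)
    features, dropped = build_feature_matrix(profiles)
    result = kmeans_best_of_n(features, k=k, n_starts=n_starts, seed=cfg.seed)
    result.assignments.rename("cluster").to_csv(out / "clusters.csv")
    result.centroids.to_csv(out / "centroids.csv")

    log.info("stage correlate: expression vs temperature covariates")
    covariates = build_covariates(series, cfg.sampling_dates,
                                  window_days=window_days)
    cov_out = covariates.copy()
    cov_out.index = cov_out.index.strftime("%Y-%m-%d")
    cov_out.to_csv(out / "covariates.csv")
    reports = correlate(profiles, covariates, grouping="both")
    reports.to_csv(out / "correlations.csv", index=False)

    manifest = {
        "package": "budchill",
        "version": __version__,
        "seed": cfg.seed,
        "qc_threshold": qc_threshold,
        "reference_genes": list(reference_genes),
        "calibrator_sample": bundle.truth.calibrator_sample,
        "k": k,
        "n_starts": n_starts,
        "window_days": window_days,
        "season_start": str(pd.Timestamp(season_start).date()),
        "simulation_config": _config_manifest(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "bundle": bundle,
        "accumulations": accs,
        "phenology": phen_df,
        "exclusions": exclusions,
        "relative_expression": rel,
        "profiles": profiles,
        "clustering": result,
        "covariates": covariates,
        "correlations": reports,
    }
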