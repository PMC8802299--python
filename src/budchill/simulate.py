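"""Synthetic study generator: coupled weather, phenology, forcing-assay and
qPCR datasets for a two-cultivar apple dormancy campaign.

The generator emulates a cool-temperate (central European) dormant season:

* **Temperature** — hourly series from a seasonal sinusoid (coldest in
  mid-January) plus a diurnal sinusoid (warmest mid-afternoon) plus AR(1)
  weather noise.
* **Phenology** — the endodormancy -> ecodormancy transition of each
  cultivar occurs on the first day its cumulative dynamic-model chill
  portions reach a cultivar-specific threshold; bud break occurs once a
  growing-degree-hour threshold is reached after the transition.  A weekly
  forcing assay (3 replicates, BBCH scored after 5 weeks) and a weekly field
  bud-break scoring are emitted with configurable replicate
  misclassification.
* **Expression** — ~40 genes follow six trajectory archetypes anchored to
  the simulated transition and bud-break dates (single endodormancy peak,
  late endodormancy peak, two peaks with a minimum near the transition, an
  ecodormancy peak, a broad dormancy plateau, bud-break induction), plus
  genes linearly coupled to mean daily temperature (optionally with
  cultivar-specific slopes) and stable reference genes.  Latent expression
  is converted to qPCR Ct values (Ct = reference level - log2 expression)
  with biological and technical replicate noise, and a designated
  calibrator sample.

Every output is reproducible bit-for-bit from the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .thermal import (
    GDHParams,
    HourlyTemperatureSeries,
    chill_portions,
    growing_degree_hours,
    mean_daily_temperature,
)

__all__ = [
    "SimulationError",
    "TemperatureParams",
    "GeneSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulationBundle",
    "default_gene_panel",
    "simulate_temperature",
    "simulate_phenology",
    "simulate_expression",
    "simulate_bundle",
]

ARCHETYPES = (
    "endo_peak",
    "late_endo_peak",
    "two_peak",
    "eco_peak",
    "broad",
    "budbreak_induced",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureParams:
    """Sinusoid + AR(1) weather model (degC)."""

    annual_mean_c: float = 10.5
    seasonal_amplitude_c: float = 9.3
    diurnal_amplitude_c: float = 3.5
    coldest_doy: int = 15  # mid-January
    ar1: float = 0.85
    noise_sd_c: float = 1.2


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the simulated panel.

    ``archetype`` is one of the six trajectory archetypes, or
    ``temp_coupled`` (latent expression ``intercept + slope * mean daily
    temperature``; slope/intercept may be cultivar-specific mappings) or
    ``reference`` (stable Ct, used for normalization).  ``noise_sd`` is the
    SD of linear-scale trajectory noise added per biological replicate.
    """

    name: str
    archetype: str
    amplitude: float = 8.0
    baseline: float = 1.0
    peak_offset_days: float = 0.0
    coupling_slope: float | Mapping[str, float] = 0.0
    coupling_intercept: float | Mapping[str, float] = 12.0
    noise_sd: float = 0.0


def default_gene_panel(noise_fraction: float = 0.2) -> list[GeneSpec]:
    """The default ~40-gene panel: 5 genes per archetype, temperature-coupled
    genes (one with cultivar-specific slopes), and 3 reference genes.

    ``noise_fraction`` scales per-gene trajectory noise as a fraction of the
    gene's signal range (amplitude).
    """
    panel: list[GeneSpec] = []
    prefixes = {
        "endo_peak": "ENDO",
        "late_endo_peak": "LEND",
        "two_peak": "TWPK",
        "eco_peak": "ECOP",
        "broad": "BRAD",
        "budbreak_induced": "BBIN",
    }
    for arch, prefix in prefixes.items():
        for i in range(1, 6):
            amp = 6.0 + 1.5 * i
            panel.append(
                GeneSpec(
                    name=f"{prefix}{i}",
                    archetype=arch,
                    amplitude=amp,
                    peak_offset_days=2.0 * (i - 3),
                    noise_sd=noise_fraction * amp,
                )
            )
    coupled = [
        ("TCPL1", -0.5, 12.0),
        ("TCPL2", -0.4, 10.0),
        ("TCPL3", -0.3, 8.0),
        ("TCPL4", 0.3, 2.0),
    ]
    for name, slope, intercept in coupled:
        signal_range = abs(slope) * 14.0  # approximate seasonal temperature span
        panel.append(
            GeneSpec(
                name=name,
                archetype="temp_coupled",
                coupling_slope=slope,
                coupling_intercept=intercept,
                noise_sd=noise_fraction * signal_range,
            )
        )
    # cultivar-divergent thermosensitivity (pooling both cultivars attenuates |r|)
    panel.append(
        GeneSpec(
            name="TDIV1",
            archetype="temp_coupled",
            coupling_slope={"Pinova": -0.9, "Gala": -0.6},
            coupling_intercept={"Pinova": 16.0, "Gala": 9.0},
            noise_sd=noise_fraction * 0.75 * 14.0,
        )
    )
    panel.extend(GeneSpec(name=f"REF{i}", archetype="reference") for i in (1, 2, 3))
    return panel


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of the simulated campaign."""

    season_start: str = "2017-09-01"
    season_end: str = "2018-05-31"
    temperature: TemperatureParams = field(default_factory=TemperatureParams)
    cultivars: tuple[str, ...] = ("Pinova", "Gala")
    first_sampling: str = "2017-09-20"
    n_timepoints: int = 28
    sampling_interval_days: int = 7
    bio_reps: int = 3
    tech_reps: int = 2
    cp_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"Pinova": 72.9, "Gala": 83.9}
    )
    gdh_threshold: float = 2750.0
    forcing_start: str = "2017-12-05"
    forcing_end: str = "2018-02-27"
    forcing_replicates: int = 3
    forcing_horizon_weeks: int = 5
    forcing_misclass_prob: float = 0.02
    gene_panel: tuple[GeneSpec, ...] = field(
        default_factory=lambda: tuple(default_gene_panel())
    )
    ref_ct_level: float = 20.0
    bio_ct_noise_sd: float = 0.4
    tech_ct_noise_sd: float = 0.15
    ref_bio_ct_noise_sd: float = 0.1
    n_bad_samples: int = 1
    n_bad_assays: int = 1
    bad_quality: float = 0.45
    good_quality_mean: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise SimulationError("need at least 4 sampling timepoints")
        if any(v <= 0 for v in self.cp_thresholds.values()) or self.gdh_threshold <= 0:
            raise SimulationError("chill/heat thresholds must be positive")

    @property
    def sampling_dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.first_sampling)
        return pd.DatetimeIndex(
            [start + pd.Timedelta(days=self.sampling_interval_days * i)
             for i in range(self.n_timepoints)]
        )

    def child_seed(self, stream: str) -> int:
        """Deterministic per-stream sub-seed derived from the master seed."""
        tag = zlib.crc32(stream.encode("utf-8"))
        h = np.random.SeedSequence([self.seed, tag])
        return int(h.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities the analysis pipeline should recover."""

    transitions: dict
    budbreaks: dict
    budbreak_windows: dict
    cluster_labels: pd.Series  # gene -> archetype (archetype genes only)
    coupling_slopes: dict  # gene -> slope or {cultivar: slope}, latent scale
    trajectories: pd.DataFrame  # calibrator-normalized latent expression
    calibrator_values: dict  # gene -> latent expression of the calibrator cell
    calibrator_sample: str
    bad_samples: tuple
    bad_assays: tuple


@dataclass(frozen=True)
class SimulationBundle:
    config: SimulationConfig
    temperature: HourlyTemperatureSeries
    forcing: pd.DataFrame
    ct_table: pd.DataFrame
    truth: GroundTruth


def _stream_rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(config.child_seed(stream))


def simulate_temperature(config: SimulationConfig) -> HourlyTemperatureSeries:
    """Hourly temperatures: seasonal + diurnal sinusoids + AR(1) noise."""
    p = config.temperature
    ts = pd.date_range(config.season_start, config.season_end, freq="h")
    doy = ts.dayofyear.to_numpy()
    hour = ts.hour.to_numpy()
    seasonal = p.annual_mean_c - p.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - p.coldest_doy) / 365.25
    )
    diurnal = -p.diurnal_amplitude_c * np.cos(2 * np.pi * (hour - 14) / 24.0)
    rng = _stream_rng(config, "temperature")
    shocks = rng.normal(0.0, p.noise_sd_c, size=len(ts))
    noise = np.empty(len(ts))
    prev = 0.0
    for i in range(len(ts)):
        prev = p.ar1 * prev + shocks[i]
        noise[i] = prev
    return HourlyTemperatureSeries(timestamps=ts, temp_c=seasonal + diurnal + noise)


def _threshold_day(cumulative: np.ndarray, timestamps: pd.DatetimeIndex,
                   threshold: float) -> pd.Timestamp:
    idx = np.searchsorted(cumulative, threshold)
    if idx >= len(cumulative):
        raise SimulationError(
            f"insufficient accumulation in simulation: threshold {threshold} never reached"
        )
    return timestamps[idx].normalize()


def simulate_phenology(
    series: HourlyTemperatureSeries, config: SimulationConfig
) -> tuple[dict, pd.DataFrame]:
    """Planted transition/bud-break dates and the weekly forcing table.

    The transition day of each cultivar is the first day cumulative chill
    portions (from the series start) reach its threshold; bud break is the
    first day post-transition GDH reach the heat threshold.  The forcing
    table reports BBCH >= 59 after the forcing horizon iff the cutting date
    is at or past the transition, with replicate misclassification at the
    configured probability.  Field bud break is scored on a weekly grid,
    giving each cultivar a one-week bud-break window.
    """
    cp = chill_portions(series)
    gdh = growing_degree_hours(series, GDHParams())
    rng = _stream_rng(config, "phenology")

    truth: dict = {}
    for cultivar in config.cultivars:
        threshold = config.cp_thresholds[cultivar]
        tdate = _threshold_day(cp.cumulative, cp.timestamps, threshold)
        after = cp.timestamps > tdate + pd.Timedelta(hours=23)
        gdh_after = np.cumsum(gdh.incremental[after])
        bdate = _threshold_day(gdh_after, cp.timestamps[after], config.gdh_threshold)
        # weekly field scoring anchored at the first sampling date
        anchor = pd.Timestamp(config.first_sampling)
        weeks_to = int(np.ceil((bdate - anchor).days / 7.0))
        score_date = anchor + pd.Timedelta(weeks=weeks_to)
        truth[cultivar] = {
            "transition": tdate,
            "budbreak": bdate,
            "budbreak_window": (score_date - pd.Timedelta(days=7), score_date),
        }

    cut_dates = pd.date_range(config.forcing_start, config.forcing_end, freq="7D")
    rows = []
    for cultivar in config.cultivars:
        tdate = truth[cultivar]["transition"]
        for cut in cut_dates:
            for rep in range(1, config.forcing_replicates + 1):
                released = cut >= tdate
                if rng.random() < config.forcing_misclass_prob:
                    released = not released
                stage = (59 + int(rng.integers(0, 3)) if released
                         else 50 + int(rng.integers(0, 6)))
                rows.append(
                    {
                        "cultivar": cultivar,
                        "cutting_date": cut,
                        "replicate": rep,
                        "weeks_in_forcing": config.forcing_horizon_weeks,
                        "bbch_stage": stage,
                    }
                )
    return truth, pd.DataFrame(rows)


def _archetype_shape(arch: str, dates: pd.DatetimeIndex, transition: pd.Timestamp,
                     budbreak: pd.Timestamp, offset_days: float) -> np.ndarray:
    """Unit-height trajectory shape on the sampling grid."""
    t = (dates - transition).days.to_numpy(dtype=float) - offset_days
    tb = (dates - budbreak).days.to_numpy(dtype=float) - offset_days

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    if arch == "endo_peak":
        return bump(-49.0, 18.0)
    if arch == "late_endo_peak":
        return bump(-14.0, 13.0)
    if arch == "two_peak":
        return np.maximum(bump(-42.0, 14.0), 0.9 * bump(28.0, 14.0))
    if arch == "eco_peak":
        return bump(21.0, 13.0)
    if arch == "broad":
        return np.exp(-0.5 * (t / 55.0) ** 2)
    if arch == "budbreak_induced":
        # induction ramps up during late ecodormancy, ahead of visible bud break
        return 1.0 / (1.0 + np.exp(-(tb + 21.0) / 5.0))
    raise SimulationError(f"unknown archetype {arch!r}")


def _per_cultivar(value, cultivar: str) -> float:
    if isinstance(value, Mapping):
        return float(value[cultivar])
    return float(value)


def simulate_expression(
    series: HourlyTemperatureSeries,
    phenology_truth: dict,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a long-format qPCR Ct table and the planted ground truth.

    Latent linear-scale expression per gene and cultivar is built on the
    sampling grid from the gene's archetype (anchored to that cultivar's
    transition and bud-break dates) or its temperature coupling.  Ct values
    are ``ref_ct_level - log2(expression)`` plus biological and technical
    noise; reference genes sit at ``ref_ct_level``.  The calibrator is the
    first biological replicate of the first cultivar at the first sampling
    date.  Optionally, low-quality samples and assays are planted for QC
    tests; quality scores are emitted per reaction.
    """
    rng = _stream_rng(config, "expression")
    dates = config.sampling_dates
    if dates[-1] > series.end:
        raise SimulationError("sampling campaign extends past the temperature series")
    mean_temps = np.array([mean_daily_temperature(series, d) for d in dates])

    panel = list(config.gene_panel)
    bad_assays = tuple(
        f"BADPRIMER{i}" for i in range(1, config.n_bad_assays + 1)
    )
    panel.extend(
        GeneSpec(name=g, archetype="broad", amplitude=4.0, noise_sd=1.0)
        for g in bad_assays
    )

    # latent linear expression per (gene, cultivar) on the sampling grid
    latent: dict[tuple[str, str], np.ndarray] = {}
    for spec in panel:
        for cultivar in config.cultivars:
            if spec.archetype == "reference":
                continue
            if spec.archetype == "temp_coupled":
                v = (_per_cultivar(spec.coupling_intercept, cultivar)
                     + _per_cultivar(spec.coupling_slope, cultivar) * mean_temps)
            else:
                tr = phenology_truth[cultivar]["transition"]
                bb = phenology_truth[cultivar]["budbreak"]
                shape = _archetype_shape(spec.archetype, dates, tr, bb,
                                         spec.peak_offset_days)
                v = spec.baseline + spec.amplitude * shape
            latent[(spec.name, cultivar)] = np.clip(v, 0.05, None)

    cal_cultivar = config.cultivars[0]
    calibrator = f"101_rep1_{cal_cultivar}"

    sample_ids = [
        f"{101 + i}_rep{b}_{cultivar}"
        for i in range(len(dates))
        for cultivar in config.cultivars
        for b in range(1, config.bio_reps + 1)
    ]
    candidates = [s for s in sample_ids if s != calibrator]
    bad_samples = tuple(
        rng.choice(candidates, size=config.n_bad_samples, replace=False)
    ) if config.n_bad_samples else ()

    rows = []
    for i, date in enumerate(dates):
        for cultivar in config.cultivars:
            for b in range(1, config.bio_reps + 1):
                sid = f"{101 + i}_rep{b}_{cultivar}"
                sample_bad = sid in bad_samples
                for spec in panel:
                    if spec.archetype == "reference":
                        true_ct = config.ref_ct_level
                        bio_noise = rng.normal(0.0, config.ref_bio_ct_noise_sd)
                    else:
                        v = latent[(spec.name, cultivar)][i]
                        if spec.noise_sd > 0:
                            v = max(0.05, v + rng.normal(0.0, spec.noise_sd))
                        true_ct = config.ref_ct_level - np.log2(v)
                        bio_noise = rng.normal(0.0, config.bio_ct_noise_sd) \
                            if config.bio_ct_noise_sd > 0 else 0.0
                    for trep in range(1, config.tech_reps + 1):
                        tech_noise = rng.normal(0.0, config.tech_ct_noise_sd) \
                            if config.tech_ct_noise_sd > 0 else 0.0
                        bad = sample_bad or spec.name in bad_assays
                        quality = (config.bad_quality + rng.normal(0.0, 0.03)
                                   if bad
                                   else config.good_quality_mean + rng.normal(0.0, 0.02))
                        rows.append(
                            {
                                "sample_id": sid,
                                "date": date,
                                "cultivar": cultivar,
                                "gene": spec.name,
                                "bio_rep": b,
                                "tech_rep": trep,
                                "ct": true_ct + bio_noise + tech_noise,
                                "quality": float(np.clip(quality, 0.0, 1.0)),
                            }
                        )
    ct_table = pd.DataFrame(rows)

    # calibrator-normalized latent trajectories (what ddCt should recover)
    target_genes = [s.name for s in panel if s.archetype != "reference"]
    cal_values = {g: latent[(g, cal_cultivar)][0] for g in target_genes}
    columns = pd.MultiIndex.from_product([dates, config.cultivars],
                                         names=["date", "cultivar"])
    traj = pd.DataFrame(
        [
            np.concatenate(
                [[latent[(g, c)][i] / cal_values[g] for c in config.cultivars]
                 for i in range(len(dates))]
            )
            for g in target_genes
        ],
        index=pd.Index(target_genes, name="gene"),
        columns=columns,
    )

    arch_specs = [s for s in panel
                  if s.archetype in ARCHETYPES and s.name not in bad_assays]
    cluster_labels = pd.Series({s.name: s.archetype for s in arch_specs},
                               name="archetype")
    coupling = {s.name: (dict(s.coupling_slope) if isinstance(s.coupling_slope, Mapping)
                         else s.coupling_slope)
                for s in panel if s.archetype == "temp_coupled"}

    truth = GroundTruth(
        transitions={c: phenology_truth.get(c, {}).get("transition")
                     for c in config.cultivars},
        budbreaks={c: phenology_truth.get(c, {}).get("budbreak")
                   for c in config.cultivars},
        budbreak_windows={c: phenology_truth.get(c, {}).get("budbreak_window")
                          for c in config.cultivars},
        cluster_labels=cluster_labels,
        coupling_slopes=coupling,
        trajectories=traj,
        calibrator_values={g: float(v) for g, v in cal_values.items()},
        calibrator_sample=calibrator,
        bad_samples=tuple(str(s) for s in bad_samples),
        bad_assays=bad_assays,
    )
    return ct_table, truth


def simulate_bundle(config: SimulationConfig | None = None) -> SimulationBundle:
    """Generate the full coupled dataset bundle for one simulated season."""
    cfg = config or SimulationConfig()
    series = simulate_temperature(cfg)
    phen_truth, forcing = simulate_phenology(series, cfg)
    ct_table, truth = simulate_expression(series, phen_truth, cfg)
    return SimulationBundle(config=cfg, temperature=series, forcing=forcing,
                            ct_table=ct_table, truth=truth)
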