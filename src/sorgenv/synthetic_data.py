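"""Synthetic weather, stress-trajectory, and trial-yield generators.

Real envirotyping studies in the US Great Plains drive the crop model with
station weather (NOAA), survey-derived soil profiles and university hybrid
performance trials.  None of those sources is bundled here; instead this
module generates statistically controlled stand-ins so that every stage of
the pipeline — simulation, clustering, classification, variance components —
can be exercised and tested with known ground truth.

Three generators are provided:

* :func:`gen_weather` — a daily stochastic weather series (Tmax, Tmin, rain,
  solar radiation) from a monthly climate description.
* :func:`gen_stress_prototypes` — noisy copies of labelled stress-trajectory
  prototypes, used to validate cluster recovery.
* :func:`gen_trial_table` — an unbalanced multi-environment trial table with
  site, environment-class-within-site, hybrid and residual variance
  components, used to validate the mixed-model machinery.

All randomness flows from an explicit integer seed; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteClimate",
    "TrialVariance",
    "SITE_PRESETS",
    "gen_weather",
    "gen_stress_prototypes",
    "gen_trial_table",
    "default_wsp_prototypes",
    "default_hsp_prototypes",
    "weather_to_csv",
    "weather_from_csv",
]

#: Mid-month day-of-year used to interpolate monthly climate to daily values.
_MONTH_MID_DOY = np.array(
    [15.5, 45.0, 74.5, 105.0, 135.5, 166.0, 196.5, 227.5, 258.0, 288.5, 319.0, 349.5]
)


@dataclass
class SiteClimate:
    """Monthly climate description of one site.

    Temperature means are interpolated to day-of-year and perturbed with
    AR(1) Gaussian noise shared by Tmax and Tmin (so the diurnal range is
    preserved).  Rain occurrence is an independent Bernoulli draw per day
    with a per-month probability; wet-day depth is exponential with the
    per-month mean.  Radiation follows a clear-sky seasonal sinusoid,
    reduced by 25% on wet days.
    """

    monthly_tmax_mean: np.ndarray  # °C, 12 values
    monthly_tmin_mean: np.ndarray  # °C, 12 values
    temp_sd: float = 3.0  # °C day-to-day noise scale
    rain_prob_wet: np.ndarray = field(
        default_factory=lambda: np.full(12, 0.25)
    )  # P(wet) per month
    rain_mean_depth: np.ndarray = field(
        default_factory=lambda: np.full(12, 8.0)
    )  # mm per wet day
    rad_clear_sky_amp: float = 8.0  # MJ m-2 d-1 seasonal amplitude
    rad_clear_sky_mean: float = 18.0  # MJ m-2 d-1 annual mean
    ar1_rho: float = 0.6  # lag-1 autocorrelation of temperature residuals

    def __post_init__(self) -> None:
        self.monthly_tmax_mean = np.asarray(self.monthly_tmax_mean, dtype=float)
        self.monthly_tmin_mean = np.asarray(self.monthly_tmin_mean, dtype=float)
        self.rain_prob_wet = np.asarray(self.rain_prob_wet, dtype=float)
        self.rain_mean_depth = np.asarray(self.rain_mean_depth, dtype=float)
        for name in ("monthly_tmax_mean", "monthly_tmin_mean", "rain_prob_wet", "rain_mean_depth"):
            if getattr(self, name).shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
        if np.any(self.monthly_tmax_mean <= self.monthly_tmin_mean):
            raise ValueError("monthly_tmax_mean must exceed monthly_tmin_mean in every month")
        if np.any((self.rain_prob_wet < 0) | (self.rain_prob_wet > 1)):
            raise ValueError("rain_prob_wet must lie in [0, 1]")
        if np.any(self.rain_mean_depth < 0):
            raise ValueError("rain_mean_depth must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass
class TrialVariance:
    """Variance structure of a synthetic multi-environment trial.

    All variances are in (kg ha⁻¹)²; ``grand_mean`` in kg ha⁻¹.
    """

    sigma2_site: float = 1.2e6
    sigma2_ecg_within_site: float = 1.8e6
    sigma2_hybrid: float = 1.5e5
    sigma2_resid: float = 6.0e5
    grand_mean: float = 6000.0

    def __post_init__(self) -> None:
        for name in ("sigma2_site", "sigma2_ecg_within_site", "sigma2_hybrid", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _annual_sinusoid(doy: np.ndarray, monthly: np.ndarray) -> np.ndarray:
    """Interpolate 12 monthly values to day-of-year, wrapping at year end."""
    x = np.concatenate([[_MONTH_MID_DOY[-1] - 365.0], _MONTH_MID_DOY, [_MONTH_MID_DOY[0] + 365.0]])
    y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return np.interp(doy, x, y)


def gen_weather(
    site: SiteClimate, start_year: int, n_years: int, seed: int
) -> pd.DataFrame:
    """Generate a daily weather series for ``n_years`` calendar years.

    Returns a DataFrame with columns ``date, tmax, tmin, rain, radn``
    (ISO dates, °C, mm, MJ m⁻² d⁻¹) — the same column semantics as an
    APSIM-style met file.  The series is reproducible for a fixed seed and
    satisfies Tmax ≥ Tmin, rain ≥ 0 and radn > 0 on every day.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    month = dates.month.to_numpy() - 1
    n = len(dates)

    tmax_mean = _annual_sinusoid(doy, site.monthly_tmax_mean)
    tmin_mean = _annual_sinusoid(doy, site.monthly_tmin_mean)

    # AR(1) residual shared between Tmax and Tmin: the diurnal gap stays at
    # its (positive) monthly-mean value, so Tmax >= Tmin holds by construction.
    eps = rng.normal(0.0, site.temp_sd * np.sqrt(max(1.0 - site.ar1_rho**2, 1e-12)), size=n)
    resid = np.empty(n)
    resid[0] = rng.normal(0.0, site.temp_sd)
    for i in range(1, n):
        resid[i] = site.ar1_rho * resid[i - 1] + eps[i]
    tmax = tmax_mean + resid
    tmin = tmin_mean + resid

    wet = rng.random(n) < site.rain_prob_wet[month]
    depth = rng.exponential(1.0, size=n) * site.rain_mean_depth[month]
    rain = np.where(wet, depth, 0.0)

    # Clear-sky sinusoid peaking at the summer solstice (~doy 172).
    radn = site.rad_clear_sky_mean + site.rad_clear_sky_amp * np.cos(
        2.0 * np.pi * (doy - 172.0) / 365.0
    )
    radn = np.where(wet, 0.75 * radn, radn)
    radn = np.maximum(radn, 0.5)

    return pd.DataFrame(
        {"date": dates, "tmax": tmax, "tmin": tmin, "rain": rain, "radn": radn}
    )


def weather_to_csv(weather: pd.DataFrame, path) -> None:
    """Write a weather series as CSV with header ``date,tmax,tmin,rain,radn``."""
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.4f")


def weather_from_csv(path) -> pd.DataFrame:
    """Read a weather CSV written by :func:`weather_to_csv`."""
    weather = pd.read_csv(path, parse_dates=["date"])
    expected = ["date", "tmax", "tmin", "rain", "radn"]
    if list(weather.columns) != expected:
        raise ValueError(f"weather CSV must have columns {expected}")
    return weather


def default_wsp_prototypes(n_bins: int = 16) -> dict[str, np.ndarray]:
    """Canonical seasonal water-deficit trajectory shapes.

    Four relative-transpiration prototypes on ``n_bins`` 100 °Cd bins,
    covering the drought archetypes seen across the western-to-eastern
    Great Plains gradient: stress around flowering with later recovery, a
    low-stress season, terminal stress through grain filling with no
    recovery, and terminal stress relieved by late-season rain.
    """
    x = np.linspace(0.0, 1.0, n_bins)
    flowering = 1.0 - 0.7 * np.exp(-(((x - 0.55) / 0.14) ** 2))
    low = np.full(n_bins, 0.95)
    terminal = 1.0 / (1.0 + np.exp((x - 0.55) / 0.08))
    terminal = 0.1 + 0.85 * terminal
    recovery = terminal.copy()
    recovery[int(0.85 * n_bins):] = 0.75
    return {
        "flowering_stress": np.clip(flowering, 0.0, 1.0),
        "low_stress": low,
        "terminal_stress": np.clip(terminal, 0.0, 1.0),
        "terminal_recovery": np.clip(recovery, 0.0, 1.0),
    }


def default_hsp_prototypes(n_bins: int = 16) -> dict[str, np.ndarray]:
    """Canonical heat-stress trajectory shapes (low / moderate / severe).

    Heat stress acts in a thermal-time window around anthesis, so the
    prototypes differ mainly in the depth of the dip at mid-season.
    """
    x = np.linspace(0.0, 1.0, n_bins)
    dip = np.exp(-(((x - 0.55) / 0.18) ** 2))
    return {
        "low_heat": np.clip(1.0 - 0.08 * dip, 0.0, 1.0),
        "moderate_heat": np.clip(1.0 - 0.45 * dip, 0.0, 1.0),
        "severe_heat": np.clip(1.0 - 0.9 * dip, 0.0, 1.0),
    }


def gen_stress_prototypes(
    prototypes: Sequence[np.ndarray],
    n_per_cluster: int,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy labelled copies of stress-trajectory prototypes.

    Returns ``(X, labels)`` where ``X`` has ``len(prototypes) *
    n_per_cluster`` rows clipped to [0, 1] and ``labels[i]`` is the index of
    the prototype row ``i`` was generated from.
    """
    if len(prototypes) == 0:
        raise ValueError("prototype list must not be empty")
    protos = [np.asarray(p, dtype=float) for p in prototypes]
    n_bins = protos[0].shape[0]
    if any(p.shape != (n_bins,) for p in protos):
        raise ValueError("all prototypes must have the same length")
    if any(np.any((p < 0) | (p > 1)) for p in protos):
        raise ValueError("prototype values must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be at least 1")

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, p in enumerate(protos):
        block = np.tile(p, (n_per_cluster, 1))
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=(n_per_cluster, n_bins))
        rows.append(np.clip(block, 0.0, 1.0))
        labels.extend([k] * n_per_cluster)
    return np.vstack(rows), np.asarray(labels)


def gen_trial_table(
    n_sites: int,
    n_years: int,
    hybrids: Sequence[str],
    tv: TrialVariance,
    missing_frac: float,
    seed: int,
    n_ecg: int = 4,
    ecg_assignment: str = "cycle",
) -> tuple[pd.DataFrame, dict]:
    """Simulate an unbalanced site × year × hybrid yield table.

    Yield is built additively: grand mean + site effect + environment-class
    effect of the site-year + hybrid effect + residual, each drawn from its
    variance in ``tv``.  Each site-year carries one environment-class (ECG)
    label; ``ecg_assignment`` is either ``"cycle"`` (years rotate through
    the ``n_ecg`` classes, giving a balanced nested design) or ``"random"``.
    A ``missing_frac`` share of records is then deleted at random, emulating
    the voluntary-entry unbalance of university performance trials.

    Returns the table (columns ``site, year, hybrid, ecg, yield_kg_ha``) and
    a dict of the true effects for recovery tests.
    """
    if not 0 <= missing_frac <= 0.5:
        raise ValueError("missing_frac must lie in [0, 0.5]")
    if n_sites < 1 or n_years < 1 or len(hybrids) < 1:
        raise ValueError("n_sites, n_years and hybrids must be non-empty")
    rng = np.random.default_rng(seed)

    sites = [f"site_{i+1:02d}" for i in range(n_sites)]
    years = list(range(2007, 2007 + n_years))
    site_eff = rng.normal(0.0, np.sqrt(tv.sigma2_site), n_sites)
    hyb_eff = rng.normal(0.0, np.sqrt(tv.sigma2_hybrid), len(hybrids))

    if ecg_assignment == "cycle":
        ecg_of = {(s, y): y % n_ecg for s in range(n_sites) for y in range(n_years)}
    elif ecg_assignment == "random":
        ecg_of = {
            (s, y): int(rng.integers(n_ecg)) for s in range(n_sites) for y in range(n_years)
        }
    else:
        raise ValueError("ecg_assignment must be 'cycle' or 'random'")
    # One ECG effect per site-year: the class label names the stress type,
    # the effect realization is specific to that site-year.
    ecg_eff = {
        key: rng.normal(0.0, np.sqrt(tv.sigma2_ecg_within_site)) for key in ecg_of
    }

    records = []
    for s in range(n_sites):
        for y in range(n_years):
            for h, hybrid in enumerate(hybrids):
                resid = rng.normal(0.0, np.sqrt(tv.sigma2_resid))
                records.append(
                    {
                        "site": sites[s],
                        "year": years[y],
                        "hybrid": hybrid,
                        "ecg": f"ECG{ecg_of[(s, y)] + 1}",
                        "yield_kg_ha": tv.grand_mean
                        + site_eff[s]
                        + ecg_eff[(s, y)]
                        + hyb_eff[h]
                        + resid,
                    }
                )
    table = pd.DataFrame(records)
    if missing_frac > 0:
        keep = rng.random(len(table)) >= missing_frac
        table = table.loc[keep].reset_index(drop=True)

    truth = {
        "site_effects": dict(zip(sites, site_eff)),
        "hybrid_effects": dict(zip(hybrids, hyb_eff)),
        "ecg_effects": {(sites[s], years[y]): v for (s, y), v in ecg_eff.items()},
        "ecg_labels": {(sites[s], years[y]): f"ECG{c + 1}" for (s, y), c in ecg_of.items()},
    }
    return table, truth


def _great_plains_preset(
    tmax_jul: float, tmin_jul: float, summer_wet_prob: float, summer_depth: float
) -> SiteClimate:
    """Build a Great Plains climate with a July temperature peak."""
    doy_mid = _MONTH_MID_DOY
    shape = np.cos(2.0 * np.pi * (doy_mid - 196.5) / 365.0)  # peaks mid-July
    tmax = tmax_jul - 12.0 + 12.0 * shape
    tmin = tmin_jul - 11.0 + 11.0 * shape
    # Warm-season rainfall maximum, scaled so summer months carry the target.
    wet = summer_wet_prob * (0.55 + 0.45 * shape)
    depth = summer_depth * (0.6 + 0.4 * shape)
    return SiteClimate(
        monthly_tmax_mean=tmax,
        monthly_tmin_mean=tmin,
        rain_prob_wet=np.clip(wet, 0.02, 0.95),
        rain_mean_depth=np.maximum(depth, 1.0),
    )


#: Three named sites spanning the west→east rainfall gradient of the US
#: Sorghum Belt (annual totals roughly 250 / 500 / 850 mm).
SITE_PRESETS: dict[str, SiteClimate] = {
    "dry_west": _great_plains_preset(34.0, 17.0, 0.22, 7.4),
    "intermediate": _great_plains_preset(32.0, 17.5, 0.31, 10.5),
    "wet_east": _great_plains_preset(31.0, 18.5, 0.42, 13.2),
}
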