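"""Simplified daily sorghum season simulator.

This module produces the two stress indices that drive the envirotyping
pipeline:

* **RT** (relative transpiration): the daily ratio of root water supply to
  canopy transpiration demand, capped at 1.  RT = 1 means the canopy is
  fully supplied; RT → 0 means severe water deficit.  RT multiplies daily
  biomass gain.
* **GT** (grain temperature factor): the seed-set multiplier derived from
  the fraction of a thermal-time window around anthesis (50 °Cd before to
  100 °Cd after) that experiences daily maxima above a threshold (32 °C by
  default).

The crop model itself is deliberately minimal: thermal-time phenology on a
broken-stick temperature response, a logistic leaf-area curve scaled by
plant density, radiation-use-efficiency biomass accumulation limited by RT,
a layered soil water bucket with per-layer extraction fractions, and a
sink/source grain yield.  Nitrogen, tillering, senescence and stay-green are
not modelled: the pipeline consumes trajectory *shapes*, not absolute APSIM
fidelity, and those processes do not change the timing or ranking of water
and heat stress across environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "CultivarParams",
    "SoilLayer",
    "SoilProfile",
    "SeasonResult",
    "SeasonIncompleteError",
    "CULTIVAR_PRESETS",
    "default_soil_profile",
    "REFERENCE_DENSITY",
    "daily_thermal_time",
    "leaf_area_index",
    "saturation_vapour_pressure",
    "water_demand",
    "water_supply",
    "rt_index",
    "step_water_balance",
    "gt_seed_set_factor",
    "simulate_season",
]

#: Plant density (plants m⁻²) at which ``lai_max`` is attained.
REFERENCE_DENSITY = 28.0

#: Canopy light-extinction coefficient for radiation interception.
EXTINCTION_COEFF = 0.55

#: Fraction of post-anthesis biomass gain available to fill grain.
HARVEST_SOURCE_FRACTION = 0.8


class SeasonIncompleteError(RuntimeError):
    """Raised when the weather series ends before maturity thermal time accrues."""


@dataclass
class CultivarParams:
    """Cultivar coefficients: phenology, canopy, growth and heat response.

    Thermal-time targets are in °Cd; ``tt_anthesis`` and ``tt_maturity``
    count from emergence, ``tt_emerge`` from sowing.  Cardinal temperatures
    default to conventional sorghum values (base 11, optimum 30,
    maximum 42 °C).
    """

    tt_emerge: float = 60.0
    tt_anthesis: float = 700.0
    tt_maturity: float = 1250.0
    t_base: float = 11.0
    t_opt: float = 30.0
    t_max: float = 42.0
    lai_max: float = 4.0  # m2 m-2 at REFERENCE_DENSITY
    lai_midpoint: float = 360.0  # °Cd at half of lai_max
    lai_slope: float = 0.013  # °Cd^-1 logistic steepness
    rue: float = 1.25  # g MJ^-1
    te_coeff: float = 0.009  # kg m-2 mm-1 kPa (transpiration efficiency coefficient)
    grain_no_coeff: float = 1500.0  # grains per (g m-2 d-1) growth rate at flowering
    grain_wt_max: float = 28.0  # mg grain^-1
    heat_threshold: float = 32.0  # °C
    heat_window_before: float = 50.0  # °Cd pre-anthesis
    heat_window_after: float = 100.0  # °Cd post-anthesis

    def __post_init__(self) -> None:
        if not self.t_base < self.t_opt < self.t_max:
            raise ValueError("cardinal temperatures must satisfy t_base < t_opt < t_max")
        if not 0 < self.tt_emerge < self.tt_anthesis < self.tt_maturity:
            raise ValueError("thermal-time targets must satisfy emerge < anthesis < maturity")


#: Two bundled hybrids differing only in phenology (relative maturity ~70 vs ~71).
CULTIVAR_PRESETS: dict[str, CultivarParams] = {
    "hybrid_1": CultivarParams(),
    "hybrid_2": CultivarParams(tt_anthesis=730.0, tt_maturity=1300.0),
}


@dataclass
class SoilLayer:
    thickness: float  # mm
    ll: float  # mm mm-1 lower limit
    dul: float  # mm mm-1 drained upper limit
    kl: float  # d-1 extraction fraction

    def __post_init__(self) -> None:
        if not 0 <= self.ll < self.dul <= 1:
            raise ValueError("layer must satisfy 0 <= ll < dul <= 1")
        if not 0 < self.kl <= 1:
            raise ValueError("kl must lie in (0, 1]")


@dataclass
class SoilProfile:
    """Layered water bucket: plant-available capacity and daily supply."""

    layers: list[SoilLayer]
    u_evap: float = 6.0  # mm stage-1 soil evaporation limit
    root_front_velocity: float = 1.5  # mm °Cd-1
    max_root_depth: float = 1800.0  # mm

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.pawc <= 0:
            raise ValueError("profile plant-available water capacity must be positive")

    @property
    def depth(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    @property
    def pawc(self) -> float:
        """Plant-available water capacity, Σ(DUL − LL) × thickness, mm."""
        return sum((l.dul - l.ll) * l.thickness for l in self.layers)

    def initial_water(self, fraction_full: float) -> np.ndarray:
        """Per-layer water at ``fraction_full`` of plant-available capacity."""
        if not 0 <= fraction_full <= 1:
            raise ValueError("fraction_full must lie in [0, 1]")
        return np.array(
            [(l.ll + fraction_full * (l.dul - l.ll)) * l.thickness for l in self.layers]
        )


def default_soil_profile() -> SoilProfile:
    """A deep silt-loam-like profile (1.5 m, ~255 mm plant-available water)."""
    thick = [150.0, 150.0, 300.0, 300.0, 300.0, 300.0]
    kl = [0.08, 0.07, 0.06, 0.05, 0.04, 0.03]
    return SoilProfile(
        layers=[SoilLayer(thickness=t, ll=0.13, dul=0.30, kl=k) for t, k in zip(thick, kl)]
    )


@dataclass
class SeasonResult:
    """Output of one site-year-management simulation."""

    sowing_date: _date
    emergence_date: _date
    anthesis_date: _date
    maturity_date: _date
    daily: pd.DataFrame  # day, date, tt, cum_tt, rt, gt, supply, demand, biomass
    yield_kg_ha: float
    gt_factor: float

    def summary(self) -> dict:
        return {
            "sowing_date": str(self.sowing_date),
            "emergence_date": str(self.emergence_date),
            "anthesis_date": str(self.anthesis_date),
            "maturity_date": str(self.maturity_date),
            "yield_kg_ha": float(self.yield_kg_ha),
            "gt_factor": float(self.gt_factor),
        }


def daily_thermal_time(tmin: float, tmax: float, cv: CultivarParams) -> float:
    """Thermal time (°Cd) for one day from a broken-stick response.

    The response on the daily mean temperature is 0 at or below ``t_base``,
    rises linearly to ``t_opt − t_base`` at ``t_opt``, then falls linearly
    to 0 at ``t_max``.
    """
    if tmin > tmax:
        raise ValueError("tmin must not exceed tmax")
    tmean = 0.5 * (tmin + tmax)
    if tmean <= cv.t_base or tmean >= cv.t_max:
        return 0.0
    if tmean <= cv.t_opt:
        return tmean - cv.t_base
    return (cv.t_opt - cv.t_base) * (cv.t_max - tmean) / (cv.t_max - cv.t_opt)


def leaf_area_index(cum_tt: float, density: float, cv: CultivarParams) -> float:
    """Leaf area index from a logistic in thermal time, scaled by density.

    LAI scales linearly with plant density relative to
    :data:`REFERENCE_DENSITY`; no senescence is modelled, so the curve
    plateaus after canopy closure.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if cum_tt < 0:
        raise ValueError("cum_tt must be non-negative")
    logistic = 1.0 / (1.0 + np.exp(-cv.lai_slope * (cum_tt - cv.lai_midpoint)))
    return cv.lai_max * (density / REFERENCE_DENSITY) * logistic


def saturation_vapour_pressure(temp_c: float) -> float:
    """Saturation vapour pressure (kPa) from the Tetens formula."""
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def water_demand(
    radn: float, lai: float, tmax: float, tmin: float, cv: CultivarParams
) -> float:
    """Canopy transpiration demand (mm) for one day.

    Demand is the water needed to realize the radiation-limited biomass
    gain at the cultivar's transpiration efficiency:
    ``(rue × intercepted radiation) × VPD / te_coeff``, with interception
    ``1 − exp(−0.55 × LAI)`` and daytime VPD taken as 75% of the
    saturation-vapour-pressure span between Tmax and Tmin.
    """
    if radn < 0:
        raise ValueError("radiation must be non-negative")
    if tmin > tmax:
        raise ValueError("tmin must not exceed tmax")
    interception = 1.0 - np.exp(-EXTINCTION_COEFF * lai)
    gain_g_m2 = cv.rue * radn * interception
    vpd = 0.75 * (saturation_vapour_pressure(tmax) - saturation_vapour_pressure(tmin))
    return (gain_g_m2 / 1000.0) * vpd / cv.te_coeff


def _rooted_fractions(profile: SoilProfile, root_depth: float) -> np.ndarray:
    """Fraction of each layer explored by roots at ``root_depth``."""
    if root_depth < 0:
        raise ValueError("root_depth must be non-negative")
    fractions = np.zeros(len(profile.layers))
    top = 0.0
    for i, layer in enumerate(profile.layers):
        bottom = top + layer.thickness
        if root_depth >= bottom:
            fractions[i] = 1.0
        elif root_depth > top:
            fractions[i] = (root_depth - top) / layer.thickness
        top = bottom
    return fractions


def water_supply(
    soil_water: np.ndarray, profile: SoilProfile, root_depth: float
) -> float:
    """Potential daily root water uptake (mm).

    Sum over rooted layers of ``kl × (water − LL × thickness)``, with
    partially rooted layers weighted by the rooted fraction.
    """
    fractions = _rooted_fractions(profile, root_depth)
    supply = 0.0
    for water, layer, frac in zip(soil_water, profile.layers, fractions):
        extractable = max(water - layer.ll * layer.thickness, 0.0)
        supply += layer.kl * extractable * frac
    return supply


def rt_index(supply: float, demand: float) -> float:
    """Relative transpiration: min(1, supply/demand); 1 when demand is zero."""
    if supply < 0 or demand < 0:
        raise ValueError("supply and demand must be non-negative")
    if demand == 0:
        return 1.0
    return min(1.0, supply / demand)


def step_water_balance(
    soil_water: np.ndarray,
    rain: float,
    soil_evap_demand: float,
    transpiration: float,
    profile: SoilProfile,
    root_depth: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Advance the layered bucket one day; returns (new state, fluxes).

    Order of operations: rain infiltrates top-down filling each layer to its
    drained upper limit, excess cascades downward and leaves the profile as
    drainage; soil evaporation is taken from the top layer only, capped by
    its water above the lower limit; transpiration is removed from rooted
    layers in proportion to each layer's extractable supply.  Mass balance
    closes to numerical precision:
    Δstorage = rain − drainage − evaporation − transpiration.
    """
    if rain < 0 or soil_evap_demand < 0 or transpiration < 0:
        raise ValueError("fluxes must be non-negative")
    water = np.asarray(soil_water, dtype=float).copy()
    if root_depth is None:
        root_depth = profile.depth

    # Infiltration cascade.
    inflow = rain
    for i, layer in enumerate(profile.layers):
        capacity = layer.dul * layer.thickness - water[i]
        absorbed = min(inflow, max(capacity, 0.0))
        water[i] += absorbed
        inflow -= absorbed
    drainage = inflow

    # Stage-limited soil evaporation from the surface layer.
    top = profile.layers[0]
    evap_avail = max(water[0] - top.ll * top.thickness, 0.0)
    evap = min(soil_evap_demand, profile.u_evap, evap_avail)
    water[0] -= evap

    # Root extraction proportional to per-layer extractable supply.
    if transpiration > 0:
        fractions = _rooted_fractions(profile, root_depth)
        per_layer = np.array(
            [
                layer.kl * max(w - layer.ll * layer.thickness, 0.0) * frac
                for w, layer, frac in zip(water, profile.layers, fractions)
            ]
        )
        total = per_layer.sum()
        if transpiration > total + 1e-9:
            raise ValueError(
                "transpiration exceeds extractable supply; cap it with rt_index first"
            )
        if total > 0:
            water -= transpiration * per_layer / total

    fluxes = {"drainage": drainage, "evaporation": evap, "transpiration": transpiration}
    return water, fluxes


def gt_seed_set_factor(
    daily_tmax: np.ndarray,
    daily_tt: np.ndarray,
    cv: CultivarParams,
    weighting: str = "tt",
) -> float:
    """Seed-set factor from heat in the window around anthesis.

    The sensitive window spans cumulative thermal time (from emergence)
    between ``tt_anthesis − heat_window_before`` and
    ``tt_anthesis + heat_window_after``.  The stressed fraction *f* is the
    share of the window — weighted by daily thermal time (``weighting="tt"``,
    the default) or by days (``"days"``) — on which Tmax exceeds
    ``heat_threshold``.  Returns the factor 1 − f ∈ [0, 1].
    """
    daily_tmax = np.asarray(daily_tmax, dtype=float)
    daily_tt = np.asarray(daily_tt, dtype=float)
    if daily_tmax.shape != daily_tt.shape:
        raise ValueError("daily_tmax and daily_tt must align")
    if weighting not in ("tt", "days"):
        raise ValueError("weighting must be 'tt' or 'days'")
    cum_tt = np.cumsum(daily_tt)
    if cum_tt[-1] < cv.tt_anthesis + cv.heat_window_after:
        raise ValueError("season too short: thermal time never covers the heat window")
    lo = cv.tt_anthesis - cv.heat_window_before
    hi = cv.tt_anthesis + cv.heat_window_after
    in_window = (cum_tt >= lo) & (cum_tt <= hi)
    weights = daily_tt[in_window] if weighting == "tt" else np.ones(in_window.sum())
    total = weights.sum()
    if in_window.sum() == 0 or total <= 0:
        raise ValueError("heat-sensitive window is empty")
    stressed = weights[daily_tmax[in_window] > cv.heat_threshold].sum()
    return float(1.0 - stressed / total)


def _daily_gt_indicator(tmax: float, cum_tt: float, cv: CultivarParams) -> float:
    """Binary daily heat-stress index for trajectory building.

    1 outside the anthesis window and on cool window days; 0 on window days
    whose maximum exceeds the threshold.  The windowed seed-set factor is
    computed separately by :func:`gt_seed_set_factor`.
    """
    lo = cv.tt_anthesis - cv.heat_window_before
    hi = cv.tt_anthesis + cv.heat_window_after
    if lo <= cum_tt <= hi and tmax > cv.heat_threshold:
        return 0.0
    return 1.0


def simulate_season(
    weather: pd.DataFrame,
    profile: SoilProfile,
    cv: CultivarParams,
    mgmt: dict,
    init: dict | None = None,
) -> SeasonResult:
    """Simulate one season from sowing to physiological maturity.

    ``mgmt`` needs ``sowing_date`` (anything ``pandas.Timestamp`` accepts)
    and ``density`` (plants m⁻²).  ``init`` may carry
    ``fraction_full_profile`` (default 0.5, i.e. the profile starts half
    full of plant-available water) and ``no3_mg_kg`` (accepted for
    config compatibility but ignored: nitrogen is not simulated).

    Daily biomass gain is the radiation-limited gain multiplied by RT;
    grain number comes from the mean growth rate over the anthesis window;
    yield is the minimum of sink (grain number × maximum grain weight) and
    source (a fixed fraction of post-anthesis gain), scaled by the GT
    seed-set factor, in kg ha⁻¹.

    Raises :class:`SeasonIncompleteError` when the weather series ends
    before maturity thermal time accumulates.
    """
    init = init or {}
    density = float(mgmt["density"])
    if density <= 0:
        raise ValueError("density must be positive")
    sowing = pd.Timestamp(mgmt["sowing_date"])
    fraction_full = float(init.get("fraction_full_profile", 0.5))

    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    tmax_arr = weather["tmax"].to_numpy(dtype=float)
    tmin_arr = weather["tmin"].to_numpy(dtype=float)
    rain_arr = weather["rain"].to_numpy(dtype=float)
    radn_arr = weather["radn"].to_numpy(dtype=float)
    start_candidates = np.flatnonzero((dates == sowing).to_numpy())
    if start_candidates.size == 0:
        raise ValueError(f"sowing date {sowing.date()} not covered by the weather series")
    start = int(start_candidates[0])

    soil_water = profile.initial_water(fraction_full)
    cum_tt_sow = 0.0  # thermal time since sowing (drives emergence)
    cum_tt = 0.0  # thermal time since emergence (drives everything else)
    emerged = False
    root_depth = 150.0
    biomass = 0.0
    biomass_at_anthesis: float | None = None
    emergence_date = anthesis_date = maturity_date = None
    gain_window: list[float] = []  # daily gains inside the anthesis window

    records = []
    tmax_series: list[float] = []
    tt_series: list[float] = []

    for i in range(start, len(dates)):
        tmax, tmin = float(tmax_arr[i]), float(tmin_arr[i])
        rain, radn = float(rain_arr[i]), float(radn_arr[i])
        tt = daily_thermal_time(tmin, tmax, cv)

        if not emerged:
            cum_tt_sow += tt
            soil_water, _ = step_water_balance(soil_water, rain, 1.0, 0.0, profile)
            if cum_tt_sow >= cv.tt_emerge:
                emerged = True
                emergence_date = dates[i].date()
            continue

        cum_tt += tt
        if cum_tt <= cv.tt_anthesis:
            root_depth = min(
                root_depth + profile.root_front_velocity * tt,
                profile.max_root_depth,
                profile.depth,
            )

        lai = leaf_area_index(cum_tt, density, cv)
        cover = 1.0 - np.exp(-EXTINCTION_COEFF * lai)
        demand = water_demand(radn, lai, tmax, tmin, cv)
        # Infiltrate today's rain and take soil evaporation first, then
        # compute supply on the updated state so uptake never overdraws.
        soil_evap_demand = 1.5 * (1.0 - cover)
        soil_water, _ = step_water_balance(
            soil_water, rain, soil_evap_demand, 0.0, profile, root_depth
        )
        supply = water_supply(soil_water, profile, root_depth)
        rt = rt_index(supply, demand)
        transpiration = min(demand, supply)
        soil_water, _ = step_water_balance(
            soil_water, 0.0, 0.0, transpiration, profile, root_depth
        )

        gain = cv.rue * radn * cover * rt
        biomass += gain
        gt_daily = _daily_gt_indicator(tmax, cum_tt, cv)

        in_anthesis_window = (
            cv.tt_anthesis - cv.heat_window_before
            <= cum_tt
            <= cv.tt_anthesis + cv.heat_window_after
        )
        if in_anthesis_window:
            gain_window.append(gain)

        tmax_series.append(tmax)
        tt_series.append(tt)
        records.append(
            {
                "day": i - start,
                "date": dates[i].date(),
                "tt": tt,
                "cum_tt": cum_tt,
                "rt": rt,
                "gt": gt_daily,
                "supply": supply,
                "demand": demand,
                "biomass": biomass,
            }
        )

        if anthesis_date is None and cum_tt >= cv.tt_anthesis:
            anthesis_date = dates[i].date()
            biomass_at_anthesis = biomass
        if cum_tt >= cv.tt_maturity:
            maturity_date = dates[i].date()
            break

    if maturity_date is None or emergence_date is None or anthesis_date is None:
        raise SeasonIncompleteError(
            "weather series ended before the season reached maturity"
        )

    gt_factor = gt_seed_set_factor(np.array(tmax_series), np.array(tt_series), cv)

    growth_rate = float(np.mean(gain_window)) if gain_window else 0.0
    grains_m2 = cv.grain_no_coeff * growth_rate
    sink_g_m2 = grains_m2 * cv.grain_wt_max / 1000.0
    source_g_m2 = HARVEST_SOURCE_FRACTION * max(biomass - (biomass_at_anthesis or 0.0), 0.0)
    yield_kg_ha = min(sink_g_m2, source_g_m2) * gt_factor * 10.0

    return SeasonResult(
        sowing_date=sowing.date(),
        emergence_date=emergence_date,
        anthesis_date=anthesis_date,
        maturity_date=maturity_date,
        daily=pd.DataFrame(records),
        yield_kg_ha=float(yield_kg_ha),
        gt_factor=float(gt_factor),
    )
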