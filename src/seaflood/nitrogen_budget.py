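"""Benthic nitrogen mass balance for flooded soil-core microcosms.

The budget chain runs:

1. :func:`compute_flux` — net solute efflux from closed core incubations
   (start/end headspace concentrations), positive out of the soil.
2. :func:`fit_jar_rate` — volumetric NH4+ production in a soil layer from the
   linear porewater accumulation in anoxic jar incubations, gated on slope
   significance (p < alpha) and corrected for porosity.
3. :func:`depth_integrate` — areal NH4+ production over 0–20 cm, linearly
   interpolating the unmeasured 10–15 cm layer between its neighbours.
4. :func:`porewater_inventory` / :func:`accumulation_rate` — depth-integrated
   porewater NH4+ stock and its rate of change between sectionings.
5. :func:`nitrogen_budget` — the mass balance: NH4+ production not accounted
   for by DIN efflux or porewater accumulation is attributed to loss as
   gaseous nitrogen (potential denitrification); potential NH4+ oxidation is
   that loss plus the NOx- efflux, since denitrified nitrogen must first have
   been oxidized.

Units are explicit throughout: concentrations µmol L−1 (= µM) for incubation
water, mM for porewater; volumetric rates nmol cm−3 d−1; areal rates and
fluxes mmol m−2 d−1; inventories mmol m−2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError

#: Jar incubation depth intervals (cm); the 10-15 cm layer is not incubated
#: and is filled in by interpolation during depth integration.
JAR_LAYERS = ((0.0, 2.0), (2.0, 5.0), (5.0, 10.0), (15.0, 20.0))
INTERPOLATED_LAYER = (10.0, 15.0)
#: Porewater sectioning depth intervals (cm).
POREWATER_LAYERS = ((0.0, 1.0), (1.0, 2.0), (2.0, 5.0), (5.0, 10.0),
                    (10.0, 15.0), (15.0, 20.0))
INTEGRATION_RANGE = (0.0, 20.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxIncubation:
    """One closed-core incubation of one analyte.

    Concentrations in µmol L−1, volume in L, area in m², duration in days.
    """

    core_id: str
    station: str
    day: float
    water_volume_L: float
    area_m2: float
    duration_d: float
    c_start_uM: float
    c_end_uM: float
    analyte: str = "NH4"

    def __post_init__(self) -> None:
        if self.duration_d <= 0:
            raise InputError(f"duration_d must be > 0, got {self.duration_d}")
        if self.area_m2 <= 0:
            raise InputError(f"area_m2 must be > 0, got {self.area_m2}")
        if self.water_volume_L <= 0:
            raise InputError(f"water_volume_L must be > 0, got {self.water_volume_L}")
        if self.c_start_uM < 0 or self.c_end_uM < 0:
            raise InputError("concentrations must be >= 0")


@dataclass(frozen=True)
class Flux:
    """Net solute flux, mmol m−2 d−1; positive = efflux out of the soil."""

    analyte: str
    value: float
    core_id: str
    day: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InputError(f"flux value must be finite, got {self.value}")


@dataclass(frozen=True)
class AggregatedFlux:
    """Mean flux over replicate cores and a time window, with SEM."""

    analyte: str
    value: float
    sem: float            # nan when only one measurement
    n_measurements: int
    window: tuple[float, float]
    single_measurement: bool = False


@dataclass(frozen=True)
class JarSeries:
    """Porewater NH4+ time series from one pooled jar depth interval."""

    station: str
    depth_interval: tuple[float, float]
    times_d: tuple[float, ...]
    nh4_uM: tuple[float, ...]
    porosity: float
    time_point: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_d, float)
        if len(t) < 3:
            raise InputError("JarSeries needs >= 3 time points")
        if len(t) != len(self.nh4_uM):
            raise InputError("times and concentrations differ in length")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if not (0.0 < self.porosity < 1.0):
            raise InputError(f"porosity must be in (0,1), got {self.porosity}")


@dataclass(frozen=True)
class VolumetricRate:
    """Layer NH4+ production rate, nmol cm−3 d−1 (= slope µM d−1 × porosity)."""

    depth_interval: tuple[float, float]
    slope_uM_d: float
    p_value: float
    r_squared: float
    porosity: float
    rate: float          # nan when not significant
    significant: bool


@dataclass(frozen=True)
class ArealRate:
    """Depth-integrated production, mmol m−2 d−1 over 0–20 cm."""

    station: str
    time_point: str
    value: float         # nan when incomplete
    depth_range: tuple[float, float]
    interpolated_layers: tuple[tuple[float, float], ...]
    complete: bool
    missing_layers: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class PorewaterProfile:
    """Per-layer porewater concentrations (mM) of one analyte, with porosity."""

    station: str
    time_point: str
    day: float
    analyte: str
    layers: tuple[tuple[float, float], ...]
    conc_mM: tuple[float, ...]
    porosity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.conc_mM) or len(self.layers) != len(self.porosity):
            raise InputError("layers, conc_mM and porosity differ in length")
        if any(c < 0 for c in self.conc_mM):
            raise InputError("concentrations must be >= 0")


@dataclass(frozen=True)
class NitrogenBudget:
    """Per-station, per-time-point nitrogen mass balance (mmol m−2 d−1)."""

    station: str
    time_point: str
    production: float
    din_efflux: float
    nox_efflux: float
    accumulation: float
    potential_denitrification_raw: float
    potential_denitrification: float
    potential_nh4_oxidation: float
    denitrified_fraction: float      # nan when production <= 0
    negligible_denitrification: bool
    complete: bool = True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_flux(incubation: FluxIncubation) -> Flux:
    """Net flux across the soil-water interface from start/end concentrations.

    value = (C_end − C_start) · V / (A · t), µmol m−2 d−1, divided by 1000 to
    give mmol m−2 d−1.  Negative values are uptake by the soil, not errors.
    """
    delta = incubation.c_end_uM - incubation.c_start_uM
    value = delta * incubation.water_volume_L / (
        incubation.area_m2 * incubation.duration_d) / 1000.0
    return Flux(analyte=incubation.analyte, value=value,
                core_id=incubation.core_id, day=incubation.day)


def compute_din_flux(nh4: Flux, nox: Flux) -> tuple[Flux, dict[str, float]]:
    """DIN flux = NH4+ flux + NOx− flux, with each analyte's share of DIN.

    Shares are reported only when DIN > 0 (otherwise nan).
    """
    if nh4.core_id != nox.core_id or nh4.day != nox.day:
        raise InputError(
            f"flux pair mismatch: {nh4.core_id}/{nh4.day} vs {nox.core_id}/{nox.day}")
    din = nh4.value + nox.value
    if din > 0:
        shares = {"NH4": nh4.value / din, "NOx": nox.value / din}
    else:
        shares = {"NH4": math.nan, "NOx": math.nan}
    return Flux(analyte="DIN", value=din, core_id=nh4.core_id, day=nh4.day), shares


def fit_jar_rate(series: JarSeries, alpha: float = 0.05) -> VolumetricRate:
    """OLS slope of jar NH4+ vs time, gated on significance, times porosity.

    The porewater slope (µM d−1 = nmol cm−3 porewater d−1) multiplied by
    porosity gives the bulk volumetric rate (nmol cm−3 bulk soil d−1).  The
    rate is reported only when the two-sided slope t-test has p < alpha;
    otherwise the diagnostics are retained and ``rate`` is nan.
    """
    if not (0.0 < alpha < 1.0):
        raise InputError(f"alpha must be in (0,1), got {alpha}")
    t = np.asarray(series.times_d, float)
    c = np.asarray(series.nh4_uM, float)
    if np.ptp(t) == 0:
        raise InputError("zero time variance in jar series")
    res = stats.linregress(t, c)
    slope = float(res.slope)
    p = float(res.pvalue)
    r2 = float(res.rvalue) ** 2
    # exactly collinear points give rvalue 1 and p underflow to 0; keep as-is
    significant = bool(p < alpha)
    rate = slope * series.porosity if significant else math.nan
    return VolumetricRate(depth_interval=series.depth_interval,
                          slope_uM_d=slope, p_value=p, r_squared=r2,
                          porosity=series.porosity, rate=rate,
                          significant=significant)


def _midpoint(interval: tuple[float, float]) -> float:
    return 0.5 * (interval[0] + interval[1])


def depth_integrate(rates: dict[tuple[float, float], VolumetricRate],
                    station: str = "", time_point: str = "",
                    target_range: tuple[float, float] = INTEGRATION_RANGE,
                    ) -> ArealRate:
    """Integrate layer rates over 0–20 cm to an areal rate (mmol m−2 d−1).

    The unmeasured 10–15 cm rate is linearly interpolated between the 5–10
    and 15–20 cm rates at the layer midpoints (7.5, 12.5, 17.5 cm; equally
    spaced for this geometry, so the interpolation equals their mean).  A
    required layer that is missing or non-significant flags the result
    incomplete rather than dropping it.
    """
    missing = []
    layer_rates: dict[tuple[float, float], float] = {}
    for layer in JAR_LAYERS:
        vr = rates.get(layer)
        if vr is None or not vr.significant or not math.isfinite(vr.rate):
            missing.append(layer)
        else:
            layer_rates[layer] = vr.rate

    interpolated: tuple[tuple[float, float], ...] = ()
    if INTERPOLATED_LAYER in rates and rates[INTERPOLATED_LAYER].significant:
        layer_rates[INTERPOLATED_LAYER] = rates[INTERPOLATED_LAYER].rate
    elif not missing:
        lo, hi = (5.0, 10.0), (15.0, 20.0)
        m, m1, m2 = (_midpoint(INTERPOLATED_LAYER), _midpoint(lo), _midpoint(hi))
        r1, r2 = layer_rates[lo], layer_rates[hi]
        layer_rates[INTERPOLATED_LAYER] = r1 + (m - m1) / (m2 - m1) * (r2 - r1)
        interpolated = (INTERPOLATED_LAYER,)

    if missing:
        return ArealRate(station=station, time_point=time_point, value=math.nan,
                         depth_range=target_range, interpolated_layers=interpolated,
                         complete=False, missing_layers=tuple(missing))

    # nmol cm−3 d−1 × cm → nmol cm−2 d−1; ×1e4 cm² m−2 / 1e6 nmol mmol−1 = ×0.01
    total = sum(r * (layer[1] - layer[0]) for layer, r in layer_rates.items())
    return ArealRate(station=station, time_point=time_point, value=total * 0.01,
                     depth_range=target_range, interpolated_layers=interpolated,
                     complete=True)


def porewater_inventory(profile: PorewaterProfile,
                        target_range: tuple[float, float] = INTEGRATION_RANGE,
                        ) -> float:
    """Depth-integrated porewater stock, mmol m−2, over the target range.

    inventory = Σ C (mM = µmol cm−3) × porosity × thickness (cm), i.e.
    µmol cm−2, converted to mmol m−2 (×10).  Layers must tile the target
    range contiguously.
    """
    layers = sorted(zip(profile.layers, profile.conc_mM, profile.porosity))
    pos = target_range[0]
    total = 0.0
    for (top, bot), conc, phi in layers:
        if abs(top - pos) > 1e-9:
            raise InputError(
                f"porewater profile gap: expected layer starting at {pos} cm, "
                f"got {top}-{bot} cm")
        total += conc * phi * (bot - top)
        pos = bot
    if abs(pos - target_range[1]) > 1e-9:
        raise InputError(
            f"porewater profile gap: coverage ends at {pos} cm, "
            f"target {target_range[1]} cm")
    return total * 10.0


def accumulation_rate(profile_t1: PorewaterProfile, profile_t2: PorewaterProfile,
                      ) -> float:
    """Porewater accumulation rate between two sectionings, mmol m−2 d−1."""
    if profile_t1.station != profile_t2.station:
        raise InputError("accumulation_rate requires profiles from one station")
    dt = profile_t2.day - profile_t1.day
    if dt <= 0:
        raise InputError(f"t2 must be > t1, got dt={dt}")
    return (porewater_inventory(profile_t2) - porewater_inventory(profile_t1)) / dt


def aggregate_fluxes(fluxes: list[Flux], window: tuple[float, float]) -> AggregatedFlux:
    """Aggregate replicate-core fluxes over a time window.

    Within each measurement day the replicate cores are averaged (SEM across
    cores); across days the daily means are combined with time weights given
    by the midpoints between consecutive measurement days, so evenly spaced
    days get equal weight and a lone day gets weight one.
    """
    selected = [f for f in fluxes if window[0] < f.day <= window[1]]
    if not selected:
        raise InputError(f"no flux measurements in window {window}")
    analytes = {f.analyte for f in selected}
    if len(analytes) > 1:
        raise InputError(f"mixed analytes in aggregation: {sorted(analytes)}")
    days = sorted({f.day for f in selected})
    means, sems, counts = [], [], []
    for d in days:
        vals = np.array([f.value for f in selected if f.day == d])
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1
                    else math.nan)
        counts.append(len(vals))
    means_a = np.array(means)
    if len(days) == 1:
        weights = np.array([1.0])
    else:
        bounds = np.concatenate([[days[0]],
                                 (np.array(days[:-1]) + np.array(days[1:])) / 2.0,
                                 [days[-1]]])
        weights = np.diff(bounds)
        weights = weights / weights.sum()
    value = float(np.sum(weights * means_a))
    single = len(selected) == 1
    if single:
        sem = math.nan
    else:
        sem_terms = [(w * s) ** 2 for w, s in zip(weights, sems)
                     if math.isfinite(s)]
        sem = math.sqrt(sum(sem_terms)) if sem_terms else math.nan
    return AggregatedFlux(analyte=selected[0].analyte, value=value, sem=sem,
                          n_measurements=len(selected), window=window,
                          single_measurement=single)


def nitrogen_budget(production: ArealRate, din_efflux: float, nox_efflux: float,
                    accumulation: float, clamp: bool = True) -> NitrogenBudget:
    """Mass-balance estimate of potential denitrification and NH4+ oxidation.

    raw potential denitrification = production − DIN efflux − accumulation.
    Negative raw values (DIN release exceeding measured production) are
    clamped to zero and flagged as negligible denitrification; the raw value
    is always retained for audit.  Potential NH4+ oxidation = clamped
    denitrification + NOx− efflux, because every denitrified mol of N passed
    through NOx− first.
    """
    if not production.complete:
        return NitrogenBudget(
            station=production.station, time_point=production.time_point,
            production=math.nan, din_efflux=din_efflux, nox_efflux=nox_efflux,
            accumulation=accumulation, potential_denitrification_raw=math.nan,
            potential_denitrification=math.nan, potential_nh4_oxidation=math.nan,
            denitrified_fraction=math.nan, negligible_denitrification=False,
            complete=False)
    p = production.value
    raw = p - din_efflux - accumulation
    negligible = raw < 0
    clamped = max(raw, 0.0) if clamp else raw
    oxidation = clamped + nox_efflux
    fraction = clamped / p if p > 0 else math.nan
    return NitrogenBudget(
        station=production.station, time_point=production.time_point,
        production=p, din_efflux=din_efflux, nox_efflux=nox_efflux,
        accumulation=accumulation, potential_denitrification_raw=raw,
        potential_denitrification=clamped, potential_nh4_oxidation=oxidation,
        denitrified_fraction=fraction, negligible_denitrification=negligible,
        complete=True)


# ---------------------------------------------------------------------------
# Table-level driver: CSV-shaped frames to a budget table
# ---------------------------------------------------------------------------

def budget_from_frames(fluxes, jars, porewater, alpha: float = 0.05):
    """Compute the per-station, per-sectioning nitrogen budget from tables.

    ``fluxes``: core_id, station, day, analyte (NH4/NOx), c_start_uM,
    c_end_uM, volume_L, area_m2, duration_d.  ``jars``: station, time_point,
    sectioning_day, depth_top_cm, depth_bottom_cm, day, nh4_uM, porosity.
    ``porewater``: station, time_point, sectioning_day, depth_top_cm,
    depth_bottom_cm, analyte, conc_mM, porosity (must include a pre-flood
    baseline profile, used for the first sectioning's accumulation).

    Flux aggregation windows span (previous sectioning, sectioning], using
    every measurement between snapshots, time-weighted.  Returns one row per
    station x post-flood sectioning; incomplete budgets (a non-significant
    jar layer) are flagged, never dropped.
    """
    import pandas as pd

    rows = []
    for station in sorted(jars["station"].unique()):
        jar_st = jars[jars["station"] == station]
        pw_st = porewater[(porewater["station"] == station)
                          & (porewater["analyte"] == "NH4")]
        flux_st = fluxes[fluxes["station"] == station]

        flux_objs = {"NH4": [], "NOx": []}
        for _, r in flux_st.iterrows():
            inc = FluxIncubation(core_id=r["core_id"], station=station,
                                 day=r["day"], water_volume_L=r["volume_L"],
                                 area_m2=r["area_m2"], duration_d=r["duration_d"],
                                 c_start_uM=r["c_start_uM"], c_end_uM=r["c_end_uM"],
                                 analyte=r["analyte"])
            flux_objs[r["analyte"]].append(compute_flux(inc))

        def profile_at(day: float) -> PorewaterProfile:
            sub = pw_st[pw_st["sectioning_day"] == day].sort_values("depth_top_cm")
            if sub.empty:
                raise InputError(f"no porewater profile at day {day} "
                                 f"for station {station}")
            return PorewaterProfile(
                station=station, time_point=str(sub["time_point"].iloc[0]),
                day=day, analyte="NH4",
                layers=tuple(zip(sub["depth_top_cm"], sub["depth_bottom_cm"])),
                conc_mM=tuple(sub["conc_mM"]), porosity=tuple(sub["porosity"]))

        sectionings = (jar_st[["time_point", "sectioning_day"]]
                       .drop_duplicates().sort_values("sectioning_day"))
        pw_days = sorted(pw_st["sectioning_day"].unique())
        prev_day = pw_days[0] if pw_days else 0.0  # pre-flood baseline
        for _, sec in sectionings.iterrows():
            tp, day = sec["time_point"], sec["sectioning_day"]
            sub = jar_st[jar_st["sectioning_day"] == day]
            vrates = {}
            for (top, bot), grp in sub.groupby(["depth_top_cm", "depth_bottom_cm"]):
                grp = grp.sort_values("day")
                series = JarSeries(station=station, depth_interval=(top, bot),
                                   times_d=tuple(grp["day"]),
                                   nh4_uM=tuple(grp["nh4_uM"]),
                                   porosity=float(grp["porosity"].iloc[0]),
                                   time_point=str(tp))
                vrates[(top, bot)] = fit_jar_rate(series, alpha=alpha)
            production = depth_integrate(vrates, station=station,
                                         time_point=str(tp))

            window = (prev_day, day)
            din = nh4 = nox = math.nan
            if flux_objs["NH4"] or flux_objs["NOx"]:
                agg_nh4 = aggregate_fluxes(flux_objs["NH4"], window)
                agg_nox = aggregate_fluxes(flux_objs["NOx"], window)
                nh4, nox = agg_nh4.value, agg_nox.value
                din = nh4 + nox
            accumulation = accumulation_rate(profile_at(prev_day), profile_at(day))
            b = nitrogen_budget(production, din_efflux=din, nox_efflux=nox,
                                accumulation=accumulation)
            rows.append((station, str(tp), day, b.production, b.din_efflux,
                         nh4, b.nox_efflux, b.accumulation,
                         b.potential_denitrification_raw,
                         b.potential_denitrification, b.potential_nh4_oxidation,
                         b.denitrified_fraction, b.negligible_denitrification,
                         b.complete))
            prev_day = day
    return pd.DataFrame(rows, columns=[
        "station", "time_point", "day", "production", "din_efflux",
        "nh4_efflux", "nox_efflux", "accumulation",
        "potential_denitrification_raw", "potential_denitrification",
        "potential_nh4_oxidation", "denitrified_fraction",
        "negligible_denitrification", "complete"])
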