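"""Seeded synthetic microcosm datasets with known ground truth.

The generator emulates a flooded-soil microcosm study: two stations with
contrasting organic-matter content, cores sectioned at a pre-flood baseline
plus four post-flood time points, six porewater depth intervals, four jar
incubation intervals, replicate-core flux incubations, T-RFLP
electropherograms with "boom and bust" OTU modules, and qPCR runs with
dilution-series standards.  Every dataset is tied to a
:class:`ScenarioTruth` so the downstream pipeline can be tested as a
recovery problem: the nitrogen budget of the truth closes exactly
(areal production = DIN efflux + porewater accumulation + denitrified
amount), and with all noise terms at zero the pipeline reproduces the truth
to numerical precision.

All randomness flows from ``ScenarioConfig.seed`` through named substreams
(one per data type), so regenerating one table never perturbs another.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import erfc

from .errors import ConfigError
from .nitrogen_budget import (JAR_LAYERS, POREWATER_LAYERS, INTERPOLATED_LAYER,
                              JarSeries)

STATION_NAMES = ("UC", "C")
TIME_LABELS = ("BF", "W1", "M2", "M4", "M6")
GENES = ("16S", "nirK", "nirS", "amoA_AOB", "amoA_AOA")

#: Core incubation geometry: 8 cm i.d. liner, ~5 cm headspace, 4 h runs.
CORE_AREA_M2 = math.pi * 0.04 ** 2
CORE_VOLUME_L = 0.25
FLUX_DURATION_D = 4.0 / 24.0

#: Flux measurement schedule (days after flooding): weekly for the first
#: month, biweekly for three months, monthly thereafter — 13 campaigns.
FLUX_DAYS = (1, 5, 9, 16, 23, 30, 44, 58, 86, 100, 114, 145, 176)

JAR_SAMPLING_DAYS = (0.0, 7.0, 14.0, 21.0, 28.0)

#: Porewater NH4+ inventory distributed over the six layers, peaked at the
#: 5-15 cm horizon where accumulation is typically highest.
INVENTORY_WEIGHTS = (0.05, 0.05, 0.15, 0.30, 0.30, 0.15)


@dataclass(frozen=True)
class MeasurementNoise:
    """Per-instrument noise magnitudes (standard deviations)."""

    flux_conc_uM: float = 0.15       # nutrient analysis, additive on µM
    jar_nh4_uM: float = 0.0          # jar series are fit-limited, not noisy
    porewater_rel: float = 0.01      # relative, porewater concentrations
    qpcr_cq_sd: float = 0.1          # Cq replicate noise
    peak_area_sd: float = 0.1        # lognormal sigma on individual peak areas
    total_area_sd: float = 0.15      # lognormal sigma on per-sample total signal

    @classmethod
    def none(cls) -> "MeasurementNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_denit_fractions() -> dict[str, tuple[float, ...]]:
    return {"UC": (0.65, 0.75, 0.85, 0.89), "C": (0.53, 0.40, 0.20, 0.0)}


def _default_production() -> dict[str, tuple[float, ...]]:
    # nmol cm-3 d-1 for the four jar layers (0-2, 2-5, 5-10, 15-20 cm)
    return {"UC": (120.0, 50.0, 20.0, 8.0), "C": (60.0, 25.0, 10.0, 5.0)}


def _default_multipliers() -> dict[str, tuple[float, ...]]:
    return {"UC": (0.6, 1.0, 1.2, 0.8), "C": (1.1, 0.9, 0.7, 0.6)}


def _default_porosity() -> dict[str, tuple[float, ...]]:
    return {"UC": (0.85, 0.80, 0.72, 0.65, 0.58, 0.52),
            "C": (0.62, 0.60, 0.55, 0.50, 0.47, 0.45)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth design of a synthetic microcosm scenario."""

    seed: int = 0
    n_stations: int = 2
    depth_intervals_porewater: tuple[tuple[float, float], ...] = POREWATER_LAYERS
    depth_intervals_jar: tuple[tuple[float, float], ...] = JAR_LAYERS
    time_points: tuple[float, ...] = (0.0, 7.0, 60.0, 120.0, 180.0)
    n_replicate_cores: int = 3
    otu_pool_size: int = 60
    n_modules: int = 4
    size_jitter_sd: float = 0.15          # bp
    noise_peak_rate: float = 25.0         # Poisson mean per electropherogram
    noise_area_scale: float = 40.0        # fluorescence units
    total_area: float = 5.0e4
    dirichlet_concentration: float = 150.0
    true_denit_fraction: dict[str, tuple[float, ...]] = field(
        default_factory=_default_denit_fractions)
    true_production_profile: dict[str, tuple[float, ...]] = field(
        default_factory=_default_production)
    production_multipliers: dict[str, tuple[float, ...]] = field(
        default_factory=_default_multipliers)
    porosity_profile: dict[str, tuple[float, ...]] = field(
        default_factory=_default_porosity)
    accumulation_share: float = 0.35      # share of non-denitrified production
    nox_share_of_din: tuple[float, ...] = (0.02, 0.35, 0.55, 0.65)
    qpcr_efficiency: float = 0.95
    measurement_noise: MeasurementNoise = field(default_factory=MeasurementNoise)

    @property
    def stations(self) -> tuple[str, ...]:
        base = list(STATION_NAMES)
        while len(base) < self.n_stations:
            base.append(f"S{len(base) + 1}")
        return tuple(base[: self.n_stations])

    @property
    def post_flood_days(self) -> tuple[float, ...]:
        return self.time_points[1:]

    def validate(self) -> None:
        def check_intervals(name, intervals, span):
            pos = intervals[0][0]
            for top, bot in intervals:
                if bot <= top or abs(top - pos) > 1e-9:
                    raise ConfigError(
                        f"{name}: intervals must be contiguous, ordered and "
                        f"non-overlapping (offending interval {top}-{bot})")
                pos = bot
            if abs(pos - span) > 1e-9:
                raise ConfigError(f"{name}: intervals must cover 0-{span} cm")

        check_intervals("depth_intervals_porewater",
                        self.depth_intervals_porewater, 20.0)
        if self.n_stations < 1:
            raise ConfigError("n_stations: must be >= 1")
        if len(self.time_points) < 2 or any(
                b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ConfigError("time_points: need pre-flood + increasing sectionings")
        if self.n_replicate_cores < 1:
            raise ConfigError("n_replicate_cores: must be >= 1")
        n_post = len(self.post_flood_days)
        for st in self.stations:
            for name, table, bounds in (
                    ("true_denit_fraction", self.true_denit_fraction, (0.0, 1.0)),
                    ("production_multipliers", self.production_multipliers, None)):
                if st not in table or len(table[st]) != n_post:
                    raise ConfigError(
                        f"{name}: need {n_post} values for station {st}")
                if bounds and any(not (bounds[0] <= v <= bounds[1])
                                  for v in table[st]):
                    raise ConfigError(f"{name}: values must be in {bounds}")
            if st not in self.true_production_profile or \
                    len(self.true_production_profile[st]) != len(self.depth_intervals_jar):
                raise ConfigError(
                    "true_production_profile: need one rate per jar layer "
                    f"for station {st}")
            phi = self.porosity_profile.get(st, ())
            if len(phi) != len(self.depth_intervals_porewater) or any(
                    not (0.0 < p < 1.0) for p in phi):
                raise ConfigError(
                    f"porosity_profile: station {st} needs one porosity in "
                    "(0,1) per porewater layer")
        if not (0.0 < self.accumulation_share < 1.0):
            raise ConfigError("accumulation_share: must be in (0,1)")
        if len(self.nox_share_of_din) != n_post or any(
                not (0.0 <= v <= 1.0) for v in self.nox_share_of_din):
            raise ConfigError(
                f"nox_share_of_din: need {n_post} fractions in [0,1]")
        if self.size_jitter_sd < 0:
            raise ConfigError("size_jitter_sd: must be >= 0")
        if self.noise_peak_rate < 0:
            raise ConfigError("noise_peak_rate: must be >= 0")
        if self.qpcr_efficiency <= 0:
            raise ConfigError("qpcr_efficiency: must be > 0")
        if self.otu_pool_size < self.n_modules * 2 + 10:
            raise ConfigError("otu_pool_size: too small for the module design")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator: independent per data type, seed-stable."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class DatasetBundle:
    """The generated CSV-shaped tables, kept as DataFrames."""

    peaks: pd.DataFrame
    jars: pd.DataFrame
    fluxes: pd.DataFrame
    porewater: pd.DataFrame
    qpcr: pd.DataFrame
    standards: pd.DataFrame
    metadata: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"peaks": self.peaks, "jars": self.jars, "fluxes": self.fluxes,
                "porewater": self.porewater, "qpcr": self.qpcr,
                "standards": self.standards, "metadata": self.metadata}

    def write(self, outdir) -> dict[str, str]:
        """Write each table as <name>.csv at full double precision."""
        import os
        paths = {}
        os.makedirs(outdir, exist_ok=True)
        for name, df in self.tables().items():
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False, float_format="%.17g")
            paths[name] = path
        return paths


@dataclass
class ScenarioTruth:
    """Ground truth of a scenario: the recovery-test oracle."""

    abundance: pd.DataFrame        # samples x OTUs, rows sum to 1
    otu_sizes: pd.Series           # OTU -> centroid fragment size (bp)
    otu_modules: pd.Series         # OTU -> module number (0 = not in a module)
    layer_rates: pd.DataFrame      # station, time_point, layer, rate
    budget: pd.DataFrame           # per station x post-flood time point
    gene_copies: pd.DataFrame      # sample_id, gene, copies_per_g_dry

    def to_json(self, path) -> None:
        payload = {
            "abundance": {"index": list(self.abundance.index),
                          "columns": list(self.abundance.columns),
                          "values": self.abundance.to_numpy().tolist()},
            "otu_sizes": self.otu_sizes.to_dict(),
            "otu_modules": {k: int(v) for k, v in self.otu_modules.items()},
            "layer_rates": self.layer_rates.to_dict(orient="list"),
            "budget": self.budget.to_dict(orient="list"),
            "gene_copies": self.gene_copies.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            p = json.load(fh)
        ab = pd.DataFrame(p["abundance"]["values"],
                          index=p["abundance"]["index"],
                          columns=p["abundance"]["columns"])
        return cls(abundance=ab,
                   otu_sizes=pd.Series(p["otu_sizes"]),
                   otu_modules=pd.Series(p["otu_modules"]),
                   layer_rates=pd.DataFrame(p["layer_rates"]),
                   budget=pd.DataFrame(p["budget"]),
                   gene_copies=pd.DataFrame(p["gene_copies"]))


# ---------------------------------------------------------------------------
# Element generators
# ---------------------------------------------------------------------------

def generate_jar_series(layer_rate: float, porosity: float, c0: float,
                        times: tuple[float, ...], noise_sd: float,
                        rng: np.random.Generator,
                        station: str = "SYN",
                        depth_interval: tuple[float, float] = (0.0, 2.0),
                        ) -> JarSeries:
    """Jar NH4+ series with porewater slope = layer_rate / porosity (µM d−1).

    1 µM is 1 nmol per cm³ of porewater, so a bulk volumetric rate divided by
    porosity is the porewater concentration slope.
    """
    if porosity <= 0 or porosity >= 1:
        raise ConfigError(f"porosity: must be in (0,1), got {porosity}")
    t = np.asarray(times, float)
    conc = c0 + (layer_rate / porosity) * t
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=len(t))
    conc = np.maximum(conc, 0.0)
    return JarSeries(station=station, depth_interval=depth_interval,
                     times_d=tuple(t), nh4_uM=tuple(conc), porosity=porosity)


def _electropherogram(abundances: pd.Series, otu_sizes: pd.Series,
                      config: ScenarioConfig, rng: np.random.Generator,
                      sample_id: str) -> pd.DataFrame:
    noise = config.measurement_noise
    present = abundances[abundances > 0]
    total_area = config.total_area * (
        math.exp(rng.normal(0.0, noise.total_area_sd))
        if noise.total_area_sd > 0 else 1.0)
    centroids = otu_sizes[present.index].to_numpy(float)
    jitter = (rng.normal(0.0, config.size_jitter_sd, size=len(present))
              if config.size_jitter_sd > 0 else np.zeros(len(present)))
    area_noise = (np.exp(rng.normal(0.0, noise.peak_area_sd, size=len(present)))
                  if noise.peak_area_sd > 0 else np.ones(len(present)))
    frames = [pd.DataFrame({
        "sample_id": sample_id,
        "size_bp": centroids + jitter,
        "area": present.to_numpy() * total_area * area_noise,
    })]
    if config.noise_peak_rate > 0:
        n_noise = rng.poisson(config.noise_peak_rate)
        if n_noise:
            frames.append(pd.DataFrame({
                "sample_id": sample_id,
                "size_bp": rng.uniform(50.0, 550.0, size=n_noise),
                "area": config.noise_area_scale * rng.uniform(0.75, 1.0, size=n_noise),
            }))
    return pd.concat(frames, ignore_index=True)


def generate_electropherogram(abundances: pd.Series, otu_sizes: pd.Series,
                              config: ScenarioConfig, rng: np.random.Generator,
                              sample_id: str = "SYN") -> pd.DataFrame:
    """One sample's peak table from its true OTU relative abundances.

    Each present OTU yields one peak at its centroid size plus Gaussian
    jitter (sd ``size_jitter_sd``), area proportional to abundance with
    multiplicative lognormal noise.  Poisson-count noise peaks land
    uniformly on the 50–550 bp window with low areas drawn from a narrow
    band, chosen so the downstream iterative area filter at factor 1.15
    removes them (see methods note).
    """
    total = float(abundances.sum())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ConfigError(f"abundances: must sum to 1, got {total}")
    return _electropherogram(abundances, otu_sizes, config, rng, sample_id)


# ---------------------------------------------------------------------------
# Community design
# ---------------------------------------------------------------------------

def _otu_roles(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Partition the OTU pool into core / module / station / marine roles."""
    n = config.otu_pool_size
    n_marine = max(4, n // 8)
    n_station = 2 * max(2, n // 16)
    module_size = max(2, (n - n_marine - n_station) // (config.n_modules + 2))
    n_module = module_size * config.n_modules
    n_core = n - n_marine - n_station - n_module
    idx = np.arange(n)
    roles = {
        "core": idx[:n_core],
        "modules": idx[n_core:n_core + n_module].reshape(config.n_modules,
                                                         module_size),
        "station": idx[n_core + n_module:n_core + n_module + n_station]
                   .reshape(2, n_station // 2),
        "marine": idx[n - n_marine:],
    }
    return roles


def _module_windows(n_modules: int, n_times: int) -> list[set[tuple[int, str]]]:
    """Disjoint occupancy windows over (time index, depth band).

    Emulates boom-and-bust dynamics: each module occupies a contiguous run of
    time points in one or both depth bands.
    """
    bands = ("surface", "deep")
    windows: list[set[tuple[int, str]]] = []
    base = [
        {(1, "surface"), (1, "deep"), (2, "surface"), (2, "deep")},
        {(0, "surface"), (1, "surface")},
        {(2, "surface"), (3, "surface")},
        {(3, "deep"), (4, "deep")},
    ]
    for m in range(n_modules):
        if m < len(base):
            windows.append({(t % n_times, b) for t, b in base[m]})
        else:
            t0 = m % n_times
            windows.append({(t0, bands[m % 2]), ((t0 + 1) % n_times, bands[m % 2])})
    return windows


def _sample_weights(config: ScenarioConfig, roles, windows, station_idx: int,
                    time_idx: int, band: str) -> np.ndarray:
    """Expected relative-abundance weights for one soil sample."""
    n = config.otu_pool_size
    w = np.zeros(n)
    active = [m for m, win in enumerate(windows) if (time_idx, band) in win]
    post_flood = time_idx > 0
    w_marine = 0.08 if post_flood else 0.0
    w_station = 0.10
    w_modules = 0.32 if active else 0.0
    w_core = 1.0 - w_marine - w_station - w_modules
    w[roles["core"]] = w_core / len(roles["core"])
    if active:
        for m in active:
            members = roles["modules"][m]
            w[members] = w_modules / (len(active) * len(members))
    st_members = roles["station"][min(station_idx, len(roles["station"]) - 1)]
    w[st_members] = w_station / len(st_members)
    if post_flood:
        invaders = roles["marine"][: len(roles["marine"]) // 2]
        w[invaders] = w_marine / len(invaders)
    return w


def _seawater_weights(config: ScenarioConfig, roles) -> np.ndarray:
    n = config.otu_pool_size
    w = np.zeros(n)
    w[roles["marine"]] = 0.75 / len(roles["marine"])
    shared = roles["core"][: max(1, len(roles["core"]) // 2)]
    w[shared] = 0.25 / len(shared)
    return w


def _dirichlet(weights: np.ndarray, conc: float, rng: np.random.Generator,
               exact: bool) -> np.ndarray:
    """Dirichlet draw around the weight vector (or the weights themselves)."""
    out = np.zeros_like(weights)
    present = weights > 0
    if exact:
        out[present] = weights[present]
    else:
        out[present] = rng.dirichlet(weights[present] * conc)
    return out


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _interp_rate(r_above: float, r_below: float) -> float:
    """Midpoint linear interpolation for the unmeasured 10-15 cm layer."""
    m, m1, m2 = 12.5, 7.5, 17.5
    return r_above + (m - m1) / (m2 - m1) * (r_below - r_above)


def _jar_porosity(config: ScenarioConfig, station: str,
                  jar_layer: tuple[float, float]) -> float:
    """Thickness-weighted mean porosity of the porewater layers a jar spans."""
    phis = config.porosity_profile[station]
    total_t, total_p = 0.0, 0.0
    for (top, bot), phi in zip(config.depth_intervals_porewater, phis):
        lo, hi = max(top, jar_layer[0]), min(bot, jar_layer[1])
        if hi > lo:
            total_t += hi - lo
            total_p += phi * (hi - lo)
    return total_p / total_t


def generate_scenario(config: ScenarioConfig) -> tuple[ScenarioTruth, DatasetBundle]:
    """Generate a complete dataset bundle plus its ground truth."""
    config.validate()
    noise = config.measurement_noise
    stations = config.stations
    n_post = len(config.post_flood_days)
    thick = {layer: layer[1] - layer[0] for layer in
             list(config.depth_intervals_jar) + [INTERPOLATED_LAYER]}

    # ---- true rates and the closed budget -------------------------------
    rate_rows, budget_rows = [], []
    for st in stations:
        base = config.true_production_profile[st]
        for k, day in enumerate(config.post_flood_days):
            tp = TIME_LABELS[k + 1] if k + 1 < len(TIME_LABELS) else f"T{k + 1}"
            mult = config.production_multipliers[st][k]
            rates = {layer: base[i] * mult
                     for i, layer in enumerate(config.depth_intervals_jar)}
            rates[INTERPOLATED_LAYER] = _interp_rate(rates[(5.0, 10.0)],
                                                     rates[(15.0, 20.0)])
            production = 0.01 * sum(r * thick[layer]
                                    for layer, r in rates.items())
            f = config.true_denit_fraction[st][k]
            denitrified = f * production
            remainder = production - denitrified
            accumulation = config.accumulation_share * remainder
            din_efflux = remainder - accumulation
            nox_efflux = config.nox_share_of_din[k] * din_efflux
            nh4_efflux = din_efflux - nox_efflux
            for layer, r in rates.items():
                rate_rows.append((st, tp, layer[0], layer[1], r))
            budget_rows.append((st, tp, day, production, din_efflux, nh4_efflux,
                                nox_efflux, accumulation, denitrified, f))
    layer_rates = pd.DataFrame(rate_rows, columns=[
        "station", "time_point", "depth_top_cm", "depth_bottom_cm", "rate"])
    budget = pd.DataFrame(budget_rows, columns=[
        "station", "time_point", "day", "production", "din_efflux",
        "nh4_efflux", "nox_efflux", "accumulation", "denitrified",
        "denit_fraction"])

    # ---- jar series ------------------------------------------------------
    rng_jar = config.rng("jars")
    jar_rows = []
    for st in stations:
        for k, day in enumerate(config.post_flood_days):
            tp = budget.query("station == @st").iloc[k]["time_point"]
            for layer in config.depth_intervals_jar:
                phi = _jar_porosity(config, st, layer)
                rate = float(layer_rates.query(
                    "station == @st and time_point == @tp and "
                    "depth_top_cm == @layer[0]")["rate"].iloc[0])
                series = generate_jar_series(rate, phi, c0=50.0,
                                             times=JAR_SAMPLING_DAYS,
                                             noise_sd=noise.jar_nh4_uM,
                                             rng=rng_jar, station=st,
                                             depth_interval=layer)
                for t, c in zip(series.times_d, series.nh4_uM):
                    jar_rows.append((st, tp, day, layer[0], layer[1], t, c, phi))
    jars = pd.DataFrame(jar_rows, columns=[
        "station", "time_point", "sectioning_day", "depth_top_cm",
        "depth_bottom_cm", "day", "nh4_uM", "porosity"])

    # ---- flux incubations ------------------------------------------------
    rng_flux = config.rng("fluxes")
    post_days = np.asarray(config.post_flood_days)
    flux_rows = []
    for st in stations:
        sub = budget[budget["station"] == st]
        for d in FLUX_DAYS:
            if d > post_days[-1]:
                continue
            k = int(np.searchsorted(post_days, d, side="left"))
            row = sub.iloc[k]
            for analyte, efflux, c0 in (("NH4", row["nh4_efflux"], 15.0),
                                        ("NOx", row["nox_efflux"], 5.0)):
                delta = efflux * 1000.0 * CORE_AREA_M2 * FLUX_DURATION_D / CORE_VOLUME_L
                for core in range(config.n_replicate_cores):
                    eps = (rng_flux.normal(0.0, noise.flux_conc_uM, size=2)
                           if noise.flux_conc_uM > 0 else np.zeros(2))
                    c_start = c0 + eps[0]
                    c_end = c0 + delta + eps[1]
                    flux_rows.append((f"{st}-F{d}-{core + 1}", st, float(d),
                                      analyte, c_start, c_end, CORE_VOLUME_L,
                                      CORE_AREA_M2, FLUX_DURATION_D))
    fluxes = pd.DataFrame(flux_rows, columns=[
        "core_id", "station", "day", "analyte", "c_start_uM", "c_end_uM",
        "volume_L", "area_m2", "duration_d"])

    # ---- porewater profiles ---------------------------------------------
    rng_pw = config.rng("porewater")
    weights = np.asarray(INVENTORY_WEIGHTS)
    pw_rows = []
    for st in stations:
        phis = config.porosity_profile[st]
        inventory = 0.5  # mmol m-2 pre-flood baseline, nearly zero
        prev_day = config.time_points[0]
        for k, day in enumerate(config.time_points):
            tp = TIME_LABELS[k] if k < len(TIME_LABELS) else f"T{k}"
            if k > 0:
                acc = float(budget.query(
                    "station == @st and day == @day")["accumulation"].iloc[0])
                inventory += acc * (day - prev_day)
            prev_day = day
            for (layer, w, phi) in zip(config.depth_intervals_porewater,
                                       weights, phis):
                t = layer[1] - layer[0]
                conc = inventory * w / (10.0 * phi * t)
                if noise.porewater_rel > 0:
                    conc *= 1.0 + rng_pw.normal(0.0, noise.porewater_rel)
                pw_rows.append((st, tp, day, layer[0], layer[1], "NH4",
                                max(conc, 0.0), phi))
                # NOx: confined to the top centimetre; Cl: diffusive front
                nox = 0.05 if layer[1] <= 1.0 else 0.002
                pw_rows.append((st, tp, day, layer[0], layer[1], "NOx", nox, phi))
                z = 0.5 * (layer[0] + layer[1])
                if day == 0:
                    cl = 5.0
                else:
                    cl = 30.0 + 330.0 * float(erfc(z / (2.0 * math.sqrt(1.0 * day))))
                pw_rows.append((st, tp, day, layer[0], layer[1], "Cl", cl, phi))
    porewater = pd.DataFrame(pw_rows, columns=[
        "station", "time_point", "sectioning_day", "depth_top_cm",
        "depth_bottom_cm", "analyte", "conc_mM", "porosity"])

    # ---- community truth + electropherograms ----------------------------
    rng_sizes = config.rng("sizes")
    rng_comm = config.rng("community")
    rng_peaks = config.rng("peaks")
    n_otus = config.otu_pool_size
    width = max(3, len(str(n_otus)))
    otu_ids = [f"OTU{i + 1:0{width}d}" for i in range(n_otus)]
    base_sizes = np.linspace(60.0, 540.0, n_otus)
    jitter_room = min(0.5, (base_sizes[1] - base_sizes[0] - 2.0) / 2) \
        if n_otus > 1 else 0.5
    sizes = base_sizes + rng_sizes.uniform(-max(jitter_room, 0.0),
                                           max(jitter_room, 0.0), size=n_otus)
    otu_sizes = pd.Series(sizes, index=otu_ids)

    roles = _otu_roles(config)
    windows = _module_windows(config.n_modules, len(config.time_points))
    modules = pd.Series(0, index=otu_ids, dtype=int)
    for m, members in enumerate(roles["modules"]):
        modules.iloc[members] = m + 1

    exact = (noise.peak_area_sd == 0 and noise.total_area_sd == 0)
    meta_rows, ab_rows, ab_index = [], [], []
    for si, st in enumerate(stations):
        for k, day in enumerate(config.time_points):
            tp = TIME_LABELS[k] if k < len(TIME_LABELS) else f"T{k}"
            for layer in config.depth_intervals_porewater:
                band = "surface" if layer[1] <= 2.0 else "deep"
                sid = f"{st}_{tp}_{layer[0]:g}-{layer[1]:g}"
                w = _sample_weights(config, roles, windows, si, k, band)
                ab = _dirichlet(w, config.dirichlet_concentration, rng_comm, exact)
                ab_rows.append(ab)
                ab_index.append(sid)
                meta_rows.append((sid, st, st, tp, day, layer[0], layer[1],
                                  0.5 * (layer[0] + layer[1]), band))
    for k, day in enumerate(config.time_points):
        tp = TIME_LABELS[k] if k < len(TIME_LABELS) else f"T{k}"
        for rep in "ab":
            sid = f"SW_{tp}_{rep}"
            w = _seawater_weights(config, roles)
            ab = _dirichlet(w, config.dirichlet_concentration, rng_comm, exact)
            ab_rows.append(ab)
            ab_index.append(sid)
            meta_rows.append((sid, "SW", "SW", tp, day, math.nan, math.nan,
                              math.nan, "water"))
    abundance = pd.DataFrame(ab_rows, index=ab_index, columns=otu_ids)
    metadata = pd.DataFrame(meta_rows, columns=[
        "sample_id", "group", "station", "time_point", "days",
        "depth_top_cm", "depth_bottom_cm", "depth_cm", "depth_band"])

    peak_frames = [
        _electropherogram(abundance.loc[sid], otu_sizes, config, rng_peaks, sid)
        for sid in abundance.index]
    peaks = pd.concat(peak_frames, ignore_index=True)

    # ---- qPCR ------------------------------------------------------------
    rng_q = config.rng("qpcr")
    slope = -1.0 / math.log10(1.0 + config.qpcr_efficiency)
    std_rows, q_rows, copy_rows = [], [], []
    intercepts = {g: 36.0 + i * 0.5 for i, g in enumerate(GENES)}
    for g in GENES:
        for e in range(1, 8):
            copies = 10.0 ** e
            cq = intercepts[g] + slope * e
            if noise.qpcr_cq_sd > 0:
                cq += rng_q.normal(0.0, noise.qpcr_cq_sd)
            std_rows.append((g, copies, cq))
    standards = pd.DataFrame(std_rows, columns=["gene", "copies", "cq"])

    gene_base = {"16S": 2.0e10, "nirK": 2.0e6, "nirS": 5.0e7,
                 "amoA_AOB": 1.0e5, "amoA_AOA": 7.0e4}
    gene_time_trend = {"16S": (1.0, 1.5, 1.2, 0.1, 0.08),
                       "nirK": (1.0, 2.0, 4.0, 8.0, 6.0),
                       "nirS": (1.0, 1.5, 1.2, 0.15, 0.1),
                       "amoA_AOB": (0.2, 0.5, 1.5, 5.0, 4.0),
                       "amoA_AOA": (1.0, 1.2, 2.0, 3.5, 4.5)}
    template_uL, elution_uL, wet_g = 2.0, 100.0, 0.35
    soil_meta = metadata[metadata["group"] != "SW"]
    time_index = {tp: i for i, tp in enumerate(
        TIME_LABELS[: len(config.time_points)])}
    for _, row in soil_meta.iterrows():
        phi = _jar_porosity(config, row["station"],
                            (row["depth_top_cm"], row["depth_bottom_cm"]))
        water_content = phi / (phi + (1 - phi) * 2.65)
        depth_decay = math.exp(-row["depth_cm"] / 8.0)
        for g in GENES:
            trend = gene_time_trend[g][time_index[row["time_point"]]]
            copies_g = gene_base[g] * trend * (0.3 + 0.7 * depth_decay) * \
                math.exp(rng_q.normal(0.0, 0.3))
            copy_rows.append((row["sample_id"], g, copies_g))
            dry_g = wet_g * (1.0 - water_content)
            copies_rxn = copies_g * dry_g / elution_uL * template_uL
            cq_true = intercepts[g] + slope * math.log10(copies_rxn)
            reps = cq_true + (rng_q.normal(0.0, noise.qpcr_cq_sd, size=2)
                              if noise.qpcr_cq_sd > 0 else np.zeros(2))
            q_rows.append((row["sample_id"], g, reps[0], reps[1], template_uL,
                           elution_uL, wet_g, water_content))
    qpcr = pd.DataFrame(q_rows, columns=[
        "sample_id", "gene", "cq_rep1", "cq_rep2", "template_uL",
        "elution_uL", "wet_mass_g", "water_content"])
    gene_copies = pd.DataFrame(copy_rows,
                               columns=["sample_id", "gene", "copies_per_g_dry"])

    truth = ScenarioTruth(abundance=abundance, otu_sizes=otu_sizes,
                          otu_modules=modules, layer_rates=layer_rates,
                          budget=budget, gene_copies=gene_copies)
    bundle = DatasetBundle(peaks=peaks, jars=jars, fluxes=fluxes,
                           porewater=porewater, qpcr=qpcr,
                           standards=standards, metadata=metadata)
    return truth, bundle
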