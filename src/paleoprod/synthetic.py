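"""Forward simulators with known ground truth.

Three generators emulate the statistical structure the downstream analysis
assumes, so every stage can be tested for parameter recovery without field
data:

* :func:`simulate_core` — a sediment core deposited under a constant (or
  piecewise-constant) dry-mass accumulation rate and constant unsupported
  ²¹⁰Pb flux, so that unsupported activity decays exponentially with
  cumulative dry mass; a Gaussian ¹³⁷Cs fallout pulse centred on the 1963
  moratorium; a chlorophyll-a history that is a flat baseline with a
  post-breakpoint linear rise; dibenzothiophenes (DBTs) at background before
  an industrial onset year and enriched after; and reflectance spectra whose
  650–700 nm peak area inverts a configured linear calibration.
* :func:`simulate_snow_grid` — snow-survey sites on a quasi-regular grid
  with an industry-centred exponentially decaying deposition plume plus
  nugget noise.
* :func:`simulate_climate` — annual and seasonal temperature series with a
  linear warming trend, plus trendless precipitation.

Every generator takes an explicit integer seed; there is no global random
state.  Activity noise is multiplicative Gaussian with a counting-error CV
(a counting-statistics approximation); chl-a and loading noise is additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paleoprod.spectral import ChlaCalibration

#: decay constant of 210Pb (half-life 22.3 yr)
PB210_LAMBDA = np.log(2.0) / 22.3

_SEASONS = ("annual", "winter", "spring", "summer", "fall")
# seasonal temperature offsets (degC) relative to the annual mean, loosely
# boreal-continental; only the shared linear trend matters downstream
_SEASON_OFFSET = {"annual": 0.0, "winter": -18.0, "spring": 1.0, "summer": 16.0, "fall": -1.0}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class CoreSimConfig:
    """Configuration of a synthetic sediment core (one lake)."""

    lake_id: str = "SIM-01"
    coring_year: int = 2014
    n_intervals: int = 80
    interval_thickness_cm: float = 0.5
    dry_mass_per_interval: float = 0.15  # g/cm^2 per interval
    pb210_flux: float = 0.1  # unsupported 210Pb supply, Bq/cm^2/yr
    supported_activity: float = 0.05  # Bq/g
    mass_accum_rate: float | list[tuple[float, float]] = 0.05  # g/cm^2/yr
    cs137_peak_year: float = 1963.0
    cs137_peak_activity: float = 0.25  # Bq/g
    cs137_age_sd: float = 3.0  # yr
    chla_baseline: float = 0.02  # mg/g
    chla_breakpoint_year: float = 1980.0
    chla_post_slope: float = 0.002  # mg/g per yr
    chla_noise_sd: float = 0.005  # mg/g
    chla_ar1: float = 0.0
    dbt_background: float = 20.0  # ng/g
    dbt_onset_year: float = 1967.0
    dbt_enrichment_ratio: float = 7.0
    counting_error_cv: float = 0.08
    calibration: ChlaCalibration = field(default_factory=ChlaCalibration)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            [self.mass_accum_rate]
            if np.isscalar(self.mass_accum_rate)
            else [r for _, r in self.mass_accum_rate]
        )
        positives = rates + [
            self.pb210_flux,
            self.supported_activity,
            self.chla_baseline,
            self.dbt_background,
            self.dbt_enrichment_ratio,
            self.dry_mass_per_interval,
            self.interval_thickness_cm,
        ]
        if any(v <= 0 for v in positives):
            raise InvalidConfigError("all rates and concentrations must be > 0")
        if self.chla_breakpoint_year >= self.coring_year:
            raise InvalidConfigError("chla_breakpoint_year must precede coring_year")
        if self.n_intervals < 2:
            raise InvalidConfigError("need at least 2 intervals")
        if self.counting_error_cv < 0 or self.chla_noise_sd < 0:
            raise InvalidConfigError("noise levels must be >= 0")


@dataclass
class SnowSimConfig:
    """Configuration of a synthetic snow-survey grid (one analyte)."""

    n_sites: int = 135
    extent_km: float = 100.0  # half-width of the sampling domain
    center: tuple[float, float] = (0.0, 0.0)  # km, industrial source
    background_loading: float = 5.0  # mg/m^2
    plume_amplitude: float = 50.0  # mg/m^2
    plume_decay_km: float = 15.0  # e-folding distance
    nugget_sd: float = 2.0  # mg/m^2
    swe_mean: float = 100.0  # mm
    swe_sd: float = 15.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plume_decay_km <= 0:
            raise InvalidConfigError("plume_decay_km must be > 0")
        if self.n_sites < 5:
            raise InvalidConfigError("need >= 5 snow sites (variogram unfittable)")
        if self.extent_km <= 0 or self.swe_mean <= 0:
            raise InvalidConfigError("extent and SWE must be > 0")


@dataclass
class ClimateSimConfig:
    """Configuration of a synthetic homogenized climate-station series."""

    start_year: int = 1916
    end_year: int = 2014
    base_temp: float = 0.5  # degC annual mean at start_year
    trend: float = 0.02  # degC / yr
    noise_sd: float = 0.8  # degC
    precip_mean: float = 450.0  # mm
    precip_sd: float = 60.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise InvalidConfigError("end_year must exceed start_year")
        if self.noise_sd < 0 or self.precip_sd < 0:
            raise InvalidConfigError("noise levels must be >= 0")


@dataclass
class SedimentCore:
    """A simulated (or assembled) core: interval table + spectra + truth."""

    lake_id: str
    coring_year: int
    intervals: pd.DataFrame
    wavelength_nm: np.ndarray
    reflectance: np.ndarray  # n_intervals x n_wavelengths
    config: CoreSimConfig | None = None


def _rate_schedule(config: CoreSimConfig) -> list[tuple[float, float]]:
    """Normalize mass_accum_rate to [(age_start, rate), ...] with age 0 first.

    Piecewise histories are given as (calendar_year, rate) pairs meaning
    "rate applies from that year forward (i.e. for ages younger than
    coring_year - year)"; internally we convert to age-since-coring pieces.
    """
    if np.isscalar(config.mass_accum_rate):
        return [(0.0, float(config.mass_accum_rate))]
    pairs = sorted(config.mass_accum_rate)  # by calendar year, oldest first
    pieces = [(0.0, float(pairs[-1][1]))]  # youngest rate applies from the surface
    for k in range(len(pairs) - 1, 0, -1):
        pieces.append((float(config.coring_year - pairs[k][0]), float(pairs[k - 1][1])))
    return pieces


def _age_mass_knots(config: CoreSimConfig, m_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Knots of the (age, cumulative mass) curve covering masses up to m_max."""
    pieces = _rate_schedule(config)
    ages = [0.0]
    masses = [0.0]
    for i, (a0, r) in enumerate(pieces):
        a1 = pieces[i + 1][0] if i + 1 < len(pieces) else None
        if a1 is None:
            # extend the last piece far enough to cover m_max
            ages.append(a0 + max((m_max - masses[-1]) / r, 1.0) * 1.01)
            masses.append(masses[-1] + (ages[-1] - a0) * r)
        else:
            ages.append(a1)
            masses.append(masses[-1] + (a1 - a0) * r)
    return np.array(ages), np.array(masses)


def simulate_core(config: CoreSimConfig) -> SedimentCore:
    """Forward-model a dated sediment core.

    Under a constant unsupported-²¹⁰Pb flux f and accumulation rate r(t), the
    unsupported activity at cumulative dry mass m is C(m) = f/r · exp(-λ·t(m))
    with λ = ln2/22.3 yr⁻¹ (for constant r, t = m/r so C = (f/r)·exp(-λ m/r)).
    True interval ages are stored in the output for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_intervals
    dm = np.full(n, float(config.dry_mass_per_interval))
    top = np.arange(n) * config.interval_thickness_cm
    bottom = top + config.interval_thickness_cm
    m_bounds = np.concatenate(([0.0], np.cumsum(dm)))
    m_mid = 0.5 * (m_bounds[:-1] + m_bounds[1:])

    age_knots, mass_knots = _age_mass_knots(config, m_bounds[-1])
    t_mid = np.interp(m_mid, mass_knots, age_knots)
    pieces = _rate_schedule(config)
    starts = np.array([a for a, _ in pieces])
    rates = np.array([r for _, r in pieces])
    rate_mid = rates[np.clip(np.searchsorted(starts, t_mid, side="right") - 1, 0, len(rates) - 1)]
    true_year = config.coring_year - t_mid

    unsupported_true = config.pb210_flux / rate_mid * np.exp(-PB210_LAMBDA * t_mid)
    supported_true = np.full(n, config.supported_activity)
    cv = config.counting_error_cv
    total_true = unsupported_true + supported_true
    total_obs = np.clip(total_true * (1.0 + cv * rng.standard_normal(n)), 0.0, None)
    total_sd = cv * total_true
    ra_obs = np.clip(supported_true * (1.0 + cv * rng.standard_normal(n)), 0.0, None)
    ra_sd = cv * supported_true

    cs_true = config.cs137_peak_activity * np.exp(
        -0.5 * ((true_year - config.cs137_peak_year) / config.cs137_age_sd) ** 2
    )
    cs_obs = np.clip(cs_true * (1.0 + cv * rng.standard_normal(n)), 0.0, None)
    cs_sd = cv * cs_true

    chla_true = config.chla_baseline + config.chla_post_slope * np.clip(
        true_year - config.chla_breakpoint_year, 0.0, None
    )
    noise = rng.standard_normal(n) * config.chla_noise_sd
    if config.chla_ar1 != 0.0:
        phi = config.chla_ar1
        for i in range(1, n):
            noise[i] += phi * noise[i - 1]
        noise *= np.sqrt(1.0 - phi**2)  # keep marginal SD at chla_noise_sd
    chla_obs = np.clip(chla_true + noise, 0.0, None)

    dbt_true = np.where(
        true_year >= config.dbt_onset_year,
        config.dbt_background * config.dbt_enrichment_ratio,
        config.dbt_background,
    )
    dbt_obs = np.clip(dbt_true * (1.0 + cv * rng.standard_normal(n)), 0.0, None)

    wavelength, reflectance = _spectra_for_chla(chla_obs, config.calibration)

    intervals = pd.DataFrame(
        {
            "lake_id": config.lake_id,
            "top_cm": top,
            "bottom_cm": bottom,
            "dry_mass_g_cm2": dm,
            "pb210_Bq_g": total_obs,
            "pb210_sd": total_sd,
            "ra226_Bq_g": ra_obs,
            "ra226_sd": ra_sd,
            "cs137_Bq_g": cs_obs,
            "cs137_sd": cs_sd,
            "chla_mg_g": chla_obs,
            "dbt_ng_g": dbt_obs,
            "true_year": true_year,
            "true_unsupported_Bq_g": unsupported_true,
            "true_chla_mg_g": chla_true,
        }
    )
    return SedimentCore(
        lake_id=config.lake_id,
        coring_year=config.coring_year,
        intervals=intervals,
        wavelength_nm=wavelength,
        reflectance=reflectance,
        config=config,
    )


def _spectra_for_chla(
    chla: np.ndarray, calibration: ChlaCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra whose chord-subtracted 650–700 nm peak area inverts the calibration.

    Baseline absorbance 0.5 with a triangular peak at 675 nm whose area equals
    (chla - intercept)/slope; any peak shape with the right area would do for
    the metric, and a triangle sampled on a grid containing 650/675/700 nm is
    integrated exactly by the trapezoidal rule.
    """
    wavelength = np.arange(400.0, 800.0 + 1e-9, 2.5)
    area = np.clip((np.asarray(chla) - calibration.intercept) / calibration.slope, 0.0, None)
    height = area / 25.0  # triangle area = 1/2 * 50 nm * height
    tri = np.clip(1.0 - np.abs(wavelength - 675.0) / 25.0, 0.0, None)
    absorbance = 0.5 + height[:, None] * tri[None, :]
    return wavelength, 10.0 ** (-absorbance)


@dataclass
class SnowSurvey:
    """Snow-survey site table with simulation truth attached."""

    sites: pd.DataFrame  # site_id, x_m, y_m, swe_mm, loading_mg_m2, conc_mg_L
    config: SnowSimConfig


def simulate_snow_grid(config: SnowSimConfig) -> SnowSurvey:
    """Quasi-regular snow-sampling grid around an industrial source.

    True loading = background + amplitude·exp(-d/decay) + nugget noise, with d
    the distance to the configured centre; loadings are truncated at 0 and
    concentrations back-computed as loading / SWE (1 mm SWE = 1 L/m²).
    """
    rng = np.random.default_rng(config.seed)
    n_side = int(np.ceil(np.sqrt(config.n_sites)))
    xs = np.linspace(-config.extent_km, config.extent_km, n_side)
    gx, gy = np.meshgrid(xs, xs)
    coords = np.column_stack([gx.ravel(), gy.ravel()])[: config.n_sites]
    # jitter off the exact lattice (quasi-regular, like a field survey)
    spacing = xs[1] - xs[0] if n_side > 1 else config.extent_km
    coords = coords + rng.uniform(-0.2, 0.2, coords.shape) * spacing

    d = np.hypot(coords[:, 0] - config.center[0], coords[:, 1] - config.center[1])
    loading = (
        config.background_loading
        + config.plume_amplitude * np.exp(-d / config.plume_decay_km)
        + rng.standard_normal(len(coords)) * config.nugget_sd
    )
    loading = np.clip(loading, 0.0, None)
    swe = np.clip(
        rng.normal(config.swe_mean, config.swe_sd, len(coords)), 1.0, None
    )
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(len(coords))],
            "x_m": coords[:, 0] * 1000.0,
            "y_m": coords[:, 1] * 1000.0,
            "swe_mm": swe,
            "loading_mg_m2": loading,
            "conc_mg_L": loading / swe,
        }
    )
    return SnowSurvey(sites=sites, config=config)


def simulate_climate(config: ClimateSimConfig) -> pd.DataFrame:
    """Annual + seasonal temperature series with a linear trend, plus precipitation.

    Returns a DataFrame indexed by year with columns ``temp_<season>`` for
    annual/winter/spring/summer/fall and matching ``precip_<season>`` columns
    (precipitation is trendless noise by default).
    """
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.start_year, config.end_year + 1)
    t = years - config.start_year
    out = {"year": years}
    for season in _SEASONS:
        out[f"temp_{season}"] = (
            config.base_temp
            + _SEASON_OFFSET[season]
            + config.trend * t
            + rng.standard_normal(len(years)) * config.noise_sd
        )
    for season in _SEASONS:
        scale = 1.0 if season == "annual" else 0.25
        out[f"precip_{season}"] = np.clip(
            rng.normal(config.precip_mean * scale, config.precip_sd * scale, len(years)),
            0.0,
            None,
        )
    return pd.DataFrame(out)
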