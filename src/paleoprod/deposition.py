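"""Snowpack nutrient loadings, ordinary kriging and radius-integrated deposition.

Late-winter snowpack integrates months of atmospheric deposition, so the
nutrient load at a site is simply concentration × snow-water equivalence
(SWE; 1 mm SWE = 1 L/m², hence mg/L × mm = mg/m²).  Site loadings are
interpolated onto a regular grid by ordinary kriging — the best linear
unbiased predictor with weights constrained to sum to 1, derived from a
semivariogram fitted to the empirical semivariance cloud — and the gridded
surface is integrated over a disc around the industrial centre to give a
deposition tonnage.  Surveys from winters with different snow-accumulation
periods are compared after normalizing to a common number of accumulation
days (a constant daily-deposition assumption).

Coordinates are projected metres throughout; geographic inputs must be
projected before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, spatial


class DepositionError(ValueError):
    pass


def site_loading(concentration: float | np.ndarray, swe_mm: float | np.ndarray):
    """Loading (mg/m²) = concentration (mg/L) × SWE (mm)."""
    concentration = np.asarray(concentration, dtype=float)
    swe_mm = np.asarray(swe_mm, dtype=float)
    if np.any(concentration < 0) or np.any(swe_mm <= 0):
        raise DepositionError("concentration must be >= 0 and SWE > 0")
    out = concentration * swe_mm
    return float(out) if out.ndim == 0 else out


@dataclass
class VariogramConfig:
    """Isotropic semivariogram: γ(h) = nugget + psill·g(h/range)."""

    model: str = "exponential"  # spherical | exponential | gaussian
    nugget: float = 0.0
    sill: float = 1.0  # total sill (nugget + partial sill)
    range_m: float = 10_000.0
    n_lags: int = 15
    max_lag_m: float | None = None  # default: half the maximum pair distance
    fitted: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("spherical", "exponential", "gaussian"):
            raise DepositionError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_m <= 0:
            raise DepositionError("require nugget >= 0, sill >= nugget, range > 0")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at separation h (m); γ(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        hr = h / self.range_m
        if self.model == "spherical":
            g = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
        elif self.model == "exponential":
            g = 1.0 - np.exp(-hr)
        else:  # gaussian
            g = 1.0 - np.exp(-(hr**2))
        return np.where(h > 0, self.nugget + psill * g, 0.0)


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_lags: int = 15, max_lag_m: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariance γ̂(h) = mean of ½(z_i − z_j)² per lag.

    Returns columns ``lag_m`` (bin midpoint of contributing pairs), ``gamma``
    and ``n_pairs``.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = spatial.distance.pdist(coords)
    sq = 0.5 * spatial.distance.pdist(values[:, None], metric="sqeuclidean")
    if max_lag_m is None:
        max_lag_m = 0.5 * d.max()
    edges = np.linspace(0.0, max_lag_m, n_lags + 1)
    idx = np.digitize(d, edges) - 1
    keep = (idx >= 0) & (idx < n_lags)
    rows = []
    for lag in range(n_lags):
        mask = keep & (idx == lag)
        if not mask.any():
            continue
        rows.append(
            {"lag_m": float(d[mask].mean()), "gamma": float(sq[mask].mean()), "n_pairs": int(mask.sum())}
        )
    return pd.DataFrame(rows)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    config: VariogramConfig | None = None,
    weights: str = "cressie",
) -> VariogramConfig:
    """Fit a variogram model to the empirical semivariance by weighted least
    squares.

    ``weights="cressie"`` (default) uses Cressie's relative weights
    N(h)/γ_model(h)², which keep the nugget- and range-defining short lags
    from being swamped by the far more numerous (and mutually correlated)
    long-lag pairs; ``weights="npairs"`` uses raw pair counts.  A spatially
    constant field yields a degenerate pure-nugget model with the
    ``degenerate`` flag set.
    """
    if config is None:
        config = VariogramConfig()
    if weights not in ("cressie", "npairs"):
        raise DepositionError(f"unknown weighting {weights!r}")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise DepositionError("need >= 10 sites to fit a variogram")
    if np.ptp(values) == 0:
        return VariogramConfig(
            model=config.model, nugget=0.0, sill=0.0 + 1e-12, range_m=config.range_m,
            fitted=True, degenerate=True,
        )

    emp = empirical_variogram(coords, values, n_lags=config.n_lags, max_lag_m=config.max_lag_m)
    h, g, w = emp["lag_m"].to_numpy(), emp["gamma"].to_numpy(), emp["n_pairs"].to_numpy()
    var = values.var()

    def residuals(theta):
        nugget, psill, rng = theta
        vc = VariogramConfig(model=config.model, nugget=nugget, sill=nugget + psill, range_m=rng)
        model = vc.gamma(h)
        if weights == "cressie":
            return np.sqrt(w) / np.maximum(model, 1e-12) * (model - g)
        return np.sqrt(w) * (model - g)

    x0 = np.array([max(g[0] * 0.5, 1e-9), max(var - g[0] * 0.5, 1e-9), h.max() / 3.0])
    res = optimize.least_squares(
        residuals,
        x0,
        bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, 10.0 * h.max()]),
    )
    nugget, psill, rng = res.x
    return VariogramConfig(
        model=config.model,
        nugget=float(nugget),
        sill=float(nugget + psill),
        range_m=float(rng),
        n_lags=config.n_lags,
        max_lag_m=config.max_lag_m,
        fitted=True,
    )


@dataclass
class GridSpec:
    """Regular grid of square cells; (x0, y0) is the centre of the first cell."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell_size_m: float = 1000.0

    @property
    def x(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.cell_size_m

    @property
    def y(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny) * self.cell_size_m

    @classmethod
    def covering(cls, xmin, xmax, ymin, ymax, cell_size_m=1000.0) -> "GridSpec":
        nx = int(np.ceil((xmax - xmin) / cell_size_m)) + 1
        ny = int(np.ceil((ymax - ymin) / cell_size_m)) + 1
        return cls(x0=xmin, y0=ymin, nx=nx, ny=ny, cell_size_m=cell_size_m)


@dataclass
class LoadingField:
    """Kriged loading surface: cell-centre coordinates, prediction + variance."""

    grid: GridSpec
    prediction: np.ndarray  # (ny, nx), mg/m^2
    variance: np.ndarray  # (ny, nx)
    analyte: str = ""
    clipped_negative: int = 0

    def to_frame(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.grid.x, self.grid.y)
        return pd.DataFrame(
            {
                "x_m": gx.ravel(),
                "y_m": gy.ravel(),
                "loading_mg_m2": self.prediction.ravel(),
                "kriging_variance": self.variance.ravel(),
            }
        )


def _dedupe(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    warnings.warn("duplicate site coordinates; averaging duplicates", stacklevel=3)
    means = np.zeros(len(uniq))
    counts = np.bincount(inverse)
    np.add.at(means, inverse, values)
    return uniq, means / counts


def _kriging_lhs(coords: np.ndarray, variogram: VariogramConfig) -> np.ndarray:
    n = len(coords)
    gamma = variogram.gamma(spatial.distance.squareform(spatial.distance.pdist(coords)))
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = gamma
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    lhs[n, n] = 0.0
    return lhs


def kriging_predict(
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    variogram: VariogramConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions at arbitrary target points.

    Solves the OK system [[Γ, 1], [1ᵀ, 0]]·[w; μ] = [γ₀; 1] per target and
    returns ``(prediction, variance, weights)`` with weights of shape
    (n_targets, n_sites).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if len(coords) < 2:
        raise DepositionError("need >= 2 sites for ordinary kriging")
    coords, values = _dedupe(coords, values)
    n = len(coords)
    lhs = _kriging_lhs(coords, variogram)
    gamma0 = variogram.gamma(spatial.distance.cdist(targets, coords))  # (m, n)
    rhs = np.column_stack([gamma0, np.ones(len(targets))])  # (m, n+1)
    try:
        sol = linalg.solve(lhs, rhs.T, assume_a="sym")  # (n+1, m)
    except linalg.LinAlgError as exc:
        raise DepositionError(f"singular kriging system: {exc}") from exc
    weights = sol[:n].T
    mu = sol[n]
    pred = weights @ values
    var = np.einsum("mn,mn->m", weights, gamma0) + mu
    return pred, np.clip(var, 0.0, None), weights


def ordinary_kriging(
    coords: np.ndarray,
    values: np.ndarray,
    variogram: VariogramConfig,
    grid: GridSpec,
    analyte: str = "",
) -> LoadingField:
    """Krige site loadings onto a regular grid of cell centres."""
    gx, gy = np.meshgrid(grid.x, grid.y)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    pred, var, _ = kriging_predict(coords, values, targets, variogram)
    return LoadingField(
        grid=grid,
        prediction=pred.reshape(grid.ny, grid.nx),
        variance=var.reshape(grid.ny, grid.nx),
        analyte=analyte,
    )


def cross_validate(
    coords: np.ndarray, values: np.ndarray, variogram: VariogramConfig
) -> pd.DataFrame:
    """Leave-one-out re-prediction of every site under a fixed variogram.

    Returns a per-site table (observed, predicted, error); summary statistics
    via :func:`cv_summary`.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise DepositionError("need >= 10 sites for cross validation")
    coords, values = _dedupe(coords, values)
    n = len(values)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        p, _, _ = kriging_predict(coords[mask], values[mask], coords[i : i + 1], variogram)
        preds[i] = p[0]
    return pd.DataFrame(
        {"x_m": coords[:, 0], "y_m": coords[:, 1], "observed": values, "predicted": preds,
         "error": preds - values}
    )


def cv_summary(cv: pd.DataFrame) -> dict:
    err = cv["error"].to_numpy()
    return {
        "mean_error": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "kriged_minus_measured_mean": float(cv["predicted"].mean() - cv["observed"].mean()),
        "n": int(len(cv)),
    }


def integrate_radius(
    field: LoadingField, center: tuple[float, float], radius_m: float
) -> float:
    """Deposition (tonnes) within a disc: Σ loading × cell area × 10⁻⁹ over
    cells whose centre lies inside the disc.

    Negative predictions are clipped to zero (loadings are physical masses);
    a disc extending beyond the gridded domain triggers a coverage warning,
    with the missing cells contributing zero.
    """
    if radius_m <= 0:
        raise DepositionError("radius must be > 0")
    g = field.grid
    if (
        center[0] - radius_m < g.x[0] - g.cell_size_m / 2
        or center[0] + radius_m > g.x[-1] + g.cell_size_m / 2
        or center[1] - radius_m < g.y[0] - g.cell_size_m / 2
        or center[1] + radius_m > g.y[-1] + g.cell_size_m / 2
    ):
        warnings.warn("integration disc extends beyond the gridded domain", stacklevel=2)
    gx, gy = np.meshgrid(g.x, g.y)
    inside = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= radius_m**2
    loading = np.clip(field.prediction, 0.0, None)
    field.clipped_negative = int(np.sum((field.prediction < 0) & inside))
    return float(np.sum(loading[inside]) * g.cell_size_m**2 * 1e-9)


def clustered_survey(
    n_primary: int = 75,
    n_duplicate: int = 75,
    n_satellite: int = 150,
    half_width_m: float = 500_000.0,
    duplicate_radius_m: tuple[float, float] = (50.0, 500.0),
    satellite_radius_m: tuple[float, float] = (5_000.0, 90_000.0),
    seed: int = 0,
) -> np.ndarray:
    """Coordinates of a clustered geostatistical survey.

    Widely spaced primary stations constrain the sill, near-duplicate pairs
    (tens to hundreds of metres apart, like field duplicates) constrain the
    nugget, and log-spaced satellites constrain the correlation range.  Used
    by the variogram-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    prim = rng.uniform(-half_width_m, half_width_m, (n_primary, 2))

    def ring(k: int, lo: float, hi: float) -> np.ndarray:
        base = prim[np.arange(k) % n_primary]
        ang = rng.uniform(0.0, 2 * np.pi, k)
        rad = 10 ** rng.uniform(np.log10(lo), np.log10(hi), k)
        return base + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])

    return np.vstack([prim, ring(n_duplicate, *duplicate_radius_m),
                      ring(n_satellite, *satellite_radius_m)])


def simulate_gaussian_field(
    coords: np.ndarray, variogram: VariogramConfig, seed: int = 0, mean: float = 0.0
) -> np.ndarray:
    """Sample a stationary Gaussian random field with the given variogram.

    The spatially structured part has covariance (sill − nugget)·ρ(h) and the
    nugget is added as independent noise; sampling is by Cholesky
    factorization of the site covariance matrix.
    """
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(coords)
    psill = variogram.sill - variogram.nugget
    d = spatial.distance.squareform(spatial.distance.pdist(coords))
    cov = psill - (variogram.gamma(d) - np.where(d > 0, variogram.nugget, 0.0))
    np.fill_diagonal(cov, psill)
    z = np.linalg.cholesky(cov + 1e-9 * max(psill, 1.0) * np.eye(n)) @ rng.standard_normal(n)
    return mean + z + rng.standard_normal(n) * np.sqrt(variogram.nugget)


def day_normalize(load_tonnes: float, days_source: float, days_target: float) -> float:
    """Rescale a tonnage between accumulation periods of different lengths,
    assuming constant daily deposition."""
    if days_source <= 0 or days_target <= 0:
        raise DepositionError("day counts must be > 0")
    return load_tonnes * days_target / days_source
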