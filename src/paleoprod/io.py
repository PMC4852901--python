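"""Delimited-text readers and writers.

All tables are plain CSV with documented headers; missing values are empty
fields (no sentinel numbers).  Simulated fixtures are written with the same
writers the real-data readers consume, so the two are interchangeable.

Core interval table columns:
    lake_id, top_cm, bottom_cm, dry_mass_g_cm2, pb210_Bq_g, pb210_sd,
    ra226_Bq_g, ra226_sd, cs137_Bq_g, cs137_sd
Spectrum table (long format): lake_id, interval_index, wavelength_nm, reflectance
Snow-site table: site_id, x_m, y_m, swe_mm, <analyte>_mg_L ...
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from paleoprod.dating import RadionuclideProfile
from paleoprod.deposition import LoadingField
from paleoprod.synthetic import SedimentCore

CORE_COLUMNS = [
    "lake_id", "top_cm", "bottom_cm", "dry_mass_g_cm2",
    "pb210_Bq_g", "pb210_sd", "ra226_Bq_g", "ra226_sd", "cs137_Bq_g", "cs137_sd",
]


def write_core_table(core: SedimentCore, path: str | Path) -> None:
    core.intervals[CORE_COLUMNS].to_csv(path, index=False)


def read_radionuclide_profile(path: str | Path) -> RadionuclideProfile:
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"core table missing columns: {missing}")
    return RadionuclideProfile.from_frame(df)


def write_spectra(core: SedimentCore, path: str | Path) -> None:
    n_int, n_wl = core.reflectance.shape
    pd.DataFrame(
        {
            "lake_id": core.lake_id,
            "interval_index": np.repeat(np.arange(n_int), n_wl),
            "wavelength_nm": np.tile(core.wavelength_nm, n_int),
            "reflectance": core.reflectance.ravel(),
        }
    ).to_csv(path, index=False)


def read_spectra(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (wavelength, reflectance-stack) from a long-format spectrum table."""
    df = pd.read_csv(path)
    pivot = df.pivot(index="interval_index", columns="wavelength_nm", values="reflectance")
    pivot = pivot.sort_index().sort_index(axis=1)
    return pivot.columns.to_numpy(dtype=float), pivot.to_numpy()


def write_snow_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, index=False)


def read_snow_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("site_id", "x_m", "y_m", "swe_mm"):
        if col not in df.columns:
            raise ValueError(f"snow table missing column {col!r}")
    return df


def write_field_csv(field: LoadingField, path: str | Path) -> None:
    field.to_frame().to_csv(path, index=False)


def write_field_geojson(field: LoadingField, path: str | Path) -> None:
    """Grid cells as GeoJSON polygon features with value + variance properties."""
    h = field.grid.cell_size_m / 2.0
    features = []
    for j, yc in enumerate(field.grid.y):
        for i, xc in enumerate(field.grid.x):
            ring = [
                [xc - h, yc - h], [xc + h, yc - h], [xc + h, yc + h],
                [xc - h, yc + h], [xc - h, yc - h],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "loading_mg_m2": float(field.prediction[j, i]),
                        "kriging_variance": float(field.variance[j, i]),
                        "analyte": field.analyte,
                    },
                }
            )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
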