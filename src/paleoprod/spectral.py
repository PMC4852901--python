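"""Sedimentary chlorophyll-a inference from visible reflectance spectra.

Whole-lake primary production leaves a sedimentary signature in chlorophyll-a
and its diagenetic products, which absorb between roughly 650 and 700 nm.
The inference used here is deliberately simple and robust: convert
reflectance to absorbance, subtract a chord baseline across the 650–700 nm
band, integrate the residual peak, and map the peak area to a concentration
through a linear calibration.  Because the metric integrates over the whole
chlorophyll degradation suite it is insensitive to post-depositional
diagenesis, which is what makes it usable downcore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BAND_LO = 650.0
BAND_HI = 700.0


class SpectrumError(ValueError):
    """Raised for spectra that cannot support the peak-area metric."""


@dataclass(frozen=True)
class ChlaCalibration:
    """Linear calibration from peak area (nm·AU) to chl-a (mg/g dry weight).

    The slope/intercept defaults of 1.0 / 0.0 are placeholders: the published
    calibrations for this metric are instrument-lineage specific and must be
    supplied by the user for results in physical units.  ``detection_limit``
    is the concentration below which inferences are reported as censored.
    """

    slope: float = 1.0
    intercept: float = 0.0
    detection_limit: float = 0.01

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be >= 0")


@dataclass
class ReflectanceSpectrum:
    """A single reflectance spectrum: wavelength (nm) vs reflectance (0, 1]."""

    wavelength: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.shape != self.reflectance.shape:
            raise SpectrumError("wavelength and reflectance must be 1-D and equal length")
        if not np.all(np.diff(self.wavelength) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.any(self.reflectance <= 0):
            raise SpectrumError("reflectance must be > 0 for absorbance to be defined")
        if self.wavelength[0] > BAND_LO or self.wavelength[-1] < BAND_HI:
            raise SpectrumError(
                f"spectrum must cover the {BAND_LO:.0f}-{BAND_HI:.0f} nm band"
            )


def absorbance_from_reflectance(spectrum: ReflectanceSpectrum) -> np.ndarray:
    """Apparent absorbance A = log10(1/R)."""
    return np.log10(1.0 / spectrum.reflectance)


def peak_area_650_700(wavelength: np.ndarray, absorbance: np.ndarray) -> float:
    """Chord-subtracted trapezoidal area of the 650–700 nm absorbance peak.

    The baseline is the straight line joining the absorbance at 650 and
    700 nm (linearly interpolated if those wavelengths are not sampled);
    negative residuals are clipped so a featureless spectrum has area zero.
    Returns the area in nm·absorbance-units.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if wavelength[0] > BAND_LO or wavelength[-1] < BAND_HI:
        raise SpectrumError("absorbance series does not cover 650-700 nm")

    # resample onto the band, keeping in-band samples and exact endpoints
    inside = (wavelength > BAND_LO) & (wavelength < BAND_HI)
    wl = np.concatenate(([BAND_LO], wavelength[inside], [BAND_HI]))
    a_lo = np.interp(BAND_LO, wavelength, absorbance)
    a_hi = np.interp(BAND_HI, wavelength, absorbance)
    ab = np.concatenate(([a_lo], absorbance[inside], [a_hi]))
    if wl.size < 3:
        raise SpectrumError("need at least 3 samples in the 650-700 nm band")

    chord = a_lo + (a_hi - a_lo) * (wl - BAND_LO) / (BAND_HI - BAND_LO)
    residual = np.clip(ab - chord, 0.0, None)
    return float(np.trapezoid(residual, wl))


def infer_chla(area: float, calibration: ChlaCalibration) -> tuple[float, bool]:
    """Map a peak area to a chl-a concentration (mg/g dry weight).

    Returns ``(concentration, censored)``; inferences below the calibration's
    detection limit are reported *at* the detection limit with ``censored``
    set, mirroring how such censored values are carried in downcore profiles.
    """
    if area < 0:
        raise ValueError("peak area must be >= 0")
    chla = calibration.slope * area + calibration.intercept
    if chla < calibration.detection_limit:
        return calibration.detection_limit, True
    return float(chla), False


def infer_profile(
    wavelength: np.ndarray, reflectance: np.ndarray, calibration: ChlaCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inference over a stack of spectra (n_intervals × n_wavelengths).

    Returns (chla, censored) arrays, one entry per spectrum row.
    """
    reflectance = np.atleast_2d(np.asarray(reflectance, dtype=float))
    chla = np.empty(reflectance.shape[0])
    censored = np.zeros(reflectance.shape[0], dtype=bool)
    for i, row in enumerate(reflectance):
        spec = ReflectanceSpectrum(wavelength, row)
        area = peak_area_650_700(spec.wavelength, absorbance_from_reflectance(spec))
        chla[i], censored[i] = infer_chla(area, calibration)
    return chla, censored
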