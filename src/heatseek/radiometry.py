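"""Blackbody radiometry of a thermal-IR stimulus.

Covers the calculations used to characterise a warm plate as an IR source
for behavioural work: Wien's displacement law for the emission peak,
Planck band fractions (how much of the emitted power falls in a wavelength
band), Stefan-Boltzmann radiant exitance, the hemispheric interception
fraction of a small detector, and a mV-ratio calibration of lock-in
detector readings against a reference blackbody.

Human skin near 34 degC (307.15 K) peaks around 9.4 um with roughly 90% of
its energy between 3 and 30 um, which is why a 34 degC source is the
ethologically relevant stimulus.

Units: temperatures in kelvin internally (helpers accept Celsius);
wavelengths in micrometres; exitance in W/m^2; detector geometry in mm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants, integrate

#: Wien displacement constant, um*K (fixed, documented).
WIEN_B_UM_K = 2897.77
#: Stefan-Boltzmann constant, W m^-2 K^-4 (CODATA).
SIGMA_W_M2_K4 = constants.Stefan_Boltzmann
#: Second radiation constant h*c/k in um*K.
C2_UM_K = 1e6 * constants.h * constants.c / constants.k


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + 273.15


@dataclass(frozen=True)
class BlackbodySource:
    """An IR-emitting surface: temperature, emissivity and emitting area."""

    temperature_k: float
    emissivity: float = 1.0
    area_m2: float = 0.01  # a 10 cm x 10 cm plate

    def __post_init__(self) -> None:
        if self.temperature_k < 0:
            raise ValueError("temperature must be >= 0 K")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must lie in (0, 1]")
        if self.area_m2 <= 0:
            raise ValueError("area must be positive")


@dataclass(frozen=True)
class DetectorGeometry:
    """A small sensor at a distance from the source."""

    sensor_area_mm2: float = 1.0
    distance_mm: float = 80.0

    def __post_init__(self) -> None:
        if self.sensor_area_mm2 < 0:
            raise ValueError("sensor area must be >= 0")
        if self.distance_mm <= 0:
            raise ValueError("distance must be positive")


@dataclass(frozen=True)
class CalibrationReference:
    """Reference blackbody readings: (temperature K, lock-in signal mV) pairs."""

    temperatures_k: tuple[float, ...]
    signals_mv: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.temperatures_k) != len(self.signals_mv) or len(self.temperatures_k) < 2:
            raise ValueError("need >= 2 matched (temperature, signal) pairs")
        if len(set(self.temperatures_k)) != len(self.temperatures_k):
            raise ValueError("reference temperatures must be distinct")
        if any(s < 0 for s in self.signals_mv):
            raise ValueError("reference signals must be >= 0")


def wien_peak_wavelength(temperature_k: float) -> float:
    """Peak emission wavelength (um) by Wien's displacement law: b / T."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return WIEN_B_UM_K / temperature_k


def _planck_x_integrand(x: float) -> float:
    if x > 700.0:  # e^x overflows double precision; the tail is numerically zero
        return 0.0
    return x**3 / math.expm1(x)


def planck_band_fraction(temperature_k: float, lam_low_um: float, lam_high_um: float) -> float:
    """Fraction of total blackbody exitance within [lam_low, lam_high] um.

    Integrates the Planck spectral exitance over the band and divides by
    sigma*T^4, via the substitution x = c2/(lambda*T), for which the total
    integral of x^3/(e^x - 1) is pi^4/15.  Adaptive quadrature, relative
    tolerance well below 1e-6.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    if lam_low_um < 0 or lam_high_um < lam_low_um:
        raise ValueError("need 0 <= lam_low <= lam_high")
    if lam_high_um == lam_low_um:
        return 0.0
    x_hi = C2_UM_K / (lam_low_um * temperature_k) if lam_low_um > 0 else np.inf
    x_lo = C2_UM_K / (lam_high_um * temperature_k) if np.isfinite(lam_high_um) else 0.0
    val, _ = integrate.quad(_planck_x_integrand, x_lo, x_hi,
                            epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(val * 15.0 / math.pi**4)


def radiant_exitance(temperature_k: float, emissivity: float = 1.0) -> float:
    """Stefan-Boltzmann radiant exitance: emissivity * sigma * T^4 (W/m^2)."""
    if temperature_k < 0:
        raise ValueError("temperature must be >= 0 K")
    if not 0 < emissivity <= 1:
        raise ValueError("emissivity must lie in (0, 1]")
    return emissivity * SIGMA_W_M2_K4 * temperature_k**4


def interception_fraction(geometry: DetectorGeometry) -> float:
    """Fraction of emitted radiation intercepted by the sensor.

    Ratio of the sensor area to the hemisphere of radius equal to the
    source-sensor distance (uniform angular emission); declines with the
    inverse square of the distance.
    """
    return geometry.sensor_area_mm2 / (2.0 * math.pi * geometry.distance_mm**2)


def calibrate_intensity(measured_mv: float, reference: CalibrationReference,
                        geometry: DetectorGeometry, source: BlackbodySource) -> float:
    """IR power (W) at the sensor, scaled from a reference-blackbody plot.

    The blackbody-predicted power at the sensor (exitance x source area x
    interception fraction) is scaled by the ratio of the measured lock-in
    signal to the reference blackbody signal at the source temperature.
    The reference signal is interpolated linearly in sigma*T^4 (the
    physical quantity the signal tracks), with no extrapolation outside the
    reference temperature range.
    """
    if measured_mv < 0:
        raise ValueError("measured signal must be >= 0")
    xs = SIGMA_W_M2_K4 * np.asarray(reference.temperatures_k, dtype=float) ** 4
    order = np.argsort(xs)
    xs = xs[order]
    mv = np.asarray(reference.signals_mv, dtype=float)[order]
    x_src = SIGMA_W_M2_K4 * source.temperature_k**4
    if x_src < xs[0] or x_src > xs[-1]:
        raise ValueError("source temperature outside the reference range (no extrapolation)")
    ref_mv = float(np.interp(x_src, xs, mv))
    if ref_mv <= 0:
        raise ValueError("interpolated reference signal is not positive")
    predicted_w = (radiant_exitance(source.temperature_k, source.emissivity)
                   * source.area_m2 * interception_fraction(geometry))
    return predicted_w * measured_mv / ref_mv


def trunk_facing_area_m2(total_body_area_m2: float = 1.7,
                         trunk_fraction: float = 0.36,
                         facing_fraction: float = 0.45) -> float:
    """Surface area of an adult human trunk facing an observer (~0.28 m^2).

    Total body surface area times the trunk's share of it times the share
    of the trunk visible from the front or back.
    """
    return total_body_area_m2 * trunk_fraction * facing_fraction


def plate_area_m2(width_cm: float, height_cm: float) -> float:
    """Area of a rectangular emitting plate given its sides in cm."""
    return (width_cm / 100.0) * (height_cm / 100.0)
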