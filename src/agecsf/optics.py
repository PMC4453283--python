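"""Age- and luminance-dependent optics of the eye.

Pupil diameter (unified-formula luminance model plus a linear senile-miosis
age correction), retinal illuminance with the Stiles-Crawford correction,
and the optical modulation transfer function (MTF) of the eye modelled as a
Gaussian low-pass filter parameterised by a dimensionless standard deviation
``sigma_opt`` and a cut-off frequency ``u_opt`` (cpd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViewingConditions",
    "ObserverProfile",
    "MIN_AGE",
    "REFERENCE_AGE",
    "stanley_davies_diameter",
    "pupil_diameter",
    "retinal_illuminance",
    "optical_sd",
    "optical_mtf",
]

#: Lower age limit of the model domain (years). The fitted analytical age
#: curves are undefined below this age.
MIN_AGE = 17.0

#: Reference age (years) at which the age correction of the pupil model
#: vanishes, so the pupil equals the luminance-only diameter.
REFERENCE_AGE = 28.58


@dataclass(frozen=True)
class ViewingConditions:
    """Photometric and geometric conditions of a CSF measurement.

    Parameters
    ----------
    luminance : float
        Adaptation luminance ``L`` in cd/m^2 (photopic range intended).
    field_x, field_y : float
        Angular field sizes ``X`` and ``Y`` in degrees. ``field_y``
        defaults to ``field_x`` (square field).
    stimulus_area : float, optional
        Stimulus area ``S`` in deg^2; defaults to ``X * Y``.
    eyes : int
        1 for monocular, 2 for binocular viewing.
    presentation_time : float
        Stimulus presentation time ``To`` in seconds; defaults to
        unbounded, in which case the effective time is the eye's
        integration time.
    eccentricity : float
        Retinal eccentricity ``e`` in degrees (0 = fovea).
    """

    luminance: float
    field_x: float
    field_y: float | None = None
    stimulus_area: float | None = None
    eyes: int = 2
    presentation_time: float = math.inf
    eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if self.field_y is None:
            object.__setattr__(self, "field_y", self.field_x)
        if self.stimulus_area is None:
            object.__setattr__(self, "stimulus_area", self.field_x * self.field_y)
        if not self.luminance > 0:
            raise ValueError(f"luminance must be > 0, got {self.luminance}")
        if not (self.field_x > 0 and self.field_y > 0):
            raise ValueError("field sizes must be > 0")
        if not self.stimulus_area > 0:
            raise ValueError("stimulus_area must be > 0")
        if self.eyes not in (1, 2):
            raise ValueError(f"eyes must be 1 or 2, got {self.eyes}")
        if not self.presentation_time > 0:
            raise ValueError("presentation_time must be > 0")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")

    def effective_time(self, integration_time: float) -> float:
        """Effective summation time ``T = min(Te, To)`` in seconds."""
        return min(integration_time, self.presentation_time)


@dataclass(frozen=True)
class ObserverProfile:
    """Observer described by age in years (the model's central covariate)."""

    age: float

    def __post_init__(self) -> None:
        if self.age < MIN_AGE:
            raise ValueError(
                f"age must be >= {MIN_AGE} years (model domain), got {self.age}"
            )


_FIELD_FACTOR = {1: 0.1, 2: 1.0}


def stanley_davies_diameter(luminance, stimulus_area, eyes=2):
    """Luminance-driven pupil diameter (mm), age correction not applied.

    Unified pupil formula: ``D = 7.75 - 5.75 * x / (x + 2)`` with
    ``x = (L * S * F(n) / 846)**0.41`` where ``F(1) = 0.1`` (monocular) and
    ``F(2) = 1`` (binocular). Bounded in (2.0, 7.75) mm.

    Parameters
    ----------
    luminance : float or array
        Adaptation luminance in cd/m^2, > 0.
    stimulus_area : float or array
        Stimulus area in deg^2, > 0.
    eyes : int
        1 (monocular) or 2 (binocular).
    """
    luminance = np.asarray(luminance, dtype=float)
    stimulus_area = np.asarray(stimulus_area, dtype=float)
    if np.any(luminance <= 0):
        raise ValueError("luminance must be > 0")
    if np.any(stimulus_area <= 0):
        raise ValueError("stimulus_area must be > 0")
    try:
        factor = _FIELD_FACTOR[int(eyes)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"eyes must be 1 or 2, got {eyes}") from None
    x = (luminance * stimulus_area * factor / 846.0) ** 0.41
    diameter = 7.75 - 5.75 * x / (x + 2.0)
    return diameter if diameter.ndim else float(diameter)


def pupil_diameter(age, luminance, stimulus_area, eyes=2):
    """Age-corrected pupil diameter (mm): senile miosis model.

    ``d = D + (A - 28.58) * (0.02132 - 0.009562 * D)`` with ``D`` the
    luminance-only diameter. At the reference age 28.58 years the result
    equals ``D`` exactly. For bright conditions (``D`` above ~2.23 mm) the
    slope is negative, so the pupil shrinks with age.

    Raises
    ------
    ValueError
        If an extreme extrapolation produces a non-positive diameter
        (never clamped: downstream noise terms would be corrupted).
    """
    age = np.asarray(age, dtype=float)
    base = np.asarray(stanley_davies_diameter(luminance, stimulus_area, eyes))
    diameter = base + (age - REFERENCE_AGE) * (0.02132 - 0.009562 * base)
    if np.any(diameter <= 0):
        raise ValueError(
            "age-corrected pupil diameter is non-positive: the age model is "
            "being extrapolated outside its physiological domain"
        )
    return diameter if diameter.ndim else float(diameter)


def retinal_illuminance(diameter, luminance):
    """Retinal illuminance in trolands with the Stiles-Crawford correction.

    ``E = (pi * L * d^2 / 4) * (1 - (d/9.7)^2 + (d/12.4)^4)`` with ``d`` in
    mm and ``L`` in cd/m^2. Linear in ``L``; positive for pupils in the
    physiological range.
    """
    diameter = np.asarray(diameter, dtype=float)
    luminance = np.asarray(luminance, dtype=float)
    if np.any(diameter <= 0):
        raise ValueError("pupil diameter must be > 0")
    if np.any(luminance <= 0):
        raise ValueError("luminance must be > 0")
    stiles_crawford = 1.0 - (diameter / 9.7) ** 2 + (diameter / 12.4) ** 4
    illuminance = math.pi * luminance * diameter**2 / 4.0 * stiles_crawford
    return illuminance if illuminance.ndim else float(illuminance)


def optical_sd(sigma0, diameter, cab=0.08):
    """Standard deviation of the optical MTF.

    ``sigma_opt = sqrt(sigma0^2 + (Cab * d)^2)``: an age-dependent
    baseline blur ``sigma0`` combined in quadrature with a pupil-dependent
    aberration term. All three quantities are treated as dimensionless
    numbers (the frequency normalisation happens in :func:`optical_mtf`).
    """
    if np.any(np.asarray(sigma0) < 0) or np.any(np.asarray(cab) < 0):
        raise ValueError("sigma0 and cab must be non-negative")
    if np.any(np.asarray(diameter) <= 0):
        raise ValueError("pupil diameter must be > 0")
    result = np.sqrt(np.asarray(sigma0, dtype=float) ** 2 + (cab * np.asarray(diameter, dtype=float)) ** 2)
    return result if result.ndim else float(result)


def optical_mtf(u, sigma_opt, u_opt):
    """Gaussian optical MTF: ``exp(-2 pi^2 sigma_opt^2 (u / u_opt)^2)``.

    Parameters
    ----------
    u : float or array
        Spatial frequency in cpd, >= 0.
    sigma_opt : float
        Dimensionless optical standard deviation (see :func:`optical_sd`).
    u_opt : float
        Optical cut-off frequency in cpd, > 0.

    Returns
    -------
    float or ndarray in (0, 1], equal to 1 at ``u = 0``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("spatial frequency must be >= 0")
    if not u_opt > 0:
        raise ValueError(f"u_opt must be > 0, got {u_opt}")
    result = np.exp(-2.0 * math.pi**2 * sigma_opt**2 * (u / u_opt) ** 2)
    return result if result.ndim else float(result)
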