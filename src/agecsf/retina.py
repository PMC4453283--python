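"""Retinal stage of the CSF model.

Cone and ganglion-cell density models as functions of age and eccentricity,
the lateral-inhibition (neural) MTF with its ganglion-density-driven
peripheral cut-off, and the photon and neural noise spectral densities.

Densities are expressed in relative units: only density *ratios* enter the
CSF, so the absolute scale (the literature sources use cells/mm^2) is
immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityModelConstants",
    "NoiseConstants",
    "DENSITY_DEFAULTS",
    "NOISE_DEFAULTS",
    "cone_density",
    "eccentricity_scale",
    "ganglion_density",
    "inhibition_cutoff",
    "lateral_mtf",
    "photon_noise",
    "neural_noise",
]


@dataclass(frozen=True)
class DensityModelConstants:
    """Constants of the cone/ganglion density models.

    The foveal cone density declines linearly with age
    (``cone_intercept - cone_slope * A``) on top of an eccentricity decay
    ``exp(-cone_ecc_rate * e)`` towards ``cone_floor``. Ganglion cells are
    tied to cones by a fixed ~3:1 convergence ratio; their eccentricity
    falloff is a two-lobe Lorentzian mixture whose primary scale ``a(A)``
    itself depends on age and whose secondary scale is fixed at 7.3 deg.
    The ``bracket_*`` entries parameterise the age-independent receptive
    field bracket used by the peripheral inhibition cut-off (weights sum to
    exactly 1 at e = 0).
    """

    cone_slope: float = 38.70          # per year
    cone_intercept: float = 6952.7     # relative density
    cone_floor: float = 300.0          # relative density
    cone_ecc_rate: float = 0.35        # per deg
    ganglion_cone_ratio: float = 3.0
    primary_weight: float = 0.85
    secondary_weight: float = 0.15
    secondary_ecc_scale: float = 7.3   # deg
    scale_coef_1: float = -0.404       # a(A) first term coefficient
    scale_rate_1: float = -0.01246     # per year
    scale_coef_2: float = -0.1792      # a(A) second term coefficient
    scale_rate_2: float = 0.01525      # per year
    bracket_weights: tuple = (0.85, 0.13, 0.02)
    bracket_scales: tuple = (4.0, 20.0)  # deg


@dataclass(frozen=True)
class NoiseConstants:
    """Constants of the photon- and neural-noise terms.

    ``photon_conversion`` (p) is in photons s^-1 deg^-2 Td^-1;
    ``foveal_neural_noise`` (Phi_neu at e = 0, any age) in s*deg^2;
    ``foveal_inhibition_cutoff`` (u_inh at e = 0) in cpd;
    ``integration_time`` (Te) in seconds.
    """

    photon_conversion: float = 1.285e6
    foveal_neural_noise: float = 3e-8
    foveal_inhibition_cutoff: float = 7.0
    integration_time: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "photon_conversion",
            "foveal_neural_noise",
            "foveal_inhibition_cutoff",
            "integration_time",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


DENSITY_DEFAULTS = DensityModelConstants()
NOISE_DEFAULTS = NoiseConstants()


def cone_density(age, eccentricity, constants: DensityModelConstants = DENSITY_DEFAULTS):
    """Cone density (relative units) at age ``A`` and eccentricity ``e``.

    ``N_c(A, e) = (6952.7 - 38.70 A) * exp(-0.35 e) + 300``: the age-related
    loss is confined to the fovea, and the density decays towards a floor of
    300 with eccentricity. Decreasing in both arguments.
    """
    age = np.asarray(age, dtype=float)
    eccentricity = np.asarray(eccentricity, dtype=float)
    if np.any(eccentricity < 0):
        raise ValueError("eccentricity must be >= 0")
    foveal = constants.cone_intercept - constants.cone_slope * age
    if np.any(foveal + constants.cone_floor <= 0):
        raise ValueError("cone density is non-positive: absurd extrapolated age")
    density = foveal * np.exp(-constants.cone_ecc_rate * eccentricity) + constants.cone_floor
    return density if density.ndim else float(density)


def eccentricity_scale(age, constants: DensityModelConstants = DENSITY_DEFAULTS):
    """Primary eccentricity scale ``a(A)`` (deg) of the ganglion falloff.

    ``a(A) = -0.404 exp(-0.01246 A) - 0.1792 exp(0.01525 A)``. Negative for
    every age; only ``a(A)^2`` is consumed downstream.
    """
    age = np.asarray(age, dtype=float)
    scale = constants.scale_coef_1 * np.exp(constants.scale_rate_1 * age) + (
        constants.scale_coef_2 * np.exp(constants.scale_rate_2 * age)
    )
    return scale if scale.ndim else float(scale)


def _ganglion_falloff(age, eccentricity, constants: DensityModelConstants):
    """Normalised ganglion density profile N_g(A, e) / N_g(A, 0)."""
    a = np.asarray(eccentricity_scale(age, constants))
    e = np.asarray(eccentricity, dtype=float)
    return constants.primary_weight / (1.0 + (e / a) ** 2) + (
        constants.secondary_weight / (1.0 + (e / constants.secondary_ecc_scale) ** 2)
    )


def ganglion_density(age, eccentricity, constants: DensityModelConstants = DENSITY_DEFAULTS):
    """Ganglion-cell density (relative units) at age ``A``, eccentricity ``e``.

    ``N_g(A, e) = 3 N_c(A, 0) * [0.85 / (1 + (e/a(A))^2)
    + 0.15 / (1 + (e/7.3)^2)]``. Equals ``3 N_c(A, 0)`` at the fovea and
    decreases strictly with eccentricity.
    """
    eccentricity = np.asarray(eccentricity, dtype=float)
    if np.any(eccentricity < 0):
        raise ValueError("eccentricity must be >= 0")
    foveal = constants.ganglion_cone_ratio * np.asarray(cone_density(age, 0.0, constants))
    density = foveal * _ganglion_falloff(age, eccentricity, constants)
    return density if density.ndim else float(density)


def _barten_bracket(eccentricity, constants: DensityModelConstants = DENSITY_DEFAULTS):
    """Age-independent receptive-field bracket; equals exactly 1 at e = 0."""
    e = np.asarray(eccentricity, dtype=float)
    w1, w2, w3 = constants.bracket_weights
    s1, s2 = constants.bracket_scales
    return w1 / (1.0 + (e / s1) ** 2) + w2 / (1.0 + (e / s2) ** 2) + w3


def inhibition_cutoff(
    age,
    eccentricity,
    u0: float = NOISE_DEFAULTS.foveal_inhibition_cutoff,
    constants: DensityModelConstants = DENSITY_DEFAULTS,
    sqrt_ratio: bool = False,
):
    """Lateral-inhibition drop-off frequency ``u_inh`` (cpd).

    ``u_inh(A, e) = u0 * (N_g(A, e) / N_g(A, 0)) * bracket(e)**-0.5`` where
    the bracket is the age-independent receptive-field mixture
    ``0.85/(1+(e/4)^2) + 0.13/(1+(e/20)^2) + 0.02``. At the fovea both
    factors equal 1, so ``u_inh(A, 0) = u0`` at every age. When the density
    ratio is replaced by the bracket itself the expression reduces to the
    classical ``u0 * bracket**0.5``.

    ``sqrt_ratio=True`` selects the alternative reading with the density
    ratio to the power 0.5.
    """
    if not u0 > 0:
        raise ValueError("u0 must be > 0")
    ratio = _ganglion_falloff(age, np.asarray(eccentricity, dtype=float), constants)
    if sqrt_ratio:
        ratio = np.sqrt(ratio)
    cutoff = u0 * ratio * _barten_bracket(eccentricity, constants) ** -0.5
    cutoff = np.asarray(cutoff)
    return cutoff if cutoff.ndim else float(cutoff)


def lateral_mtf(u, u_inh):
    """Lateral-inhibition MTF: ``sqrt(1 - exp(-(u / u_inh)^2))``.

    High-pass: 0 at ``u = 0``, strictly increasing, tending to 1. ``u_inh``
    is the drop-off frequency in cpd.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("spatial frequency must be >= 0")
    if np.any(np.asarray(u_inh) <= 0):
        raise ValueError("u_inh must be > 0")
    result = np.sqrt(1.0 - np.exp(-((u / u_inh) ** 2)))
    return result if result.ndim else float(result)


def photon_noise(eta, p, illuminance):
    """Photon-noise spectral density ``Phi_opt = 1 / (eta p E)`` in s*deg^2.

    ``eta`` is the quantum efficiency (fraction of photons entering the eye
    that productively activate photoreceptors), ``p`` the photon conversion
    factor, ``E`` the retinal illuminance in trolands.
    """
    eta = np.asarray(eta, dtype=float)
    illuminance = np.asarray(illuminance, dtype=float)
    if np.any(eta <= 0) or np.any(np.asarray(p) <= 0) or np.any(illuminance <= 0):
        raise ValueError("eta, p and illuminance must all be > 0")
    result = 1.0 / (eta * p * illuminance)
    return result if result.ndim else float(result)


def neural_noise(
    age,
    eccentricity,
    phi0: float = NOISE_DEFAULTS.foveal_neural_noise,
    constants: DensityModelConstants = DENSITY_DEFAULTS,
):
    """Neural-noise spectral density ``Phi_neu(A, e)`` in s*deg^2.

    Independent of retinal illuminance; equal to ``phi0`` in the fovea at
    every age, and inflated off-fovea by the inverse normalised
    ganglion-cell density: ``Phi_neu = phi0 * N_g(A, 0) / N_g(A, e)``.
    """
    if not phi0 > 0:
        raise ValueError("phi0 must be > 0")
    eccentricity = np.asarray(eccentricity, dtype=float)
    if np.any(eccentricity < 0):
        raise ValueError("eccentricity must be >= 0")
    result = phi0 / _ganglion_falloff(age, eccentricity, constants)
    result = np.asarray(result)
    return result if result.ndim else float(result)
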