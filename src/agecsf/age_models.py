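"""Fitted analytical age curves for the four free CSF parameters.

The four parameters that cannot be derived from physiological data —
optical baseline blur ``sigma0``, quantum efficiency ``eta``, optical
cut-off frequency ``u_opt`` and the signal-to-noise ratio ``k`` — were
estimated per age group by grid search against published photopic CSF
measurements and then summarised as smooth (``sigma0``, ``eta``) or
piecewise-constant (``k``, ``u_opt``) functions of age. A separate
saturating curve ``k*(w)`` captures the temporal-frequency dependence of
``k`` under the assumption that age and temporal frequency act
independently: ``k(A, w) = k(A) * k*(w)``.

The age domain starts at 17 years: below that the fractional powers inside
the fitted curves are undefined, and no data constrained them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig
from .optics import MIN_AGE

__all__ = [
    "ParameterSet",
    "sigma0_of_age",
    "eta_of_age",
    "k_of_age",
    "uopt_of_age",
    "kstar_of_w",
    "params_for_age",
    "barten_default_params",
    "AGE_STEP",
]

#: Age (years) of the step in the piecewise-constant k and u_opt models.
#: Ages <= AGE_STEP take the younger-branch values.
AGE_STEP = 50.0


@dataclass(frozen=True)
class ParameterSet:
    """The four fitted CSF parameters plus the fixed model constants.

    Attributes
    ----------
    k : float
        Signal-to-noise ratio linking internal noise modulation to the
        detection threshold (dimensionless, >= 0.5).
    u_opt : float
        Optical cut-off frequency, cpd.
    sigma0 : float
        Baseline optical standard deviation (dimensionless, arcmin scale).
    eta : float
        Quantum efficiency, fraction in (0, 1).
    cab : float
        Pupil-coupled aberration coefficient, per mm.
    p : float
        Photon conversion factor, photons s^-1 deg^-2 Td^-1.
    u0 : float
        Foveal lateral-inhibition cut-off, cpd.
    phi0 : float
        Foveal neural-noise spectral density, s*deg^2.
    te : float
        Eye integration time, s.
    """

    k: float
    u_opt: float
    sigma0: float
    eta: float
    cab: float = 0.08
    p: float = 1.285e6
    u0: float = 7.0
    phi0: float = 3e-8
    te: float = 0.1

    def __post_init__(self) -> None:
        if not self.k >= 0.5:
            raise ValueError(f"k must be >= 0.5, got {self.k}")
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")
        for name in ("u_opt", "sigma0", "p", "u0", "phi0", "te"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cab < 0:
            raise ValueError("cab must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls(**json.loads(text))

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < MIN_AGE):
        raise ValueError(
            f"age must be >= {MIN_AGE} years: the fitted age curves are "
            "undefined below the model domain"
        )
    return age


def sigma0_of_age(age):
    """Baseline optical standard deviation ``sigma0(A)``.

    ``0.42 + 0.26 * (1 - exp(-((A - 17) / 27.1837)**1.547))``: increases
    strictly from 0.42 at age 17 towards an asymptote of 0.68, reflecting
    the growing intraocular scatter of the ageing lens.
    """
    age = _check_age(age)
    value = 0.42 + 0.26 * (1.0 - np.exp(-(((age - MIN_AGE) / 27.1837) ** 1.547)))
    return value if value.ndim else float(value)


def eta_of_age(age):
    """Quantum efficiency ``eta(A)``.

    ``0.019 + 0.023 * (1 - exp(-((A - 17) / 13.0645)**-1.753))``: decreases
    strictly from 0.042 (the exact right limit at age 17, where the inner
    negative power diverges) towards 0.019, reflecting fewer productive
    photon absorptions in the older retina.
    """
    age = _check_age(age)
    at_limit = age == MIN_AGE
    with np.errstate(divide="ignore"):
        inner = ((age - MIN_AGE) / 13.0645) ** -1.753
    value = 0.019 + 0.023 * (1.0 - np.exp(-inner))
    value = np.where(at_limit, 0.042, value)
    return value if value.ndim else float(value)


def k_of_age(age):
    """Signal-to-noise ratio ``k(A)``: 3 for ages <= 50, 4 above."""
    age = _check_age(age)
    value = np.where(age <= AGE_STEP, 3.0, 4.0)
    return value if value.ndim else float(value)


def uopt_of_age(age):
    """Optical cut-off frequency ``u_opt(A)`` in cpd: 35 for ages <= 50, 30 above."""
    age = _check_age(age)
    value = np.where(age <= AGE_STEP, 35.0, 30.0)
    return value if value.ndim else float(value)


def kstar_of_w(w):
    """Temporal-frequency factor ``k*(w)`` of the signal-to-noise ratio.

    ``1.0835 + 3.1045 * (1 - exp(-((w - 0.5) / 8.4785)**2.497))`` for
    ``w >= 0.5`` Hz, clamped to its lower value 1.0835 below 0.5 Hz
    (static or slowly drifting stimuli). Saturates at 4.188 for fast
    flicker, expressing the loss of sensitivity at high temporal
    frequencies.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("temporal frequency must be >= 0")
    shifted = np.clip(w - 0.5, 0.0, None)
    value = 1.0835 + 3.1045 * (1.0 - np.exp(-((shifted / 8.4785) ** 2.497)))
    return value if value.ndim else float(value)


def params_for_age(age: float, config: ModelConfig = DEFAULT_CONFIG) -> ParameterSet:
    """Assemble the full :class:`ParameterSet` for an observer age.

    The four fitted parameters come from the analytical age curves; the
    fixed constants come from ``config``.
    """
    return ParameterSet(
        k=float(k_of_age(age)),
        u_opt=float(uopt_of_age(age)),
        sigma0=float(sigma0_of_age(age)),
        eta=float(eta_of_age(age)),
        cab=config.cab,
        p=config.photon_conversion,
        u0=config.foveal_inhibition_cutoff,
        phi0=config.foveal_neural_noise,
        te=config.integration_time,
    )


def barten_default_params(
    u_opt: float = 60.0, config: ModelConfig = DEFAULT_CONFIG
) -> ParameterSet:
    """Age-independent baseline parameters (classical photopic defaults).

    ``sigma0 = 0.5``, ``eta = 0.03``, ``k = 3`` with the shared fixed
    constants. The split (sigma_opt, u_opt) parameterisation needs a
    cut-off frequency: the default 60 cpd pairs with ``sigma0 = 0.5`` so
    that the Gaussian optical MTF matches the classical 0.5-arcmin blur at
    the ~60 cpd foveal resolution limit.
    """
    return ParameterSet(
        k=3.0,
        u_opt=u_opt,
        sigma0=0.5,
        eta=0.03,
        cab=config.cab,
        p=config.photon_conversion,
        u0=config.foveal_inhibition_cutoff,
        phi0=config.foveal_neural_noise,
        te=config.integration_time,
    )
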