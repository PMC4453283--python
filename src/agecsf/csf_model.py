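"""Assembly of the contrast sensitivity function.

Three entry points:

* :func:`csf_barten` — the age-independent physiological CSF: Gaussian
  optical MTF, photon noise, neural noise filtered by the
  lateral-inhibition MTF, and the signal-to-noise criterion ``k``;
* :func:`csf_spatial` — the age-dependent generalisation, in which the
  pupil, retinal illuminance, optical MTF, noise terms and the fitted
  parameters are all resolved from the observer's age;
* :func:`csf_spatiotemporal` — the extension to drifting/flickering
  stimuli through pluggable temporal filters ``H1``/``H2`` and the
  separable criterion ``k(A, w) = k(A) * k*(w)``.

The core expression is::

    CSF(u) = M_opt(u) / k * sqrt( X*Y*T / (2 * (Phi_opt + Phi_neu / M_lat(u)^2)) )

with ``T = min(Te, To)``. Sensitivity is 0 at ``u = 0`` (the
lateral-inhibition MTF vanishes there, so the neural noise diverges) and
falls to 0 at high frequency under the optical MTF: a band-pass curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .age_models import ParameterSet, barten_default_params, kstar_of_w, params_for_age
from .config import DEFAULT_CONFIG, ModelConfig
from .optics import (
    ViewingConditions,
    optical_mtf,
    optical_sd,
    pupil_diameter,
    retinal_illuminance,
    stanley_davies_diameter,
)
from .retina import (
    _barten_bracket,
    inhibition_cutoff,
    lateral_mtf,
    neural_noise,
    photon_noise,
)

__all__ = [
    "CSFQuery",
    "TemporalFilters",
    "csf_barten",
    "csf_spatial",
    "csf_spatiotemporal",
]


def _identity_filter(w):
    return 1.0


@dataclass(frozen=True)
class TemporalFilters:
    """Temporal filters of the spatiotemporal CSF.

    ``h1`` models the temporal low-pass of the photoreceptor signal, ``h2``
    the temporal component of lateral inhibition. Both map a temporal
    frequency (Hz) to a fraction in (0, 1] with ``H(0) = 1`` by convention.
    Defaults are identity (no temporal attenuation beyond ``k*(w)``); users
    supply their own callables to model a specific display or observer.
    """

    h1: Callable[[float], float] = _identity_filter
    h2: Callable[[float], float] = _identity_filter


def _csf_core(u, mopt, mlat2, phi_opt, phi_neu, k, area_time, gain):
    """Shared closed form; mlat2 is the squared lateral-inhibition MTF."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore"):
        denom = phi_opt + phi_neu / mlat2
    sensitivity = gain * mopt / k * np.sqrt(area_time / (2.0 * denom))
    sensitivity = np.where(mlat2 > 0.0, sensitivity, 0.0)
    return sensitivity if sensitivity.ndim else float(sensitivity)


def csf_barten(
    u,
    conditions: ViewingConditions,
    params: ParameterSet | None = None,
    *,
    pupil: float | None = None,
    u_inh: float | None = None,
    phi_neu: float | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Age-independent physiological CSF at spatial frequencies ``u`` (cpd).

    Parameters
    ----------
    u : float or array
        Spatial frequency in cpd, >= 0.
    conditions : ViewingConditions
        Luminance, field geometry, eyes, presentation time, eccentricity.
    params : ParameterSet, optional
        Defaults to the classical photopic baseline
        (:func:`agecsf.age_models.barten_default_params`).
    pupil, u_inh, phi_neu : float, optional
        Overrides for the pupil diameter (mm), inhibition cut-off (cpd)
        and neural noise (s*deg^2). By default the pupil follows the
        luminance-only unified formula, and the neural stage uses the
        age-independent receptive-field bracket at the conditions'
        eccentricity (which reduces to ``u0`` and ``phi0`` at the fovea).
        :func:`csf_spatial` passes age-resolved values through these hooks.

    Returns
    -------
    float or ndarray
        Contrast sensitivity (dimensionless), 0 at ``u = 0``.
    """
    if params is None:
        params = barten_default_params(config=config)
    if pupil is None:
        pupil = stanley_davies_diameter(
            conditions.luminance, conditions.stimulus_area, conditions.eyes
        )
    e = conditions.eccentricity
    if u_inh is None:
        u_inh = params.u0 * float(np.sqrt(_barten_bracket(e)))
    if phi_neu is None:
        phi_neu = params.phi0 / float(_barten_bracket(e))
    illuminance = retinal_illuminance(pupil, conditions.luminance)
    phi_opt = photon_noise(params.eta, params.p, illuminance)
    sigma_opt = optical_sd(params.sigma0, pupil, params.cab)
    mopt = optical_mtf(u, sigma_opt, params.u_opt)
    mlat2 = np.asarray(lateral_mtf(u, u_inh), dtype=float) ** 2
    area_time = (
        conditions.field_x
        * conditions.field_y
        * conditions.effective_time(params.te)
    )
    return _csf_core(u, mopt, mlat2, phi_opt, phi_neu, params.k, area_time, config.gain)


def csf_spatial(
    age: float,
    u,
    conditions: ViewingConditions,
    params: ParameterSet | None = None,
    *,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Age-dependent spatial CSF.

    Identical in structure to :func:`csf_barten`, but every stage is
    resolved from the observer's age: the pupil follows the senile-miosis
    model (hence so does the retinal illuminance and the aberration term of
    the optical MTF), the neural cut-off and neural noise follow the
    age-dependent ganglion-density model at the conditions' eccentricity,
    and the four fitted parameters default to their analytical age curves.

    Pass an explicit ``params`` to evaluate candidate parameter values
    (e.g. during fitting) while keeping the age-resolved optics chain.
    """
    if params is None:
        params = params_for_age(age, config)
    d = pupil_diameter(age, conditions.luminance, conditions.stimulus_area, conditions.eyes)
    e = conditions.eccentricity
    u_inh = inhibition_cutoff(age, e, u0=params.u0, sqrt_ratio=config.inhibition_sqrt_ratio)
    phi = neural_noise(age, e, phi0=params.phi0)
    return csf_barten(
        u,
        conditions,
        params,
        pupil=d,
        u_inh=float(u_inh),
        phi_neu=float(phi),
        config=config,
    )


def csf_spatiotemporal(
    age: float,
    u,
    w: float,
    conditions: ViewingConditions,
    filters: TemporalFilters | None = None,
    params: ParameterSet | None = None,
    *,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Age-dependent spatiotemporal CSF at temporal frequency ``w`` (Hz).

    The neural-noise denominator becomes
    ``(H1(w) * (1 - H2(w) * (1 - M_lat(u))))**2`` (unsquared if
    ``config.temporal_denominator_squared`` is False) and the criterion is
    ``k(A) * k*(w)``. With identity filters and ``w = 0.5`` Hz this reduces
    to ``csf_spatial / k*(0.5)``.
    """
    if filters is None:
        filters = TemporalFilters()
    if params is None:
        params = params_for_age(age, config)
    d = pupil_diameter(age, conditions.luminance, conditions.stimulus_area, conditions.eyes)
    e = conditions.eccentricity
    u_inh = float(
        inhibition_cutoff(age, e, u0=params.u0, sqrt_ratio=config.inhibition_sqrt_ratio)
    )
    phi_neu = float(neural_noise(age, e, phi0=params.phi0))
    illuminance = retinal_illuminance(d, conditions.luminance)
    phi_opt = photon_noise(params.eta, params.p, illuminance)
    sigma_opt = optical_sd(params.sigma0, d, params.cab)
    mopt = optical_mtf(u, sigma_opt, params.u_opt)
    mlat = np.asarray(lateral_mtf(u, u_inh), dtype=float)
    h1 = float(filters.h1(w))
    h2 = float(filters.h2(w))
    if not (0.0 < h1 <= 1.0 and 0.0 < h2 <= 1.0):
        raise ValueError("temporal filters must return fractions in (0, 1]")
    temporal_term = h1 * (1.0 - h2 * (1.0 - mlat))
    if config.temporal_denominator_squared:
        temporal_term = temporal_term**2
    k_eff = params.k * float(kstar_of_w(w))
    area_time = (
        conditions.field_x
        * conditions.field_y
        * conditions.effective_time(params.te)
    )
    with np.errstate(divide="ignore"):
        denom = phi_opt + phi_neu / temporal_term
    sensitivity = config.gain * mopt / k_eff * np.sqrt(area_time / (2.0 * denom))
    sensitivity = np.where(temporal_term > 0.0, sensitivity, 0.0)
    return sensitivity if sensitivity.ndim else float(sensitivity)


@dataclass
class CSFQuery:
    """A bundled CSF evaluation request.

    Evaluates the age-dependent CSF (spatial, or spatiotemporal when a
    ``temporal_frequency`` is given) at a vector of spatial frequencies and
    returns a tidy table with ``frequency_cpd``, ``sensitivity`` and
    ``log10_sensitivity`` columns.
    """

    age: float
    frequencies: np.ndarray
    conditions: ViewingConditions
    temporal_frequency: float | None = None
    params: ParameterSet | None = None
    filters: TemporalFilters | None = None
    config: ModelConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be >= 0")

    def evaluate(self) -> pd.DataFrame:
        if self.temporal_frequency is None:
            sens = csf_spatial(
                self.age, self.frequencies, self.conditions,
                params=self.params, config=self.config,
            )
        else:
            sens = csf_spatiotemporal(
                self.age, self.frequencies, self.temporal_frequency,
                self.conditions, filters=self.filters, params=self.params,
                config=self.config,
            )
        sens = np.asarray(sens, dtype=float)
        with np.errstate(divide="ignore"):
            log10 = np.log10(sens, out=np.full_like(sens, -np.inf), where=sens > 0)
        return pd.DataFrame(
            {
                "frequency_cpd": self.frequencies,
                "sensitivity": sens,
                "log10_sensitivity": log10,
            }
        )
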