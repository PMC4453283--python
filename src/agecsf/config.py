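"""Model configuration: fixed physiological constants and structural switches.

All constants of the CSF model that are *not* fitted per age group live here,
with their defaults. Two kinds of entries:

* physical/physiological constants (chromatic-aberration coefficient,
  photon-conversion factor, foveal inhibition cut-off, foveal neural noise,
  eye integration time), each overridable for sensitivity analyses;
* structural switches that select between alternative readings of
  ambiguously printed formulas (see ``docs/methods.md``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml

__all__ = ["ModelConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class ModelConfig:
    """Fixed constants and structural choices of the CSF model.

    Attributes
    ----------
    cab : float
        Chromatic-aberration coefficient ``Cab`` coupling the optical
        standard deviation to the pupil diameter, per mm. Barten's value
        0.08 is used at every age.
    photon_conversion : float
        Photon conversion factor ``p`` in photons s^-1 deg^-2 Td^-1.
        Relates retinal illuminance to the photon flux available to the
        photoreceptors. Default 1.285e6 (photopic, Barten's scale).
    foveal_inhibition_cutoff : float
        Lateral-inhibition drop-off frequency ``u_inh(0)`` in the fovea,
        cpd. Age-independent; default 7 cpd.
    foveal_neural_noise : float
        Neural noise spectral density ``Phi_neu(A, 0)`` in the fovea,
        s*deg^2. Age-independent; default 3e-8.
    integration_time : float
        Eye integration time ``Te`` in seconds (photopic). Default 0.1 s.
    gain : float
        Global multiplicative gain on the predicted sensitivity. Default 1
        (the algebraically derived prefactor); 1/sqrt(2) reaches the
        alternative printed convention.
    inhibition_sqrt_ratio : bool
        If True, the ganglion-density ratio entering the peripheral
        inhibition cut-off is taken to the power 0.5 instead of 1
        (alternative reading of the cut-off formula). Default False.
    temporal_denominator_squared : bool
        If True (default) the temporal neural-noise denominator
        ``H1(w) * (1 - H2(w) * (1 - M_lat(u)))`` is squared, by analogy
        with the squared spatial lateral-inhibition term. If False, the
        literal unsquared rendering is used.
    """

    cab: float = 0.08
    photon_conversion: float = 1.285e6
    foveal_inhibition_cutoff: float = 7.0
    foveal_neural_noise: float = 3e-8
    integration_time: float = 0.1
    gain: float = 1.0
    inhibition_sqrt_ratio: bool = False
    temporal_denominator_squared: bool = True

    def __post_init__(self) -> None:
        for name in (
            "cab",
            "photon_conversion",
            "foveal_inhibition_cutoff",
            "foveal_neural_noise",
            "integration_time",
            "gain",
        ):
            value = getattr(self, name)
            if not value > 0 and name != "cab":
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.cab < 0:
            raise ValueError(f"cab must be non-negative, got {self.cab}")

    # -- serialisation -----------------------------------------------------

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


#: Shared default configuration used throughout the package.
DEFAULT_CONFIG = ModelConfig()
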