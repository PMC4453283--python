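"""CSF table I/O and the synthetic-data generator.

CSV dialect is pinned: comma separator, dot decimal, UTF-8, header
required. Columns: ``age,frequency_cpd,sensitivity,luminance_cd_m2,
field_deg,eyes[,temporal_hz]``.

The synthetic generator emulates published photopic CSF tables: a handful
of spatial frequencies between 0.5 and 22 cpd, adaptation luminances of
12.5-300 cd/m^2, adult age groups, and multiplicative lognormal measurement
noise (psychophysical thresholds are ratio-scale, so noise is naturally
multiplicative and sensitivities stay positive).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_models import ParameterSet, params_for_age
from .config import DEFAULT_CONFIG, ModelConfig
from .csf_model import csf_spatial
from .optics import ViewingConditions

__all__ = [
    "CSFMeasurement",
    "CSFDataset",
    "DEFAULT_FREQUENCIES",
    "read_csf_csv",
    "write_csf_csv",
    "synthesize_dataset",
]

#: Default spatial-frequency ladder (cpd), mirroring the spans of the
#: published photopic CSF experiments the model was fitted to.
DEFAULT_FREQUENCIES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 22.0)

_REQUIRED_COLUMNS = (
    "age",
    "frequency_cpd",
    "sensitivity",
    "luminance_cd_m2",
    "field_deg",
    "eyes",
)


@dataclass(frozen=True)
class CSFMeasurement:
    """One observed contrast-sensitivity point with its conditions."""

    age_label: float
    frequency: float
    sensitivity: float
    luminance: float
    field_deg: float
    eyes: int = 2
    temporal_frequency: float = 0.5

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not self.sensitivity > 0:
            raise ValueError(f"sensitivity must be > 0, got {self.sensitivity}")
        if not self.luminance > 0:
            raise ValueError("luminance must be > 0")
        if not self.field_deg > 0:
            raise ValueError("field_deg must be > 0")
        if self.eyes not in (1, 2):
            raise ValueError(f"eyes must be 1 or 2, got {self.eyes}")


@dataclass
class CSFDataset:
    """A collection of CSF measurements plus free-form metadata."""

    measurements: list[CSFMeasurement]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.measurements])

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([m.sensitivity for m in self.measurements])

    @property
    def ages(self) -> np.ndarray:
        return np.unique([m.age_label for m in self.measurements])

    def group_by_age(self) -> dict[float, "CSFDataset"]:
        groups: dict[float, list[CSFMeasurement]] = {}
        for m in self.measurements:
            groups.setdefault(m.age_label, []).append(m)
        return {
            age: CSFDataset(ms, dict(self.metadata)) for age, ms in sorted(groups.items())
        }

    def conditions(self) -> ViewingConditions:
        """Derive homogeneous viewing conditions from the measurements."""
        if not self.measurements:
            raise ValueError("empty dataset has no conditions")
        lum = {m.luminance for m in self.measurements}
        fld = {m.field_deg for m in self.measurements}
        eyes = {m.eyes for m in self.measurements}
        if len(lum) > 1 or len(fld) > 1 or len(eyes) > 1:
            raise ValueError(
                "heterogeneous viewing conditions in dataset: "
                f"luminance={sorted(lum)}, field={sorted(fld)}, eyes={sorted(eyes)}"
            )
        return ViewingConditions(
            luminance=lum.pop(), field_x=fld.pop(), eyes=eyes.pop()
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": [m.age_label for m in self.measurements],
                "frequency_cpd": [m.frequency for m in self.measurements],
                "sensitivity": [m.sensitivity for m in self.measurements],
                "luminance_cd_m2": [m.luminance for m in self.measurements],
                "field_deg": [m.field_deg for m in self.measurements],
                "eyes": [m.eyes for m in self.measurements],
                "temporal_hz": [m.temporal_frequency for m in self.measurements],
            }
        )


def read_csf_csv(path) -> CSFDataset:
    """Read a CSF table from CSV, validating every row.

    Malformed rows (non-numeric cells, non-positive sensitivity or
    frequency, bad eye counts) are reported together with their 1-based
    file line numbers in a single :class:`ValueError`.
    """
    frame = pd.read_csv(
        path, sep=",", decimal=".", encoding="utf-8", float_precision="round_trip"
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_temporal = "temporal_hz" in frame.columns
    measurements: list[CSFMeasurement] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            measurements.append(
                CSFMeasurement(
                    age_label=float(row["age"]),
                    frequency=float(row["frequency_cpd"]),
                    sensitivity=float(row["sensitivity"]),
                    luminance=float(row["luminance_cd_m2"]),
                    field_deg=float(row["field_deg"]),
                    eyes=int(row["eyes"]),
                    temporal_frequency=(
                        float(row["temporal_hz"]) if has_temporal else 0.5
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("invalid rows in CSF table:\n" + "\n".join(errors))
    return CSFDataset(measurements, metadata={"source": str(path)})


def write_csf_csv(dataset: CSFDataset, path) -> None:
    """Write a CSF table to CSV (comma, dot decimal, UTF-8, with header)."""
    dataset.to_dataframe().to_csv(path, sep=",", index=False, encoding="utf-8")


def synthesize_dataset(
    age: float,
    conditions: ViewingConditions,
    frequencies=DEFAULT_FREQUENCIES,
    noise_cv: float = 0.05,
    seed: int | None = None,
    params: ParameterSet | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> CSFDataset:
    """Generate a synthetic CSF measurement table for one age group.

    Sensitivities are the age-dependent model predictions (with the
    age-resolved optics chain; ``params`` overrides the fitted age curves,
    e.g. to plant an on-grid truth) multiplied by lognormal noise with mean
    exactly 1 and coefficient of variation ``noise_cv``. Deterministic
    under a fixed ``seed``.

    Parameters
    ----------
    age : float
        Observer age group mean, years (>= 17).
    conditions : ViewingConditions
        Shared photometric conditions of the simulated experiment.
    frequencies : sequence of float
        Spatial frequencies in cpd; defaults to the 0.5-22 cpd ladder.
    noise_cv : float
        Coefficient of variation of the multiplicative measurement noise;
        0 yields exact model predictions.
    seed : int, optional
        Seed for the random generator; required for reproducibility.
    params : ParameterSet, optional
        Explicit parameters (defaults to the analytical age curves).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be > 0")
    predicted = np.asarray(
        csf_spatial(age, frequencies, conditions, params=params, config=config)
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=frequencies.size)
        observed = predicted * factors
    else:
        observed = predicted
    measurements = [
        CSFMeasurement(
            age_label=float(age),
            frequency=float(f),
            sensitivity=float(s),
            luminance=conditions.luminance,
            field_deg=conditions.field_x,
            eyes=conditions.eyes,
        )
        for f, s in zip(frequencies, observed)
    ]
    return CSFDataset(
        measurements,
        metadata={
            "source": "synthetic",
            "age": float(age),
            "noise_cv": float(noise_cv),
            "seed": seed,
        },
    )
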