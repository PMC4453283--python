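"""Grid-search parameter estimation for the CSF model.

The four free parameters (quantum efficiency ``eta``, optical baseline SD
``sigma0``, optical cut-off ``u_opt``, signal-to-noise ratio ``k``) are
estimated by minimising the root-mean-square error (RMSE, linear
sensitivity scale) between model and data over a finite parameter grid
whose ranges and samplings follow the published fitting protocol:

* ``eta``    in [0.005, 0.150], step 0.0001
* ``sigma0`` in [0.01, 2.00],  step 0.01
* ``u_opt``  in [1, 100],      step 2.5 cpd
* ``k``      in [0.5, 20.0],   step 0.25

The full grid has ~9e8 cells, so the default strategy is a staged
coarse-to-fine search (coarse subsampled pass, then full-resolution
refinement windows around the best coarse candidates). An exact exhaustive
scan of the full grid is available behind an explicit flag; it relies on an
algebraic expansion of the sum of squared errors, contracted once over the
frequency axis per ``(eta, sigma0, u_opt)`` cell and scanned analytically
over ``k``, so every grid cell is evaluated without materialising the 4-D
error array.

Ties in RMSE are broken towards the lexicographically smallest
``(eta, sigma0, u_opt, k)`` for determinism.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .age_models import ParameterSet, barten_default_params, params_for_age
from .config import DEFAULT_CONFIG, ModelConfig
from .csf_model import csf_barten, csf_spatial
from .data_io import CSFDataset
from .optics import ViewingConditions, pupil_diameter, retinal_illuminance
from .retina import inhibition_cutoff, lateral_mtf, neural_noise

__all__ = [
    "GridSpec",
    "FitResult",
    "ModelComparison",
    "rmse",
    "grid_fit",
    "compare_models",
    "aging_predictor",
    "baseline_predictor",
]

#: Above this many cells, strategy="exhaustive" requires allow_full_exhaustive.
_EXHAUSTIVE_GATE = 100_000_000


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("grid step must be > 0")
    if hi <= lo:
        raise ValueError("grid range must be non-degenerate")
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True, eq=False)
class GridSpec:
    """The four parameter axes of the search grid (strictly increasing)."""

    eta: np.ndarray
    sigma0: np.ndarray
    u_opt: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eta", "sigma0", "u_opt", "k"):
            axis = np.asarray(getattr(self, name), dtype=float)
            if axis.ndim != 1 or axis.size == 0:
                raise ValueError(f"{name} axis must be a non-empty 1-D array")
            if axis.size > 1 and not np.all(np.diff(axis) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            object.__setattr__(self, name, axis)

    @classmethod
    def default(cls) -> "GridSpec":
        """The published protocol grid (ranges and samplings above)."""
        return cls(
            eta=_axis(0.005, 0.150, 0.0001),
            sigma0=_axis(0.01, 2.00, 0.01),
            u_opt=_axis(1.0, 100.0, 2.5),
            k=_axis(0.5, 20.0, 0.25),
        )

    @classmethod
    def from_ranges(cls, eta, sigma0, u_opt, k) -> "GridSpec":
        """Build from (lo, hi, step) triples per axis."""
        return cls(eta=_axis(*eta), sigma0=_axis(*sigma0), u_opt=_axis(*u_opt), k=_axis(*k))

    def subsample(self, factor: int) -> "GridSpec":
        """Every ``factor``-th point per axis (first point always kept)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return GridSpec(
            eta=self.eta[::factor],
            sigma0=self.sigma0[::factor],
            u_opt=self.u_opt[::factor],
            k=self.k[::factor],
        )

    @property
    def n_cells(self) -> int:
        return self.eta.size * self.sigma0.size * self.u_opt.size * self.k.size

    def summary(self) -> dict:
        return {
            name: {
                "min": float(axis[0]),
                "max": float(axis[-1]),
                "n": int(axis.size),
            }
            for name, axis in (
                ("eta", self.eta),
                ("sigma0", self.sigma0),
                ("u_opt", self.u_opt),
                ("k", self.k),
            )
        }


@dataclass
class FitResult:
    """Outcome of a grid fit."""

    best: ParameterSet
    rmse: float
    residuals: np.ndarray  # predicted - observed, per measurement
    grid: GridSpec
    n_evaluated: int
    strategy: str
    age: float

    def to_dict(self) -> dict:
        return {
            "best": self.best.as_dict(),
            "rmse": float(self.rmse),
            "residuals": [float(r) for r in self.residuals],
            "grid": self.grid.summary(),
            "n_evaluated": int(self.n_evaluated),
            "strategy": self.strategy,
            "age": float(self.age),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def rmse(predicted, observed) -> float:
    """Root-mean-square error on the linear sensitivity scale."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same shape")
    if predicted.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


# ---------------------------------------------------------------------------
# internal machinery


@dataclass(frozen=True)
class _FitContext:
    """Data and age-resolved quantities shared by all grid evaluations."""

    u: np.ndarray
    y: np.ndarray
    pupil: float
    illuminance: float
    u_inh: float
    phi_neu: float
    area_time: float
    p: float
    cab: float
    gain: float


def _contractions(ctx: _FitContext, eta: np.ndarray, sigma0: np.ndarray, u_opt: np.ndarray):
    """Contract the frequency axis.

    For model(u) = P(u; sigma0, u_opt) * N(u; eta) / k the SSE at a cell is
    A/k^2 - 2B/k + C with A = sum(P^2 N^2), B = sum(P N y), C = sum(y^2);
    A and B are returned with axes ordered (eta, sigma0, u_opt).
    """
    mlat2 = 1.0 - np.exp(-((ctx.u / ctx.u_inh) ** 2))
    phi_opt = 1.0 / (eta * ctx.p * ctx.illuminance)           # (e,)
    denom = phi_opt[:, None] + ctx.phi_neu / mlat2[None, :]   # (e, m)
    noise = ctx.gain * np.sqrt(ctx.area_time / (2.0 * denom))  # (e, m)
    sig2 = sigma0**2 + (ctx.cab * ctx.pupil) ** 2             # (s,)
    expo = (
        -2.0
        * math.pi**2
        * sig2[:, None, None]
        * (ctx.u[None, None, :] / u_opt[None, :, None]) ** 2
    )
    optic = np.exp(expo)                                      # (s, o, m)
    a = np.einsum("som,em->eso", optic * optic, noise * noise)
    b = np.einsum("som,em->eso", optic, noise * ctx.y)
    c = float(ctx.y @ ctx.y)
    return a, b, c


def _block_argmin(ctx: _FitContext, grid: GridSpec):
    """Exact argmin over a (small-to-large) grid block, k scanned in a loop.

    Returns ((ie, is_, io, ik), sse, n_eval) with indices local to ``grid``.
    Lexicographic tie-breaking on (eta, sigma0, u_opt, k).
    """
    a, b, c = _contractions(ctx, grid.eta, grid.sigma0, grid.u_opt)
    candidates = []
    for ik, k in enumerate(grid.k):
        sse = a / (k * k) - (2.0 / k) * b + c
        flat = int(np.argmin(sse))  # C-order: lexicographic (eta, sigma0, u_opt)
        idx = np.unravel_index(flat, sse.shape)
        candidates.append((float(sse[idx]), idx[0], idx[1], idx[2], ik))
    best = min(candidates)  # (sse, ie, is, io, ik) lexicographic
    n_eval = grid.n_cells
    return (best[1], best[2], best[3], best[4]), best[0], n_eval


def _eta_profile(ctx: _FitContext, grid: GridSpec) -> np.ndarray:
    """Per-eta profile SSE: min over (sigma0, u_opt, k) for each eta value."""
    a, b, c = _contractions(ctx, grid.eta, grid.sigma0, grid.u_opt)
    profile = np.full(grid.eta.size, np.inf)
    for k in grid.k:
        sse = a / (k * k) - (2.0 / k) * b + c
        np.minimum(profile, sse.min(axis=(1, 2)), out=profile)
    return profile


def _staged_argmin(ctx: _FitContext, grid: GridSpec, coarse_factor: int, n_candidates: int):
    """Coarse-to-fine search staged over the eta axis only.

    The optical parameters (sigma0, u_opt) enter the model only through
    the ratio sigma_opt/u_opt, so their 2-D grid carries a near-degenerate
    ridge that defeats coarse-to-fine refinement staged over all four
    axes. Instead, only the long eta axis (1451 points on the default
    grid) is subsampled; (sigma0, u_opt, k) are always scanned
    exhaustively via the SSE contraction, which is cheap. The coarse pass
    profiles SSE over eta; full-resolution eta windows around the best
    ``n_candidates`` coarse points are then searched exactly.

    Returns full-grid indices, lexicographic tie-breaking as in
    :func:`_block_argmin`.
    """
    coarse_idx = np.arange(0, grid.eta.size, coarse_factor)
    coarse = GridSpec(
        eta=grid.eta[coarse_idx], sigma0=grid.sigma0, u_opt=grid.u_opt, k=grid.k
    )
    profile = _eta_profile(ctx, coarse)
    n_eval = coarse.n_cells
    order = np.argsort(profile, kind="stable")[: max(1, n_candidates)]
    # union of full-resolution eta windows around the best coarse points
    keep = np.zeros(grid.eta.size, dtype=bool)
    for pos in order:
        center = int(coarse_idx[pos])
        keep[max(0, center - coarse_factor): center + coarse_factor + 1] = True
    eta_idx = np.flatnonzero(keep)
    sub = GridSpec(
        eta=grid.eta[eta_idx], sigma0=grid.sigma0, u_opt=grid.u_opt, k=grid.k
    )
    (ie, is_, io, ik), sse, n = _block_argmin(ctx, sub)
    n_eval += n
    return (int(eta_idx[ie]), is_, io, ik), sse, n_eval


def _build_context(
    dataset: CSFDataset,
    conditions: ViewingConditions,
    age: float,
    config: ModelConfig,
) -> _FitContext:
    u = dataset.frequencies
    y = dataset.sensitivities
    if u.size == 0:
        raise ValueError("cannot fit an empty dataset")
    if np.any(u <= 0):
        raise ValueError("all frequencies must be > 0 for fitting")
    pupil = pupil_diameter(age, conditions.luminance, conditions.stimulus_area, conditions.eyes)
    illuminance = retinal_illuminance(pupil, conditions.luminance)
    e = conditions.eccentricity
    u_inh = float(
        inhibition_cutoff(
            age,
            e,
            u0=config.foveal_inhibition_cutoff,
            sqrt_ratio=config.inhibition_sqrt_ratio,
        )
    )
    phi_neu = float(neural_noise(age, e, phi0=config.foveal_neural_noise))
    area_time = (
        conditions.field_x
        * conditions.field_y
        * conditions.effective_time(config.integration_time)
    )
    return _FitContext(
        u=u,
        y=y,
        pupil=pupil,
        illuminance=illuminance,
        u_inh=u_inh,
        phi_neu=phi_neu,
        area_time=area_time,
        p=config.photon_conversion,
        cab=config.cab,
        gain=config.gain,
    )


def grid_fit(
    dataset: CSFDataset,
    grid: GridSpec | None = None,
    conditions: ViewingConditions | None = None,
    age: float | None = None,
    strategy: str = "staged",
    config: ModelConfig = DEFAULT_CONFIG,
    allow_full_exhaustive: bool = False,
    coarse_factor: int = 10,
    n_candidates: int = 10,
) -> FitResult:
    """Fit (eta, sigma0, u_opt, k) to one age group's CSF data.

    Parameters
    ----------
    dataset : CSFDataset
        Measurements of a single age group under homogeneous conditions.
    grid : GridSpec, optional
        Defaults to the published protocol grid.
    conditions : ViewingConditions, optional
        Derived from the dataset when omitted.
    age : float, optional
        Observer age used to resolve the pupil, retinal illuminance and
        neural stage; defaults to the dataset's (unique) age label.
    strategy : {"staged", "exhaustive"}
        Staged coarse-to-fine search (default), or an exact scan of every
        grid cell. The exhaustive scan of grids larger than 1e8 cells must
        be enabled explicitly with ``allow_full_exhaustive=True``.
    coarse_factor, n_candidates : int
        Staged-search tuning: subsampling factor of the coarse pass, and
        how many coarse candidates are refined at full resolution.

    Returns
    -------
    FitResult
        Best on-grid parameters (RMSE-minimal, ties broken towards the
        lexicographically smallest cell), the achieved RMSE recomputed
        through the public model, per-point residuals and search metadata.
    """
    if grid is None:
        grid = GridSpec.default()
    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    ages = dataset.ages
    if age is None:
        if ages.size != 1:
            raise ValueError(
                f"dataset mixes age groups {list(ages)}; fit one group at a time "
                "or pass an explicit age"
            )
        age = float(ages[0])
    if conditions is None:
        conditions = dataset.conditions()
    ctx = _build_context(dataset, conditions, age, config)

    if strategy == "exhaustive":
        if grid.n_cells > _EXHAUSTIVE_GATE and not allow_full_exhaustive:
            raise ValueError(
                f"exhaustive search over {grid.n_cells} cells is gated; pass "
                "allow_full_exhaustive=True or use strategy='staged'"
            )
        (ie, is_, io, ik), _, n_eval = _block_argmin(ctx, grid)
    elif strategy == "staged":
        (ie, is_, io, ik), _, n_eval = _staged_argmin(ctx, grid, coarse_factor, n_candidates)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    best = ParameterSet(
        k=float(grid.k[ik]),
        u_opt=float(grid.u_opt[io]),
        sigma0=float(grid.sigma0[is_]),
        eta=float(grid.eta[ie]),
        cab=config.cab,
        p=config.photon_conversion,
        u0=config.foveal_inhibition_cutoff,
        phi0=config.foveal_neural_noise,
        te=config.integration_time,
    )
    predicted = np.asarray(
        csf_spatial(age, ctx.u, conditions, params=best, config=config)
    )
    residuals = predicted - ctx.y
    return FitResult(
        best=best,
        rmse=rmse(predicted, ctx.y),
        residuals=residuals,
        grid=grid,
        n_evaluated=n_eval,
        strategy=strategy,
        age=age,
    )


# ---------------------------------------------------------------------------
# model comparison


def aging_predictor(config: ModelConfig = DEFAULT_CONFIG) -> Callable:
    """Predictor using the full age-dependent model (analytical age curves)."""

    def predict(age, u, conditions):
        return np.asarray(csf_spatial(age, u, conditions, config=config))

    return predict


def baseline_predictor(
    params: ParameterSet | None = None, config: ModelConfig = DEFAULT_CONFIG
) -> Callable:
    """Age-independent predictor (classical defaults, luminance-only pupil)."""
    if params is None:
        params = barten_default_params(config=config)

    def predict(age, u, conditions):
        return np.asarray(csf_barten(u, conditions, params, config=config))

    return predict


@dataclass
class ModelComparison:
    """Per-age-group RMSE comparison of two CSF models."""

    label_a: str
    label_b: str
    groups: list  # dicts: {"age", "rmse_a", "rmse_b", "winner"}

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "groups": self.groups,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelComparison":
        return cls(label_a=data["label_a"], label_b=data["label_b"], groups=data["groups"])

    @classmethod
    def from_json(cls, text: str) -> "ModelComparison":
        return cls.from_dict(json.loads(text))


def compare_models(
    dataset: CSFDataset,
    model_a: Callable,
    model_b: Callable,
    label_a: str = "model_a",
    label_b: str = "model_b",
) -> ModelComparison:
    """Compare two CSF predictors by per-age-group RMSE.

    Each model is a callable ``(age, frequencies, conditions) -> array`` of
    predicted sensitivities. The winner per group is the model with the
    smaller RMSE ("tie" on exact equality).
    """
    if len(dataset) == 0:
        raise ValueError("cannot compare models on an empty dataset")
    groups = []
    for age, group in dataset.group_by_age().items():
        conditions = group.conditions()
        u = group.frequencies
        y = group.sensitivities
        ra = rmse(model_a(age, u, conditions), y)
        rb = rmse(model_b(age, u, conditions), y)
        winner = "tie" if ra == rb else (label_a if ra < rb else label_b)
        groups.append(
            {"age": float(age), "rmse_a": ra, "rmse_b": rb, "winner": winner}
        )
    return ModelComparison(label_a=label_a, label_b=label_b, groups=groups)
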