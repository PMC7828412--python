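"""Synthetic solubility data with the error structure the models assume.

The generator emulates a static-equilibrium solubility study: a solute
equilibrated at a small grid of temperatures (default five points,
298.15–318.15 K) and, for binary solvents, a composition grid (default
w2 = 0, 0.1, …, 1). Measurement error is multiplicative log-normal on x —
saturation solubilities span orders of magnitude across solvents, so
relative (not absolute) error is the physically sensible noise model — and
each reported point is the arithmetic mean of ``replicates`` independent
draws on the linear scale, mirroring triplicate assays averaged before
analysis.

For a coefficient of variation ``cv`` the log-scale noise is
ε ~ Normal(0, σ²) with σ² = ln(1 + cv²), which gives each *draw*
(not its mean) exactly the requested cv. Draws that land above x = 1 are
rejected and resampled a bounded number of times, so generated solubilities
always remain valid mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, WrongModelError
from .models import (
    ApelblatParams,
    BKMParams,
    JAVHParams,
    MixtureGrid,
    TemperatureSeries,
    VantHoffParams,
    eval_apelblat,
    eval_bkm,
    eval_javh,
    eval_vanthoff,
)

__all__ = ["GeneratorSpec", "generate_temperature_series", "generate_mixture_grid"]

DEFAULT_TEMPERATURES = (298.15, 303.15, 308.15, 313.15, 318.15)
DEFAULT_COMPOSITIONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))

_SINGLE_SOLVENT_MODELS = {"apelblat", "vanthoff", "bkm"}
_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    ``model`` is one of ``apelblat``, ``vanthoff``, ``bkm`` (single-solvent)
    or ``javh`` (binary mixture); ``params`` must be the matching parameter
    record. ``noise_cv`` is the per-draw coefficient of variation of the
    multiplicative noise (0.03 by default, a typical relative uncertainty
    for HPLC-assayed equilibrium solubilities).
    """

    model: str
    params: object
    temperatures: tuple = DEFAULT_TEMPERATURES
    compositions: tuple | None = DEFAULT_COMPOSITIONS
    noise_cv: float = 0.03
    seed: int = 0
    replicates: int = 3
    solvent_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.model not in _SINGLE_SOLVENT_MODELS | {"javh"}:
            raise InvalidInputError(f"unknown model {self.model!r}")
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if any(t <= 0 for t in self.temperatures):
            raise InvalidInputError("temperatures must be positive")
        expected = {
            "apelblat": ApelblatParams,
            "vanthoff": VantHoffParams,
            "bkm": BKMParams,
            "javh": JAVHParams,
        }[self.model]
        if not isinstance(self.params, expected):
            raise InvalidInputError(
                f"model {self.model!r} requires {expected.__name__} parameters"
            )


def _predict_x(spec: GeneratorSpec, w2: np.ndarray | None, T: np.ndarray) -> np.ndarray:
    if spec.model == "apelblat":
        return np.exp(eval_apelblat(spec.params, T))
    if spec.model == "vanthoff":
        return np.exp(eval_vanthoff(spec.params, T))
    if spec.model == "bkm":
        return np.asarray(eval_bkm(spec.params, T))
    return np.exp(eval_javh(spec.params, w2, T))


def _noisy_mean(x_true: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Arithmetic mean over replicates of log-normal multiplicative draws,
    resampling (bounded) any draw that exceeds x = 1."""
    if spec.noise_cv == 0:
        return x_true.copy()
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    draws = np.empty((spec.replicates, x_true.size))
    for r in range(spec.replicates):
        sample = x_true * np.exp(rng.normal(0.0, sigma, size=x_true.size))
        for _ in range(_MAX_RESAMPLE):
            bad = sample > 1.0
            if not bad.any():
                break
            sample[bad] = x_true[bad] * np.exp(rng.normal(0.0, sigma, size=bad.sum()))
        else:
            raise InvalidInputError(
                "could not generate valid mole fractions; noise_cv too large "
                "for solubilities this close to 1"
            )
        draws[r] = sample
    return draws.mean(axis=0)


def generate_temperature_series(spec: GeneratorSpec) -> TemperatureSeries:
    """Synthetic single-solvent solubility series; deterministic given seed."""
    if spec.model not in _SINGLE_SOLVENT_MODELS:
        raise WrongModelError(
            f"{spec.model!r} is composition-dependent; use generate_mixture_grid"
        )
    rng = np.random.default_rng(spec.seed)
    T = np.asarray(sorted(spec.temperatures), dtype=float)
    x = _noisy_mean(_predict_x(spec, None, T), spec, rng)
    return TemperatureSeries(solvent_id=spec.solvent_id, temperatures=T, x=x)


def generate_mixture_grid(spec: GeneratorSpec) -> MixtureGrid:
    """Synthetic (w2 × T) solubility grid; deterministic given seed."""
    if spec.model != "javh":
        raise WrongModelError("generate_mixture_grid requires the javh model")
    if spec.compositions is None or len(spec.compositions) == 0:
        raise InvalidInputError("a composition list is required for a mixture grid")
    rng = np.random.default_rng(spec.seed)
    w2g, Tg = np.meshgrid(
        np.asarray(spec.compositions, dtype=float),
        np.asarray(sorted(spec.temperatures), dtype=float),
        indexing="ij",
    )
    w2, T = w2g.ravel(), Tg.ravel()
    x = _noisy_mean(_predict_x(spec, w2, T), spec, rng)
    return MixtureGrid(w2=w2, temperatures=T, x=x)
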