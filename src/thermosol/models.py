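"""Temperature- and composition-dependent solubility models.

Five models are implemented, in the forms standard in the solubility
correlation literature:

* modified Apelblat:            ln x = A + B/T + C·ln T
* van't Hoff:                   ln x = a + b/T
* Buchowski–Ksiazaczak λh:      ln(1 + λ(1−x)/x) = λh·(1/T − 1/Tm)
* Yalkowsky log-linear mixing:  ln x_m = w1·ln x1 + w2·ln x2
* Jouyban–Acree van't Hoff:     ln x = α1·w1 + α2·w1/T + α3·w2 + α4·w2/T
                                       + Σ_i J_i·w1·w2·(w1−w2)^i / T

Fit quality is scored by the signed mean relative deviation (MRD %), its
absolute-value variant, and the root-mean-square deviation (RMSD), all on
the linear mole-fraction scale.

By default every fit minimises residuals in ln x, the scale on which these
models are linear or nearly so and on which multiplicative measurement error
is homoscedastic; pass ``objective="linear"`` to the nonlinear fitters to
minimise residuals in x instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateDesignError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    OutOfDomainError,
)

__all__ = [
    "TemperatureSeries",
    "MixtureGrid",
    "ApelblatParams",
    "VantHoffParams",
    "BKMParams",
    "JAVHParams",
    "FitQuality",
    "eval_apelblat",
    "eval_vanthoff",
    "eval_bkm",
    "eval_yalkowsky",
    "eval_javh",
    "fit_apelblat",
    "fit_vanthoff",
    "fit_bkm",
    "fit_javh",
    "mrd",
    "mrd_abs",
    "rmsd",
    "select_antisolvent_composition",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureSeries:
    """Mole-fraction solubility of one solute in one solvent vs temperature."""

    solvent_id: str
    temperatures: np.ndarray  # K, strictly increasing
    x: np.ndarray  # mole fraction, in (0, 1]

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "x", x)
        if T.shape != x.shape or T.ndim != 1:
            raise InvalidInputError("temperatures and x must be 1-D and equal length")
        if np.any(np.diff(T) <= 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        if np.any(T <= 0):
            raise InvalidInputError("temperatures must be positive (kelvin)")
        if np.any(x <= 0) or np.any(x > 1):
            raise InvalidInputError("mole fractions must lie in (0, 1]")

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class MixtureGrid:
    """Solubility over a (cosolvent fraction w2, temperature) grid.

    Stored long-form: parallel 1-D arrays of w2, T and x. The grid need not
    be complete or rectangular.
    """

    w2: np.ndarray
    temperatures: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        w2 = np.asarray(self.w2, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        x = np.asarray(self.x, dtype=float)
        for name, arr in (("w2", w2), ("temperatures", T), ("x", x)):
            object.__setattr__(self, name, arr)
        if not (w2.shape == T.shape == x.shape) or w2.ndim != 1:
            raise InvalidInputError("w2, temperatures and x must be 1-D, equal length")
        if np.any((w2 < 0) | (w2 > 1)):
            raise InvalidInputError("w2 must lie in [0, 1]")
        if np.any(T <= 0):
            raise InvalidInputError("temperatures must be positive (kelvin)")
        if np.any(x <= 0) or np.any(x > 1):
            raise InvalidInputError("mole fractions must lie in (0, 1]")

    def __len__(self) -> int:
        return self.w2.size

    @property
    def n_compositions(self) -> int:
        return np.unique(self.w2).size

    @property
    def n_temperatures(self) -> int:
        return np.unique(self.temperatures).size


@dataclass(frozen=True)
class ApelblatParams:
    A: float
    B: float  # K
    C: float


@dataclass(frozen=True)
class VantHoffParams:
    a: float  # intercept
    b: float  # K, slope against 1/T


@dataclass(frozen=True)
class BKMParams:
    lam: float  # λ > 0, dimensionless
    h: float  # K
    Tm: float  # melting temperature, K

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise InvalidInputError("λ must be > 0")
        if self.Tm <= 0:
            raise InvalidInputError("Tm must be > 0")


@dataclass(frozen=True)
class JAVHParams:
    """Jouyban–Acree van't Hoff parameters.

    ``alpha1, alpha2`` are the van't Hoff intercept/slope of solvent 1 (the
    w2 = 0 endpoint), ``alpha3, alpha4`` those of solvent 2; ``J0, J1, J2``
    are the three composition–temperature interaction coefficients.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    J0: float
    J1: float
    J2: float


@dataclass(frozen=True)
class FitQuality:
    """Agreement between observed and fitted solubilities.

    ``mrd_percent`` is the signed mean relative deviation
    100/N · Σ (x_exp − x_cal)/x_exp, in which positive and negative
    deviations cancel; ``mrd_abs_percent`` takes absolute deviations and is
    the variant reported in comparison tables. ``rmsd`` is on the linear
    mole-fraction scale.
    """

    mrd_percent: float
    mrd_abs_percent: float
    rmsd: float
    n_points: int
    residuals: np.ndarray = field(repr=False)  # x_exp − x_cal


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------


def _as_pair(x_exp, x_cal) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(x_exp, dtype=float)
    b = np.asarray(x_cal, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("x_exp and x_cal must have equal length")
    if a.size == 0:
        raise InvalidInputError("inputs must be nonempty")
    return a, b


def mrd(x_exp, x_cal) -> float:
    """Signed mean relative deviation in percent: 100/N Σ (x_exp−x_cal)/x_exp."""
    a, b = _as_pair(x_exp, x_cal)
    if np.any(a <= 0):
        raise InvalidInputError("x_exp must be strictly positive")
    return float(100.0 * np.mean((a - b) / a))


def mrd_abs(x_exp, x_cal) -> float:
    """Mean absolute relative deviation in percent."""
    a, b = _as_pair(x_exp, x_cal)
    if np.any(a <= 0):
        raise InvalidInputError("x_exp must be strictly positive")
    return float(100.0 * np.mean(np.abs((a - b) / a)))


def rmsd(x_exp, x_cal) -> float:
    """Root-mean-square deviation on the linear mole-fraction scale."""
    a, b = _as_pair(x_exp, x_cal)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _quality(x_exp: np.ndarray, x_cal: np.ndarray) -> FitQuality:
    return FitQuality(
        mrd_percent=mrd(x_exp, x_cal),
        mrd_abs_percent=mrd_abs(x_exp, x_cal),
        rmsd=rmsd(x_exp, x_cal),
        n_points=int(np.asarray(x_exp).size),
        residuals=np.asarray(x_exp, float) - np.asarray(x_cal, float),
    )


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("temperature must be > 0 K")
    return T


def eval_apelblat(params: ApelblatParams, T) -> np.ndarray | float:
    """ln x = A + B/T + C·ln T."""
    T = _check_T(T)
    out = params.A + params.B / T + params.C * np.log(T)
    return float(out) if out.ndim == 0 else out


def eval_vanthoff(params: VantHoffParams, T) -> np.ndarray | float:
    """ln x = a + b/T."""
    T = _check_T(T)
    out = params.a + params.b / T
    return float(out) if out.ndim == 0 else out


def _bkm_lnx(loglam: float, h: float, Tm: float, T: np.ndarray) -> np.ndarray:
    """ln x of the λh model, computed stably in log space.

    ln x = ln λ − ln(expm1(u) + λ) with u = λh(1/T − 1/Tm). For large u the
    denominator is evaluated as u + log1p((λ−1)e^{−u}) to avoid overflow;
    a non-positive denominator (reachable only at unphysical h < 0 trial
    points during optimisation) is clamped, which acts as a large residual
    penalty rather than a NaN.
    """
    lam = np.exp(loglam)
    u = np.asarray(lam * h * (1.0 / T - 1.0 / Tm), dtype=float)
    ln_denom = np.empty_like(u)
    big = u > 30.0
    ln_denom[big] = u[big] + np.log1p((lam - 1.0) * np.exp(-u[big]))
    d = np.expm1(u[~big]) + lam
    ln_denom[~big] = np.log(np.maximum(d, 1e-300))
    return loglam - ln_denom


def eval_bkm(params: BKMParams, T) -> np.ndarray | float:
    """Mole-fraction solubility from the λh model, by closed-form inversion.

    The implicit relation ln(1 + λ(1−x)/x) = λh(1/T − 1/Tm) solves exactly to

        x = λ / (expm1(λh(1/T − 1/Tm)) + λ),

    which satisfies the defining identity to rounding error and hits x = 1
    at T = Tm.
    """
    T = _check_T(T)
    if np.any(T > params.Tm):
        raise OutOfDomainError("λh model is defined only for T <= Tm")
    out = np.exp(_bkm_lnx(np.log(params.lam), params.h, params.Tm, T))
    return float(out) if out.ndim == 0 else out


def eval_yalkowsky(lnx1, lnx2, w2) -> np.ndarray | float:
    """Log-linear mixing rule: ln x_m = (1−w2)·ln x1 + w2·ln x2."""
    w2 = np.asarray(w2, dtype=float)
    if np.any((w2 < 0) | (w2 > 1)):
        raise InvalidInputError("w2 must lie in [0, 1]")
    out = (1.0 - w2) * np.asarray(lnx1, float) + w2 * np.asarray(lnx2, float)
    return float(out) if out.ndim == 0 else out


def _javh_design(w2: np.ndarray, T: np.ndarray) -> np.ndarray:
    w1 = 1.0 - w2
    return np.column_stack(
        [
            w1,
            w1 / T,
            w2,
            w2 / T,
            w1 * w2 / T,
            w1 * w2 * (w1 - w2) / T,
            w1 * w2 * (w1 - w2) ** 2 / T,
        ]
    )


def eval_javh(params: JAVHParams, w2, T) -> np.ndarray | float:
    """ln x under the Jouyban–Acree van't Hoff model."""
    T = _check_T(T)
    w2 = np.asarray(w2, dtype=float)
    if np.any((w2 < 0) | (w2 > 1)):
        raise InvalidInputError("w2 must lie in [0, 1]")
    w2b, Tb = np.broadcast_arrays(w2, T)
    beta = np.array(
        [
            params.alpha1,
            params.alpha2,
            params.alpha3,
            params.alpha4,
            params.J0,
            params.J1,
            params.J2,
        ]
    )
    out = _javh_design(np.atleast_1d(w2b).ravel(), np.atleast_1d(Tb).ravel()) @ beta
    out = out.reshape(w2b.shape)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _require_points(series: TemperatureSeries, n: int, what: str) -> None:
    if len(series) < n:
        raise InsufficientDataError(
            f"{what} needs at least {n} points, got {len(series)}"
        )


def fit_vanthoff(series: TemperatureSeries) -> tuple[VantHoffParams, FitQuality]:
    """Ordinary least squares of ln x on 1/T; exact, no iteration."""
    _require_points(series, 3, "van't Hoff fit")
    T, lnx = series.temperatures, np.log(series.x)
    X = np.column_stack([np.ones_like(T), 1.0 / T])
    beta, *_ = np.linalg.lstsq(X, lnx, rcond=None)
    params = VantHoffParams(a=float(beta[0]), b=float(beta[1]))
    x_cal = np.exp(eval_vanthoff(params, T))
    return params, _quality(series.x, x_cal)


def fit_apelblat(
    series: TemperatureSeries, objective: str = "log"
) -> tuple[ApelblatParams, FitQuality]:
    """Least-squares Apelblat fit.

    The model is linear in (A, B, C), so with the default ``objective="log"``
    the minimiser of the ln-x residuals is found in closed form. The 1, 1/T
    and ln T regressors are strongly collinear over narrow temperature
    windows, so the normal equations are avoided in favour of an SVD-based
    solve. With ``objective="linear"`` residuals are minimised in x by
    Levenberg–Marquardt, warm-started from the log-scale solution.
    """
    _require_points(series, 4, "Apelblat fit")
    T, lnx = series.temperatures, np.log(series.x)
    X = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])
    beta, *_ = np.linalg.lstsq(X, lnx, rcond=None)
    params = ApelblatParams(A=float(beta[0]), B=float(beta[1]), C=float(beta[2]))
    if objective == "linear":

        def resid(p):
            return np.exp(X @ p) - series.x

        sol = least_squares(resid, beta, method="lm", xtol=1e-15, ftol=1e-15)
        if not sol.success:
            raise FitFailureError(
                "Apelblat linear-scale fit did not converge",
                {"status": sol.status, "message": sol.message},
            )
        params = ApelblatParams(A=float(sol.x[0]), B=float(sol.x[1]), C=float(sol.x[2]))
    elif objective != "log":
        raise InvalidInputError("objective must be 'log' or 'linear'")
    x_cal = np.exp(eval_apelblat(params, T))
    return params, _quality(series.x, x_cal)


def fit_bkm(
    series: TemperatureSeries, Tm: float, objective: str = "log"
) -> tuple[BKMParams, FitQuality]:
    """Nonlinear λh fit with λ > 0, warm-started from the van't Hoff line.

    In the small-λ / small-x regime the λh model degenerates to
    ln x ≈ ln λ − λh/T + λh/Tm, so the van't Hoff slope b fixes the product
    λh ≈ −b; the starting point takes λ0 = 1e-3 and h0 = −b/λ0. λ is
    optimised on a log scale to keep it positive and to make the search
    well-scaled across the many orders of magnitude it can span.
    """
    _require_points(series, 3, "λh fit")
    if Tm <= series.temperatures.max():
        raise InvalidInputError("Tm must exceed the largest data temperature")
    if objective not in ("log", "linear"):
        raise InvalidInputError("objective must be 'log' or 'linear'")
    T = series.temperatures
    vh, _ = fit_vanthoff(series)
    lam0 = 1e-3
    h0 = -vh.b / lam0 if vh.b < 0 else max(abs(vh.b), 1.0) / lam0

    lnx = np.log(series.x)

    def resid(p):
        lnx_cal = _bkm_lnx(p[0], p[1], Tm, T)
        if objective == "log":
            return lnx_cal - lnx
        return np.exp(lnx_cal) - series.x

    best = None
    tried = []
    for lam_start in (lam0, 1e-1, 1.0):
        h_start = h0 * lam0 / lam_start
        sol = least_squares(
            resid,
            np.array([np.log(lam_start), h_start]),
            method="trf",
            bounds=([-60.0, -np.inf], [6.0, np.inf]),  # λ ∈ [e⁻⁶⁰, e⁶]
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        tried.append({"lam0": lam_start, "status": sol.status, "cost": sol.cost})
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("λh fit did not converge", {"attempts": tried})
    params = BKMParams(lam=float(np.exp(best.x[0])), h=float(best.x[1]), Tm=float(Tm))
    x_cal = eval_bkm(params, T)
    return params, _quality(series.x, x_cal)


def fit_javh(grid: MixtureGrid) -> tuple[JAVHParams, FitQuality]:
    """Multiple linear regression of ln x on the seven Jouyban–Acree van't
    Hoff regressors; exact linear-algebra solution."""
    if grid.n_compositions < 3 or grid.n_temperatures < 3:
        raise InsufficientDataError(
            "JAVH fit needs a grid spanning >= 3 compositions and >= 3 temperatures"
        )
    X = _javh_design(grid.w2, grid.temperatures)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("JAVH design matrix is rank deficient")
    lnx = np.log(grid.x)
    beta, *_ = np.linalg.lstsq(X, lnx, rcond=None)
    params = JAVHParams(*(float(v) for v in beta))
    x_cal = np.exp(X @ beta)
    return params, _quality(grid.x, x_cal)


# ---------------------------------------------------------------------------
# anti-solvent design
# ---------------------------------------------------------------------------


def select_antisolvent_composition(
    fit: JAVHParams,
    T: float,
    max_solvent_fraction: float,
    grid_step: float = 0.1,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Choose the cosolvent fraction for anti-solvent precipitation.

    Liquid anti-solvent precipitation works by quenching a drug–solvent
    solution into a miscible anti-solvent; supersaturation (hence nucleation
    rate) is highest where the mixed-solvent solubility is lowest. This
    searches a composition grid restricted to
    ``w2 <= max_solvent_fraction`` — the solvent-to-anti-solvent ratio cap,
    conventionally < 0.2 — and returns ``(w2*, x_pred)`` minimising the
    predicted solubility, breaking ties toward smaller w2.
    """
    if not 0.0 < max_solvent_fraction <= 1.0:
        raise InvalidInputError("max_solvent_fraction must lie in (0, 1]")
    if grid is None:
        grid = np.arange(0.0, 1.0 + 0.5 * grid_step, grid_step)
    grid = np.asarray(grid, dtype=float)
    feasible = grid[grid <= max_solvent_fraction + 1e-12]
    if feasible.size == 0:
        raise InvalidInputError("no grid point satisfies the composition cap")
    feasible = np.sort(feasible)
    lnx = np.atleast_1d(eval_javh(fit, feasible, T))
    i = int(np.argmin(lnx))  # argmin takes the first minimum: ties → smaller w2
    return float(feasible[i]), float(np.exp(lnx[i]))
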