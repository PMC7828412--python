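"""Kamlet–Taft linear solvation energy relationship (KAT-LSER).

Solubility across a solvent panel is regressed on solvatochromic
descriptors:

    ln x_e = c0 + c1·α + c2·β + c3·π* + c4·Vs·δH²/(100·R·T)

where α is hydrogen-bond donor acidity, β hydrogen-bond acceptor basicity,
π* dipolarity/polarizability, δH the Hildebrand solubility parameter
(MPa^0.5) and Vs the solute molar volume entering the cohesive-energy
(cavity) term. c1 and c2 measure the solute's susceptibility to
solute–solvent hydrogen bonding, c3 to non-specific electrostatic
interactions, and c4 to the solvent–solvent cohesion penalty of cavity
formation.

Percentage contributions of the four non-intercept terms are computed as
|cᵢ|·mean(|regressor_i|), normalised to 100% — the usual effect-share
convention in the LSER literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import inf

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import GAS_CONSTANT as R
from .exceptions import DegenerateDesignError, InsufficientDataError, InvalidInputError

__all__ = [
    "SolventDescriptors",
    "KATLSERFit",
    "load_descriptors",
    "build_design_matrix",
    "fit_katlser",
]

#: Default solute molar-volume input for the cohesive-energy regressor, the
#: Fedors group-contribution value reported for ABN401. The literature source
#: prints it with solubility-parameter units, so its magnitude should be
#: treated as a convention of that dataset; supply your own Vs for other
#: solutes.
DEFAULT_VS = 26.5

TERM_NAMES = ("alpha", "beta", "pi_star", "cavity")


@dataclass(frozen=True)
class SolventDescriptors:
    """Kamlet–Taft descriptors plus Hildebrand parameter for one solvent."""

    solvent_id: str
    alpha: float
    beta: float
    pi_star: float
    delta_H: float  # MPa^0.5

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.pi_star, self.delta_H)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("descriptors must be finite")
        if self.delta_H < 0:
            raise InvalidInputError("delta_H must be >= 0")


@dataclass(frozen=True)
class KATLSERFit:
    coef: np.ndarray  # c0..c4
    standard_errors: np.ndarray
    r2: float
    F: float  # +inf on an exact (zero-residual) fit
    rss: float
    Vs: float
    contributions: dict[str, float]  # percent share per non-intercept term
    n: int


def load_descriptors(path=None) -> list[SolventDescriptors]:
    """Read a descriptor table (columns solvent_id, alpha, beta, pi_star,
    delta_H); defaults to the bundled literature-typical panel of ten common
    pharmaceutical solvents."""
    if path is None:
        ref = resources.files("thermosol.data") / "solvent_descriptors.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"solvent_id", "alpha", "beta", "pi_star", "delta_H"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"descriptor table missing columns: {sorted(missing)}")
    return [
        SolventDescriptors(
            solvent_id=str(r.solvent_id),
            alpha=float(r.alpha),
            beta=float(r.beta),
            pi_star=float(r.pi_star),
            delta_H=float(r.delta_H),
        )
        for r in df.itertuples()
    ]


def build_design_matrix(descriptors, Vs: float, T: float) -> np.ndarray:
    """Rows = solvents; columns = [1, α, β, π*, Vs·δH²/(100·R·T)]."""
    if Vs <= 0:
        raise InvalidInputError("Vs must be > 0")
    if T <= 0:
        raise InvalidInputError("T must be > 0 K")
    rows = [
        [1.0, d.alpha, d.beta, d.pi_star, Vs * d.delta_H**2 / (100.0 * R * T)]
        for d in descriptors
    ]
    return np.asarray(rows, dtype=float)


def fit_katlser(lnx, design: np.ndarray, Vs: float = DEFAULT_VS) -> KATLSERFit:
    """OLS fit of ln x on a KAT-LSER design matrix built by
    :func:`build_design_matrix`."""
    lnx = np.asarray(lnx, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != 5:
        raise InvalidInputError("design must be n×5 ([1, α, β, π*, cavity])")
    if lnx.shape != (design.shape[0],):
        raise InvalidInputError("lnx length must match design rows")
    n = design.shape[0]
    if n < 6:
        raise InsufficientDataError("KAT-LSER needs >= 6 solvents (5 coefficients)")
    if np.linalg.matrix_rank(design) < 5:
        raise DegenerateDesignError("KAT-LSER design matrix is rank deficient")

    res = sm.OLS(lnx, design).fit()
    rss = float(res.ssr)
    tss = float(np.sum((lnx - lnx.mean()) ** 2))
    # guard the exact-fit limit: statsmodels returns nan/overflow F there
    if rss <= 1e-12 * max(tss, 1.0):
        F, r2 = inf, 1.0
    else:
        F, r2 = float(res.fvalue), float(res.rsquared)
    coef = np.asarray(res.params, dtype=float)
    weights = np.abs(coef[1:]) * np.mean(np.abs(design[:, 1:]), axis=0)
    total = weights.sum()
    if total == 0:
        contributions = {name: 0.0 for name in TERM_NAMES}
    else:
        contributions = {
            name: float(100.0 * w / total) for name, w in zip(TERM_NAMES, weights)
        }
    return KATLSERFit(
        coef=coef,
        standard_errors=np.asarray(res.bse, dtype=float),
        r2=r2,
        F=F,
        rss=rss,
        Vs=Vs,
        contributions=contributions,
        n=n,
    )
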