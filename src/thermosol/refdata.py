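"""Bundled reference parameter sets for ABN401.

ABN401 is a synthetic c-Met tyrosine-kinase inhibitor (C29H34N12O,
566.66 g·mol⁻¹) whose equilibrium solubility has been characterised in
eleven pure solvents and in Transcutol HP–water mixtures over
298.15–318.15 K. The literature-reported model parameters for those systems
ship with the package as a worked reference system: they parameterise the
synthetic-data generator, the example pipeline, and golden-value tests.

Scale factors used by the published tables (λ·10⁻², h·10⁻³, …) are already
applied in the bundled JSON, so every accessor here returns true parameter
values.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .models import ApelblatParams, BKMParams, JAVHParams, VantHoffParams
from .thermo import FusionProperties

__all__ = [
    "load_reference",
    "reference_temperatures",
    "fusion_properties",
    "vanthoff_params",
    "apelblat_params",
    "bkm_params",
    "javh_params",
    "mixture_vanthoff_rows",
    "yalkowsky_endpoints",
    "solvent_ids",
]


@lru_cache(maxsize=1)
def load_reference() -> dict:
    """Raw reference record (parsed JSON); cached."""
    ref = resources.files("thermosol.data") / "abn401_reference_params.json"
    with resources.as_file(ref) as p:
        return json.loads(p.read_text())


def reference_temperatures() -> np.ndarray:
    return np.asarray(load_reference()["temperatures_K"], dtype=float)


def fusion_properties() -> FusionProperties:
    d = load_reference()["drug"]
    return FusionProperties(Tfus=d["Tfus_K"], dHfus=d["dHfus_J_mol"])


def solvent_ids() -> list[str]:
    return list(load_reference()["pure_solvents"].keys())


def _solvent(solvent_id: str) -> dict:
    try:
        return load_reference()["pure_solvents"][solvent_id]
    except KeyError:
        raise KeyError(
            f"no reference parameters for {solvent_id!r}; "
            f"known solvents: {solvent_ids()}"
        ) from None


def vanthoff_params(solvent_id: str) -> VantHoffParams:
    return VantHoffParams(**_solvent(solvent_id)["vanthoff"])


def apelblat_params(solvent_id: str) -> ApelblatParams:
    return ApelblatParams(**_solvent(solvent_id)["apelblat"])


def bkm_params(solvent_id: str, Tm: float | None = None) -> BKMParams:
    rec = _solvent(solvent_id)["bkm"]
    if Tm is None:
        Tm = load_reference()["drug"]["Tfus_K"]
    return BKMParams(lam=rec["lam"], h=rec["h"], Tm=Tm)


def javh_params() -> JAVHParams:
    return JAVHParams(**load_reference()["binary_mixture"]["javh"])


def mixture_vanthoff_rows() -> list[tuple[float, VantHoffParams]]:
    """Per-composition van't Hoff parameters of the binary mixture,
    as (w2, params) pairs ordered by w2."""
    rows = load_reference()["binary_mixture"]["rows"]
    return [(r["w2"], VantHoffParams(**r["vanthoff"])) for r in rows]


def yalkowsky_endpoints() -> dict[float, tuple[float, float]]:
    """Published pure-solvent ln x endpoints keyed by temperature.

    Returns {T: (ln x_solvent1, ln x_solvent2)} with solvent1 = water and
    solvent2 = Transcutol HP.
    """
    ep = load_reference()["binary_mixture"]["yalkowsky_endpoints"]
    return {
        float(T): (float(l1), float(l2))
        for T, l1, l2 in zip(
            ep["temperatures_K"], ep["lnx_solvent1"], ep["lnx_solvent2"]
        )
    }
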