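"""In-vitro to in-vivo extrapolation of hepatic clearance.

Intrinsic clearance measured in hepatocyte stability assays (uL/min per 1e6
cells) is corrected for incubational binding, scaled to whole-liver per-kg
terms via hepatocellularity and liver weight, and folded through the
well-stirred liver model to predict blood clearance, bounded by hepatic blood
flow.  An empirical regression offset (default 3-fold) corrects the
well-known systematic underprediction of in-vivo clearance from hepatocyte
data; two placements of the offset are supported because the published
species predictions do not pin down a single one:

* ``pre_wsm_multiply`` (default): multiply the scaled unbound intrinsic
  clearance by the offset before the well-stirred model, which preserves the
  hepatic-flow ceiling;
* ``post_wsm_divide``: apply the well-stirred model to the raw scaled value
  and divide the result by the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import SpeciesBundle, load_species
from .model import ConfigurationError, InvalidInputError

__all__ = [
    "IviveInput",
    "scale_clint",
    "well_stirred",
    "blood_to_plasma_cl",
    "predict_clearance",
    "ivive_report",
]

OFFSET_MODES = ("pre_wsm_multiply", "post_wsm_divide")

# uL/min/kg -> L/h/kg
_UL_MIN_TO_L_H = 60.0 / 1e9 * 1e3  # 60 min/h, 1e6 uL/L; == 6e-5


@dataclass(frozen=True)
class IviveInput:
    """Hepatocyte-assay and physiological inputs for one species."""

    Clint: float  # uL/min per 1e6 cells
    hepatocellularity: float  # 1e6 cells per g liver
    liver_weight: float  # g
    BW: float  # kg
    Qh: float  # hepatic blood flow, L/kg/h
    fu_blood: float  # fraction unbound in blood
    fuinc: float = 0.007  # incubational unbound fraction
    regression_offset: float = 3.0
    offset_mode: str = "pre_wsm_multiply"

    def __post_init__(self) -> None:
        for name in ("Clint", "hepatocellularity", "liver_weight", "BW", "Qh"):
            if getattr(self, name) < 0 or (name != "Clint" and getattr(self, name) == 0):
                raise InvalidInputError(f"{name} must be positive")
        if self.fuinc <= 0:
            raise InvalidInputError("fuinc must be positive")
        if not 0 < self.fu_blood <= 1:
            raise InvalidInputError("fu_blood must lie in (0, 1]")
        if self.offset_mode not in OFFSET_MODES:
            raise InvalidInputError(
                f"offset_mode must be one of {OFFSET_MODES}"
            )


def scale_clint(inp: IviveInput) -> float:
    """Scaled unbound intrinsic clearance, L/h per kg body weight.

    ``(Clint / fuinc) * hepatocellularity * liver_weight / BW`` converted from
    uL/min/kg to L/h/kg.
    """
    ul_min_per_kg = (
        inp.Clint / inp.fuinc * inp.hepatocellularity * inp.liver_weight / inp.BW
    )
    return ul_min_per_kg * _UL_MIN_TO_L_H


def well_stirred(
    cl_scaled_u: float,
    fu_blood: float,
    qh: float,
    offset: float = 1.0,
    offset_mode: str = "pre_wsm_multiply",
) -> float:
    """Well-stirred liver model: CL = Qh*fu*CLu / (Qh + fu*CLu), L/kg/h.

    With ``pre_wsm_multiply`` the offset multiplies CLu inside the model (the
    output stays below Qh); with ``post_wsm_divide`` the model output is
    divided by the offset.
    """
    if qh <= 0:
        raise InvalidInputError("Qh must be positive")
    if cl_scaled_u < 0 or fu_blood <= 0 or offset <= 0:
        raise InvalidInputError("cl_scaled_u >= 0 and fu_blood, offset > 0 required")
    if offset_mode not in OFFSET_MODES:
        raise InvalidInputError(f"offset_mode must be one of {OFFSET_MODES}")
    if offset_mode == "pre_wsm_multiply":
        eff = fu_blood * cl_scaled_u * offset
        return qh * eff / (qh + eff)
    eff = fu_blood * cl_scaled_u
    return qh * eff / (qh + eff) / offset


def blood_to_plasma_cl(cl_blood: float, bpr: float) -> float:
    """Convert blood clearance to plasma clearance: CL_plasma = CL_blood * BPR."""
    if bpr <= 0:
        raise InvalidInputError("BPR must be positive")
    return cl_blood * bpr


def predict_clearance(inp: IviveInput, bpr: float) -> dict[str, float]:
    """Full IVIVE chain for one species: scaled Clint -> blood and plasma CL."""
    cl_scaled = scale_clint(inp)
    cl_blood = well_stirred(
        cl_scaled, inp.fu_blood, inp.Qh, inp.regression_offset, inp.offset_mode
    )
    return {
        "cl_scaled_u": cl_scaled,
        "cl_blood": cl_blood,
        "cl_plasma": blood_to_plasma_cl(cl_blood, bpr),
    }


def _input_from_bundle(bundle: SpeciesBundle, offset_mode: str) -> IviveInput:
    iv = bundle.ivive
    missing = {"Clint", "hepatocellularity", "liver_weight", "Qh"} - iv.keys()
    if missing:
        raise ConfigurationError(
            f"{bundle.name} config lacks IVIVE fields: {sorted(missing)}"
        )
    return IviveInput(
        Clint=iv["Clint"],
        hepatocellularity=iv["hepatocellularity"],
        liver_weight=iv["liver_weight"],
        BW=bundle.physiology.BW,
        Qh=iv["Qh"],
        fu_blood=bundle.physiology.fup / bundle.physiology.BPR,
        fuinc=iv.get("fuinc", 0.007),
        offset_mode=offset_mode,
    )


def ivive_report(
    species: tuple[str, ...] = ("mouse", "rat", "dog", "human"),
    offset_mode: str = "pre_wsm_multiply",
) -> pd.DataFrame:
    """Predicted vs measured clearance per species, with a 2-fold concordance
    flag (``within_2fold`` is NaN where no in-vivo measurement exists)."""
    rows = []
    for name in species:
        bundle = load_species(name)
        inp = _input_from_bundle(bundle, offset_mode)
        pred = predict_clearance(inp, bundle.physiology.BPR)
        measured = bundle.ivive.get("measured_blood_CL")
        fold = (
            max(measured / pred["cl_blood"], pred["cl_blood"] / measured)
            if measured
            else float("nan")
        )
        rows.append(
            {
                "species": name,
                "Clint_uL_min_1e6cells": inp.Clint,
                "cl_scaled_u_L_h_kg": pred["cl_scaled_u"],
                "predicted_blood_CL_L_h_kg": pred["cl_blood"],
                "predicted_plasma_CL_L_h_kg": pred["cl_plasma"],
                "measured_blood_CL_L_h_kg": measured,
                "fold_difference": fold,
                "within_2fold": fold <= 2 if measured else None,
            }
        )
    return pd.DataFrame(rows)
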