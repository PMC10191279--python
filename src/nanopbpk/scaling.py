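"""Interspecies scaling of the mouse-fitted parameter set.

The mouse model is the only fitted one; rat, dog and human sets derive from
it by three rules:

* apparent volumes (V_b, V_R) scale with the ratio of blood unbound fractions
  fu,blood = fup/BPR between target species and mouse;
* the blood<->rest intercompartmental clearance Q_BR scales allometrically
  with body weight (exponent 0.7, applied on the absolute L/h scale and
  re-normalised per kg);
* binding/partition parameters (P_L, P_S, Bmax_L, Bmax_S, K_NBL) scale with
  the fu,blood ratio, while dissociation constants (KD_L, KD_S) and the fixed
  spleen partition coefficient K_NBS are held constant across species;
* nanoparticle extravasation rates (N_BL, N_BS) scale with the ratio of blood
  flow to the receiving organ (blood->liver flow for N_BL, spleen flow for
  N_BS).

Release rate constants and vascular volume fractions are conserved across
species.  The scaler doubles as a validator: every scaled entry is compared
against the published species value and mismatches beyond printed rounding
fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .config import SpeciesBundle, load_species
from .model import (
    ConfigurationError,
    ConjugatedApiParams,
    InvalidInputError,
    ReleasedApiParams,
    SpeciesPhysiology,
    rest_volume,
)

__all__ = [
    "ScalingContext",
    "fu_blood",
    "scale_volume",
    "scale_flow_allometric",
    "scale_binding",
    "scale_extravasation",
    "build_species_params",
    "compare_to_reference",
]

# fu,blood-ratio scaling applies to these binding parameters only; the
# dissociation constants and the fixed spleen partition coefficient are
# species-invariant and must not be passed to scale_binding.
BINDING_SCALED = ("P_L", "P_S", "Bmax_L", "Bmax_S", "K_NBL")
BINDING_FIXED = ("KD_L", "KD_S", "K_NBS")


def fu_blood(fup: float, bpr: float) -> float:
    """Fraction unbound in blood: fup / BPR."""
    if fup <= 0 or bpr <= 0:
        raise InvalidInputError("fup and BPR must be positive")
    return fup / bpr


@dataclass(frozen=True)
class ScalingContext:
    """Mouse (source) physiology paired with a target species physiology."""

    source: SpeciesPhysiology
    target: SpeciesPhysiology
    allometric_exponent: float = 0.7

    @property
    def fu_blood_ratio(self) -> float:
        return fu_blood(self.target.fup, self.target.BPR) / fu_blood(
            self.source.fup, self.source.BPR
        )


def scale_volume(v_source: float, ctx: ScalingContext) -> float:
    """Apparent volume scaling by the blood unbound-fraction ratio (V_b, V_R)."""
    return v_source * ctx.fu_blood_ratio


def scale_flow_allometric(q_source: float, ctx: ScalingContext) -> float:
    """Power-law body-weight scaling of a per-kg flow (Q_BR).

    The flow is converted to absolute L/h before exponentiation, then
    re-normalised per kg of the target species:
    ``(Q*BW_src) * (BW_tgt/BW_src)**b / BW_tgt``.
    """
    bw_s, bw_t = ctx.source.BW, ctx.target.BW
    return (q_source * bw_s) * (bw_t / bw_s) ** ctx.allometric_exponent / bw_t


def scale_binding(k_source: float, ctx: ScalingContext, name: str) -> float:
    """fu,blood-ratio scaling of a binding/partition parameter.

    Only P_L, P_S, Bmax_L, Bmax_S and K_NBL scale; dissociation constants and
    K_NBS are species-invariant and rejected here.
    """
    if name in BINDING_FIXED:
        raise InvalidInputError(f"{name} is constant across species; not scalable")
    if name not in BINDING_SCALED:
        raise InvalidInputError(f"{name} is not a binding/partition parameter")
    return k_source * ctx.fu_blood_ratio


def scale_extravasation(n_source: float, ctx: ScalingContext, organ: str) -> float:
    """Extravasation-rate scaling by the organ blood-flow ratio.

    Uses the blood->liver flow Q_BL_i for liver (extravasation is an uptake
    process) and the spleen flow Q_BS for spleen.
    """
    if organ == "liver":
        return n_source * ctx.target.Q_BL_i / ctx.source.Q_BL_i
    if organ == "spleen":
        return n_source * ctx.target.Q_BS / ctx.source.Q_BS
    raise InvalidInputError(f"unknown organ {organ!r}; expected liver or spleen")


def build_species_params(
    target_physio: SpeciesPhysiology,
    source: SpeciesBundle | None = None,
) -> tuple[ReleasedApiParams, ConjugatedApiParams]:
    """Derive a full released + conjugated parameter pair for a target species.

    ``source`` defaults to the packaged mouse bundle.  Clearance is not
    scalable this way (it comes from hepatocyte IVIVE or in-vivo measurement)
    and is copied from the source; callers override it per species.
    """
    if source is None:
        source = load_species("mouse")
    ctx = ScalingContext(source=source.physiology, target=target_physio)
    rel_s, conj_s = source.released, source.conjugated
    if ctx.source.species_name == target_physio.species_name:
        return rel_s, conj_s

    released = ReleasedApiParams(
        V_b=scale_volume(rel_s.V_b, ctx),
        V_R=scale_volume(rel_s.V_R, ctx),
        Q_BR=scale_flow_allometric(rel_s.Q_BR, ctx),
        CL=rel_s.CL,
        Bmax_L=scale_binding(rel_s.Bmax_L, ctx, "Bmax_L"),
        KD_L=rel_s.KD_L,
        P_L=scale_binding(rel_s.P_L, ctx, "P_L"),
        Bmax_S=scale_binding(rel_s.Bmax_S, ctx, "Bmax_S"),
        KD_S=rel_s.KD_S,
        P_S=scale_binding(rel_s.P_S, ctx, "P_S"),
    )
    conjugated = ConjugatedApiParams(
        V_NR=rest_volume(target_physio),
        N_BL=scale_extravasation(conj_s.N_BL, ctx, "liver"),
        N_BS=scale_extravasation(conj_s.N_BS, ctx, "spleen"),
        N_BR=0.0,
        K_NBL=scale_binding(conj_s.K_NBL, ctx, "K_NBL"),
        K_NBS=conj_s.K_NBS,
        krel_b=conj_s.krel_b,
        krel_L=conj_s.krel_L,
        krel_S=conj_s.krel_S,
        krel_R=conj_s.krel_R,
    )
    return released, conjugated


def _printed_tolerance(printed: float, rel_tol: float) -> float:
    """Allowance for a published value: max of rel_tol and half a unit in the
    last printed digit (tables round some entries to one significant figure)."""
    if printed == 0:
        return rel_tol
    # decimal exponent of the least-significant printed digit
    s = f"{printed:.15g}"
    if "e" in s or "E" in s:
        mantissa, exp = s.split("e")
        digits = len(mantissa.replace("-", "").replace(".", "").rstrip("0"))
        lsd = int(exp) - (digits - 1)
    elif "." in s:
        lsd = -len(s.split(".")[1])
    else:
        lsd = len(s) - len(s.rstrip("0"))
    half_ulp = 0.5 * 10.0 ** lsd
    return max(rel_tol * abs(printed), half_ulp)


def compare_to_reference(
    target: SpeciesBundle,
    source: SpeciesBundle | None = None,
    rel_tol: float = 0.05,
    strict: bool = True,
) -> pd.DataFrame:
    """Re-derive every scaled entry for a species and compare to its published
    value.  Returns a tidy report; with ``strict`` a disagreement beyond
    printed rounding raises :class:`ConfigurationError`.
    """
    released, conjugated = build_species_params(target.physiology, source=source)
    rows = []
    scaled_fields = [
        ("V_b", "released"), ("V_R", "released"), ("Q_BR", "released"),
        ("Bmax_L", "released"), ("P_L", "released"),
        ("Bmax_S", "released"), ("P_S", "released"),
        ("N_BL", "conjugated"), ("N_BS", "conjugated"), ("K_NBL", "conjugated"),
        ("V_NR", "conjugated"),
    ]
    derived = {"released": released, "conjugated": conjugated}
    published = {"released": target.released, "conjugated": target.conjugated}
    for name, block in scaled_fields:
        got = getattr(derived[block], name)
        want = getattr(published[block], name)
        tol = _printed_tolerance(want, rel_tol)
        rows.append(
            {
                "parameter": name,
                "scaled": got,
                "published": want,
                "rel_dev": abs(got - want) / abs(want) if want else float("nan"),
                "within_tolerance": abs(got - want) <= tol,
            }
        )
    report = pd.DataFrame(rows)
    if strict and not report["within_tolerance"].all():
        bad = report.loc[~report["within_tolerance"], "parameter"].tolist()
        raise ConfigurationError(
            f"scaled parameters deviate from published {target.name} values: {bad}"
        )
    return report


def scaled_bundle(species: str) -> SpeciesBundle:
    """Published bundle for a species with its scaled block re-derived from
    mouse (clearance and fixed rows taken from the packaged file)."""
    target = load_species(species)
    released, conjugated = build_species_params(target.physiology)
    released = replace(released, CL=target.released.CL)
    return SpeciesBundle(
        name=target.name,
        physiology=target.physiology,
        released=released,
        conjugated=conjugated,
        cl_range=target.cl_range,
        ivive=target.ivive,
    )
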