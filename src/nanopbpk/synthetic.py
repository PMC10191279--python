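"""Synthetic in-vivo-like study generator and parameter recovery.

No raw animal data are deposited for the nanoparticle studies, so this
module generates stand-in datasets from the PBPK model itself: the published
study designs (doses, routes, destructive sampling schedules, animals per
time point) drive a noiseless simulation, and per-observation multiplicative
log-normal measurement error plus optional lower-limit-of-quantification
(LLOQ) censoring produce realistic tables in the same tidy CSV dialect the
NCA and pipeline stages consume.  A least-squares fitter closes the loop by
recovering model parameters from such datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import load_species
from .model import (
    ConjugatedApiParams,
    DoseRegimen,
    InvalidInputError,
    ReleasedApiParams,
    SpeciesPhysiology,
    simulate,
)

__all__ = [
    "StudyDesign",
    "default_designs",
    "generate_dataset",
    "recover_parameters",
    "FitResult",
]

# Default residual variability: 20% CV multiplicative log-normal, a typical
# bioanalytical assay precision for LC-MS/MS plasma measurements.
DEFAULT_CV = 0.2

FITTABLE_PARAMETERS = ("CL", "krel_b", "V_b")
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "CL": (0.05, 25.0),
    "krel_b": (0.001, 2.0),
    "V_b": (0.01, 5.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """One species' in-vivo study layout."""

    species: str
    dose_groups: tuple[DoseRegimen, ...]
    plasma_times: tuple[float, ...]  # h
    tissue_times: tuple[float, ...]  # h; destructive (one animal per point)
    n_per_timepoint: int = 3
    cv: float = DEFAULT_CV  # multiplicative log-normal CV
    lloq: float | None = None  # ug/mL

    def __post_init__(self) -> None:
        for ts in (self.plasma_times, self.tissue_times):
            arr = np.asarray(ts, dtype=float)
            if len(arr) and (np.any(arr < 0) or np.any(np.diff(arr) <= 0)):
                raise InvalidInputError("sampling times must be sorted, non-negative")
        if self.cv < 0:
            raise InvalidInputError("CV must be >= 0")
        if self.n_per_timepoint < 1:
            raise InvalidInputError("need at least one animal per time point")


def default_designs() -> dict[str, StudyDesign]:
    """The three preclinical nanoparticle study designs.

    Mouse: 10 mg/kg IV bolus, plasma at 20 min and 1, 6, 24, 48, 72, 96 h,
    3 animals per time point.  Rat: 55/110/505 mg/kg 30-min infusions, plasma
    at 0.5, 1, 8, 24, 72 h; liver sampled at 24 h only.  Dog: 12 mg/kg 30-min
    infusion, plasma through 120 h, liver and spleen at 1 h and 120 h.
    """
    return {
        "mouse": StudyDesign(
            species="mouse",
            dose_groups=(DoseRegimen(10.0, "bolus"),),
            plasma_times=(1 / 3, 1, 6, 24, 48, 72, 96),
            tissue_times=(1 / 3, 1, 6, 24, 48, 72, 96),
            n_per_timepoint=3,
        ),
        "rat": StudyDesign(
            species="rat",
            dose_groups=tuple(
                DoseRegimen(d, "infusion", 0.5) for d in (55.0, 110.0, 505.0)
            ),
            plasma_times=(0.5, 1, 8, 24, 72),
            tissue_times=(24.0,),
            n_per_timepoint=3,
        ),
        "dog": StudyDesign(
            species="dog",
            dose_groups=(DoseRegimen(12.0, "infusion", 0.5),),
            plasma_times=(0.5, 1, 4, 8, 24, 48, 72, 120),
            tissue_times=(1.0, 120.0),
            n_per_timepoint=2,
        ),
    }


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_dataset(
    design: StudyDesign,
    physio: SpeciesPhysiology,
    rel: ReleasedApiParams,
    conj: ConjugatedApiParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate a study and overlay measurement noise.

    Each observation is the noiseless model prediction times
    ``exp(sigma * Z)`` with ``sigma = sqrt(ln(1 + CV^2))`` (median-preserving
    log-normal error), so every uncensored value stays positive and the
    per-time-point sample CV approaches the design CV.  Values below the LLOQ
    are kept but flagged ``censored``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(design.cv)
    rows = []
    for g, regimen in enumerate(design.dose_groups):
        all_times = np.unique(
            np.concatenate(
                [np.asarray(design.plasma_times), np.asarray(design.tissue_times)]
            )
        )
        grid = np.unique(np.concatenate([[0.0], all_times]))
        course = simulate(physio, rel, conj, regimen, times=grid)
        idx = {t: i for i, t in enumerate(course.times)}
        matrix_times = {
            "plasma": design.plasma_times,
            "liver": design.tissue_times,
            "spleen": design.tissue_times,
        }
        for matrix, sample_times in matrix_times.items():
            for t in sample_times:
                for animal in range(design.n_per_timepoint):
                    subject = f"{design.species}-d{g}-t{t:g}-a{animal}"
                    for analyte in ("released", "total"):
                        pred = float(
                            course.concentration(matrix, analyte)[idx[float(t)]]
                        )
                        noise = math.exp(sigma * rng.standard_normal()) if sigma else 1.0
                        obs = pred * noise
                        rows.append(
                            {
                                "subject_id": subject,
                                "species": design.species,
                                "dose_mg_per_kg": regimen.dose,
                                "matrix": matrix,
                                "analyte": analyte,
                                "time_h": float(t),
                                "concentration_ug_per_ml": obs,
                                "censored": bool(
                                    design.lloq is not None and obs < design.lloq
                                ),
                            }
                        )
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    converged: bool
    n_starts: int
    start_objectives: list[float]
    message: str = ""


def _objective(
    log_values: np.ndarray,
    free: tuple[str, ...],
    dataset: pd.DataFrame,
    physio: SpeciesPhysiology,
    rel: ReleasedApiParams,
    conj: ConjugatedApiParams,
    rtol: float,
) -> float:
    params = dict(zip(free, np.exp(log_values)))
    rel_f = replace(rel, **{k: v for k, v in params.items() if k in ("CL", "V_b")})
    conj_f = (
        replace(conj, krel_b=params["krel_b"]) if "krel_b" in params else conj
    )
    sse = 0.0
    for (dose, matrix), grp in dataset.groupby(["dose_mg_per_kg", "matrix"]):
        regimen = grp["_regimen"].iloc[0]
        times = np.unique(grp["time_h"].to_numpy())
        grid = np.unique(np.concatenate([[0.0], times]))
        try:
            course = simulate(physio, rel_f, conj_f, regimen, times=grid, rtol=rtol,
                              atol=1e-9)
        except Exception:
            return 1e12
        idx = {t: i for i, t in enumerate(course.times)}
        for analyte, sub in grp.groupby("analyte"):
            pred = course.concentration(matrix, analyte)
            for t, obs in zip(sub["time_h"], sub["concentration_ug_per_ml"]):
                p = pred[idx[float(t)]]
                if p <= 0 or obs <= 0:
                    continue
                r = math.log(obs) - math.log(p)
                sse += r * r
    return sse


def recover_parameters(
    dataset: pd.DataFrame,
    physio: SpeciesPhysiology,
    rel: ReleasedApiParams,
    conj: ConjugatedApiParams,
    regimens: dict[float, DoseRegimen] | DoseRegimen,
    free_params: tuple[str, ...] = ("CL",),
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 5,
    rtol: float = 1e-6,
) -> FitResult:
    """Estimate free parameters by least squares on log concentrations.

    Minimises the summed squared log-residuals between simulation and the
    uncensored plasma observations (released and total) over the chosen
    subset of {CL, krel_b, V_b}, in log-parameter space with L-BFGS-B from
    ``n_starts`` seeded log-uniform starting points within the bounds.

    ``regimens`` maps dose (mg/kg) to its regimen, or is a single regimen for
    single-dose datasets.  With ``free_params=()`` the objective is evaluated
    at the nominal values and no optimisation runs.
    """
    unknown = set(free_params) - set(FITTABLE_PARAMETERS)
    if unknown:
        raise InvalidInputError(f"cannot fit parameters {sorted(unknown)}")
    data = dataset.copy()
    if "censored" in data.columns:
        data = data[~data["censored"].astype(bool)]
    data = data[data["matrix"] == "plasma"]
    if data.empty:
        raise InvalidInputError("dataset has no uncensored plasma observations")
    if isinstance(regimens, DoseRegimen):
        regimens = {d: replace(regimens, dose=float(d))
                    for d in data["dose_mg_per_kg"].unique()}
    data["_regimen"] = data["dose_mg_per_kg"].map(regimens)
    if data["_regimen"].isna().any():
        raise InvalidInputError("missing regimen for some dose group")

    if not free_params:
        obj = _objective(np.array([]), (), data, physio, rel, conj, rtol)
        return FitResult({}, obj, True, 0, [], "objective only; no optimisation")

    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    log_bounds = [tuple(np.log(bnds[p])) for p in free_params]
    rng = np.random.default_rng(seed)
    starts = [
        np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
        for _ in range(n_starts)
    ]

    best = None
    start_objs = []
    for x0 in starts:
        res = minimize(
            _objective,
            x0,
            args=(tuple(free_params), data, physio, rel, conj, rtol),
            method="L-BFGS-B",
            bounds=log_bounds,
        )
        start_objs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        return FitResult({}, float("inf"), False, n_starts, start_objs,
                         "all starts failed")
    estimates = dict(zip(free_params, np.exp(best.x)))
    return FitResult(
        estimates=estimates,
        objective=float(best.fun),
        converged=bool(best.success) or best.fun < 1e12,
        n_starts=n_starts,
        start_objectives=start_objs,
        message=str(best.message),
    )


def generate_default_dataset(species: str, seed: int, cv: float | None = None,
                             lloq: float | None = None) -> pd.DataFrame:
    """Convenience wrapper: packaged bundle + default design for one species."""
    bundle = load_species(species)
    design = default_designs()[species]
    if cv is not None:
        design = replace(design, cv=cv)
    if lloq is not None:
        design = replace(design, lloq=lloq)
    return generate_dataset(
        design, bundle.physiology, bundle.released, bundle.conjugated, seed
    )
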