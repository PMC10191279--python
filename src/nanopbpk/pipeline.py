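"""End-to-end orchestration: species runs, goodness of fit, human projection.

``run_species`` simulates a species at its configured dose/regimen across the
configured clearance values, runs NCA on the simulated profiles, and — when
an observed-data table is supplied — summarises goodness of fit as the
fraction of predictions within 3-fold of the observations (the standard
acceptance band in discovery PK).  ``project_human`` builds the human
parameter set and simulates the clinical dose, emitting dose-normalized
profiles comparable to the preclinical species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SpeciesBundle, load_species
from .model import (
    ConcentrationTimeCourse,
    ConfigurationError,
    DoseRegimen,
    InvalidInputError,
    default_time_grid,
    simulate,
)
from .nca import nca_table

__all__ = [
    "fold_error",
    "GofSummary",
    "gof_summary",
    "SpeciesRun",
    "run_species",
    "dose_normalized_overlay",
    "project_human",
    "default_regimen",
]

logger = logging.getLogger("nanopbpk")


def fold_error(observed: float, predicted: float) -> float:
    """Symmetric fold deviation: max(obs/pred, pred/obs); >= 1 by definition."""
    if observed <= 0 or predicted <= 0:
        raise InvalidInputError("fold error requires positive values")
    ratio = observed / predicted
    return max(ratio, 1.0 / ratio)


@dataclass
class GofSummary:
    """Per matrix x analyte prediction accuracy against observations."""

    table: pd.DataFrame  # matrix, analyte, n, frac_within_3fold, max_fold_error
    per_observation: pd.DataFrame  # adds fold_error per observed point
    threshold: float = 3.0

    @property
    def overall_fraction(self) -> float:
        n = self.table["n"].sum()
        return float((self.table["frac_within_3fold"] * self.table["n"]).sum() / n)


def gof_summary(
    observed: pd.DataFrame,
    course: ConcentrationTimeCourse,
    threshold: float = 3.0,
) -> GofSummary:
    """Compare observed concentrations to a simulated course.

    Predictions are interpolated log-linearly in time from the simulated
    series; observations at or below zero are skipped (nothing to compare on
    a fold scale).
    """
    per_obs_rows = []
    for (matrix, analyte), grp in observed.groupby(["matrix", "analyte"]):
        try:
            series = course.concentration(matrix, analyte)
        except InvalidInputError:
            continue
        pos = series > 0
        for _, row in grp.iterrows():
            obs = row["concentration_ug_per_ml"]
            if obs <= 0 or bool(row.get("censored", False)):
                continue
            pred = float(
                np.exp(
                    np.interp(
                        row["time_h"], course.times[pos], np.log(series[pos])
                    )
                )
            )
            per_obs_rows.append(
                {
                    "matrix": matrix,
                    "analyte": analyte,
                    "time_h": row["time_h"],
                    "observed": obs,
                    "predicted": pred,
                    "fold_error": fold_error(obs, pred),
                }
            )
    per_obs = pd.DataFrame(per_obs_rows)
    if per_obs.empty:
        raise InvalidInputError("no comparable observations for goodness of fit")
    table = (
        per_obs.groupby(["matrix", "analyte"])
        .agg(
            n=("fold_error", "size"),
            frac_within_3fold=("fold_error", lambda f: float((f <= threshold).mean())),
            max_fold_error=("fold_error", "max"),
        )
        .reset_index()
    )
    return GofSummary(table=table, per_observation=per_obs, threshold=threshold)


def default_regimen(species: str, dose: float | None = None) -> DoseRegimen:
    """Published nanoparticle regimen per species (human assumed bolus)."""
    base = {
        "mouse": DoseRegimen(10.0, "bolus"),
        "rat": DoseRegimen(55.0, "infusion", 0.5),
        "dog": DoseRegimen(12.0, "infusion", 0.5),
        "human": DoseRegimen(10.0, "bolus"),
    }
    try:
        regimen = base[species]
    except KeyError:
        raise ConfigurationError(f"no default regimen for species {species!r}")
    if dose is not None:
        regimen = replace(regimen, dose=dose)
    return regimen


@dataclass
class SpeciesRun:
    bundle: SpeciesBundle
    regimen: DoseRegimen
    profiles: dict[float, ConcentrationTimeCourse]  # keyed by CL value
    nca: pd.DataFrame
    gof: GofSummary | None


def run_species(
    species: str | SpeciesBundle,
    dose: float | None = None,
    cl_values: tuple[float, ...] | None = None,
    observed: pd.DataFrame | None = None,
    t_end: float = 120.0,
    out_dir: str | Path | None = None,
) -> SpeciesRun:
    """Simulate one species across its clearance range and summarise.

    The goodness-of-fit comparison (when observations are given) uses the
    last CL in ``cl_values``, which for the packaged configs is the in-vivo
    measured value.
    """
    bundle = species if isinstance(species, SpeciesBundle) else load_species(species)
    regimen = default_regimen(bundle.name, dose)
    cls = tuple(cl_values) if cl_values else bundle.cl_range
    times = default_time_grid(t_end)
    logger.info(
        "run_species species=%s dose=%s route=%s CL values=%s",
        bundle.name, regimen.dose, regimen.route, cls,
    )

    profiles: dict[float, ConcentrationTimeCourse] = {}
    nca_frames = []
    for cl in cls:
        rel = replace(bundle.released, CL=cl)
        course = simulate(bundle.physiology, rel, bundle.conjugated, regimen, times)
        profiles[cl] = course
        frame = course.to_frame()
        frame["subject_id"] = f"sim-CL={cl:g}"
        res = nca_table(frame)
        res.insert(0, "CL_input", cl)
        nca_frames.append(res)
    nca = pd.concat(nca_frames, ignore_index=True)

    gof = None
    if observed is not None:
        gof = gof_summary(observed, profiles[cls[-1]])

    run = SpeciesRun(bundle=bundle, regimen=regimen, profiles=profiles,
                     nca=nca, gof=gof)
    if out_dir is not None:
        _write_run(run, Path(out_dir))
    return run


def _write_run(run: SpeciesRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for cl, course in run.profiles.items():
        course.to_frame().to_csv(
            out_dir / f"{run.bundle.name}_profile_CL{cl:g}.csv",
            index=False, float_format="%.10g",
        )
    run.nca.to_csv(out_dir / f"{run.bundle.name}_nca.csv", index=False,
                   float_format="%.10g")
    summary = {
        "species": run.bundle.name,
        "dose_mg_per_kg": run.regimen.dose,
        "route": run.regimen.route,
        "cl_values": list(run.profiles),
    }
    if run.gof is not None:
        summary["gof"] = run.gof.table.to_dict(orient="records")
        run.gof.per_observation.to_csv(
            out_dir / f"{run.bundle.name}_gof.csv", index=False,
            float_format="%.10g",
        )
    with open(out_dir / f"{run.bundle.name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def dose_normalized_overlay(
    courses: list[ConcentrationTimeCourse],
) -> pd.DataFrame:
    """Merge profiles across species on a per-(mg/kg) concentration scale."""
    frames = []
    for course in courses:
        if course.regimen.dose <= 0:
            raise InvalidInputError("profile carries no positive dose")
        frame = course.to_frame()
        frame["dn_concentration"] = (
            frame["concentration_ug_per_ml"] / course.regimen.dose
        )
        frames.append(frame)
    if not frames:
        raise InvalidInputError("no profiles supplied")
    return pd.concat(frames, ignore_index=True)


def project_human(
    dose: float = 10.0,
    cl: float | None = None,
    t_end: float = 120.0,
) -> SpeciesRun:
    """Simulate the human projection (default 10 mg/kg IV bolus).

    Human clearance comes from the packaged config (hepatocyte IVIVE result)
    unless overridden.
    """
    bundle = load_species("human")
    if cl is None:
        cl = bundle.released.CL
    if cl is None or cl <= 0:
        raise ConfigurationError("human clearance unresolved")
    return run_species(bundle, dose=dose, cl_values=(cl,), t_end=t_end)
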