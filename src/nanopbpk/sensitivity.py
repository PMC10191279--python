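"""One-at-a-time local sensitivity analysis of simulated PK profiles.

Each recognised released-API parameter is multiplied by a grid of fold
factors (default 1/5, 1, 5 — a five-fold fluctuation in both directions)
with everything else held at its nominal value; the impact is summarised as
AUC fold-changes of released and total API in plasma, liver and spleen.  A
perturbation is classified *minimal* when no matrix moves beyond a threshold
(default 10% AUC change), *local* when only liver or only spleen does, and
*systemic* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ConcentrationTimeCourse,
    ConjugatedApiParams,
    DoseRegimen,
    InvalidInputError,
    ReleasedApiParams,
    SpeciesPhysiology,
    simulate,
    with_parameter,
)
from .nca import auc_trapezoid

__all__ = ["SENSITIVITY_PARAMETERS", "SensitivityResult", "oat_sensitivity",
           "classify_sensitivity"]

SENSITIVITY_PARAMETERS = (
    "CL", "V_b", "Q_BR", "V_R",
    "Bmax_L", "KD_L", "P_L", "Bmax_S", "KD_S", "P_S",
)

TISSUE_MATRICES = ("plasma", "liver", "spleen")
DEFAULT_FOLDS = (0.2, 1.0, 5.0)


@dataclass
class SensitivityResult:
    parameter: str
    folds: tuple[float, ...]
    nominal_value: float
    profiles: dict[float, ConcentrationTimeCourse]
    auc: pd.DataFrame  # columns: fold, matrix, analyte, AUC, fold_change

    def fold_change(self, matrix: str, analyte: str, fold: float) -> float:
        sel = self.auc[
            (self.auc["matrix"] == matrix)
            & (self.auc["analyte"] == analyte)
            & (self.auc["fold"] == fold)
        ]
        if sel.empty:
            raise InvalidInputError(
                f"no AUC entry for {matrix}/{analyte} at fold {fold}"
            )
        return float(sel["fold_change"].iloc[0])

    def max_abs_change(self, analyte: str, matrix: str) -> float:
        """max over folds of |AUC fold-change - 1| for one matrix."""
        sel = self.auc[
            (self.auc["matrix"] == matrix) & (self.auc["analyte"] == analyte)
        ]
        return float((sel["fold_change"] - 1.0).abs().max())


def oat_sensitivity(
    physio: SpeciesPhysiology,
    rel: ReleasedApiParams,
    conj: ConjugatedApiParams,
    regimen: DoseRegimen,
    parameter: str,
    folds: tuple[float, ...] = DEFAULT_FOLDS,
    times: np.ndarray | None = None,
) -> SensitivityResult:
    """Simulate with one parameter multiplied by each fold factor.

    Fold 1 is always included as the reference; AUC fold-changes are relative
    to it.  The fold-1 run reuses the unmodified parameter bundle, so it is
    bit-identical to the nominal simulation.
    """
    if parameter not in SENSITIVITY_PARAMETERS:
        raise InvalidInputError(
            f"unknown sensitivity parameter {parameter!r}; "
            f"expected one of {SENSITIVITY_PARAMETERS}"
        )
    if any(f <= 0 for f in folds):
        raise InvalidInputError("fold factors must be positive")
    folds = tuple(sorted(set(folds) | {1.0}))
    nominal_value = getattr(rel, parameter)

    profiles: dict[float, ConcentrationTimeCourse] = {}
    rows = []
    for fold in folds:
        rel_f = rel if fold == 1.0 else with_parameter(rel, parameter, nominal_value * fold)
        course = simulate(physio, rel_f, conj, regimen, times=times)
        profiles[fold] = course
        for matrix in TISSUE_MATRICES:
            for analyte in ("released", "total"):
                rows.append(
                    {
                        "parameter": parameter,
                        "fold": fold,
                        "matrix": matrix,
                        "analyte": analyte,
                        "AUC": auc_trapezoid(
                            course.times, course.concentration(matrix, analyte),
                            method="linear",
                        ),
                    }
                )
    auc = pd.DataFrame(rows)
    ref = auc[auc["fold"] == 1.0].set_index(["matrix", "analyte"])["AUC"]
    auc["fold_change"] = auc.apply(
        lambda r: r["AUC"] / ref.loc[(r["matrix"], r["analyte"])], axis=1
    )
    return SensitivityResult(
        parameter=parameter,
        folds=folds,
        nominal_value=nominal_value,
        profiles=profiles,
        auc=auc,
    )


def classify_sensitivity(
    result: SensitivityResult,
    threshold_pct: float = 10.0,
    analyte: str = "released",
) -> str:
    """Label a perturbation minimal / local / systemic from its AUC changes.

    *minimal*: every matrix stays within the threshold; *local*: only liver
    or only spleen exceeds it; *systemic*: plasma moves, or several tissues do.
    """
    thr = threshold_pct / 100.0
    exceeded = {
        m for m in TISSUE_MATRICES if result.max_abs_change(analyte, m) >= thr
    }
    if not exceeded:
        return "minimal"
    if exceeded in ({"liver"}, {"spleen"}):
        return "local"
    return "systemic"
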