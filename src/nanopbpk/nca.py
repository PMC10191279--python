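"""Non-compartmental analysis of concentration-time profiles.

Model-free PK metrics: trapezoidal AUC (linear or linear-up/log-down),
terminal half-life from a log-linear regression over an automatically
selected terminal window, clearance as dose/AUC, back-extrapolated C0 for
bolus profiles, through-origin dose-proportionality slopes and relative
exposure between formulations.

Units follow the tidy CSV dialect used across the package: time in h,
concentration in ug/mL (= mg/L), dose in mg/kg, so dose/AUC is L/h/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import InvalidInputError

__all__ = [
    "NcaResult",
    "auc_trapezoid",
    "terminal_half_life",
    "clearance",
    "c0_extrapolate",
    "dose_proportionality_slope",
    "relative_exposure",
    "nca_profile",
    "nca_table",
]

MIN_TERMINAL_POINTS = 3
MIN_TERMINAL_R2 = 0.8


@dataclass(frozen=True)
class HalfLifeEstimate:
    half_life: float  # h; NaN when not estimable
    lambda_z: float  # 1/h
    n_points: int
    r_squared: float
    reliable: bool
    reason: str = ""

    @property
    def estimable(self) -> bool:
        return math.isfinite(self.half_life)


@dataclass(frozen=True)
class NcaResult:
    """Per-profile NCA summary (one subject x matrix x analyte)."""

    dose: float  # mg/kg
    AUC_last: float  # ug/mL*h
    AUC_inf: float | None
    half_life: float  # h, NaN if not estimable
    half_life_reliable: bool
    CL: float  # L/h/kg, dose / AUC_last
    C0: float | None  # ug/mL, bolus back-extrapolation
    dose_normalized_AUC: float  # (ug/mL*h) / (mg/kg)


def _validate_profile(times, concentrations) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or c.shape != t.shape:
        raise InvalidInputError("times and concentrations must be 1-D and aligned")
    if len(t) < 2:
        raise InvalidInputError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise InvalidInputError("concentrations must be finite and non-negative")
    return t, c


def auc_trapezoid(times, concentrations, method: str = "linuplogdown") -> float:
    """AUC to the last time point by the trapezoidal rule.

    ``linear`` uses plain trapezoids throughout; ``linuplogdown`` switches to
    logarithmic trapezoids on declining segments with two positive endpoints
    (the standard choice for post-peak mono-exponential decline).
    """
    if method not in ("linear", "linuplogdown"):
        raise InvalidInputError(f"unknown AUC method {method!r}")
    t, c = _validate_profile(times, concentrations)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = dt * (c1 + c2) / 2.0
    if method == "linear":
        return float(linear.sum())
    segs = linear.copy()
    logdown = (c2 < c1) & (c2 > 0)
    segs[logdown] = (
        dt[logdown] * (c1[logdown] - c2[logdown]) / np.log(c1[logdown] / c2[logdown])
    )
    return float(segs.sum())


def terminal_half_life(times, concentrations) -> HalfLifeEstimate:
    """ln2 / lambda_z from a log-linear fit over the terminal points.

    The terminal window is the suffix of >=3 positive-concentration points
    (starting after the observed peak) whose log-linear fit maximises the
    adjusted R^2; a best fit under R^2 = 0.8 or a non-negative slope is
    flagged unreliable / not estimable.
    """
    t, c = _validate_profile(times, concentrations)
    positive = c > 0
    t_pos, c_pos = t[positive], c[positive]
    if len(t_pos) < MIN_TERMINAL_POINTS:
        return HalfLifeEstimate(
            float("nan"), float("nan"), 0, float("nan"), False,
            "fewer than 3 positive terminal points",
        )
    i_peak = int(np.argmax(c_pos))
    # candidate suffixes start after the peak where possible
    first_start = min(i_peak + 1, len(t_pos) - MIN_TERMINAL_POINTS)
    log_c = np.log(c_pos)
    best: tuple[float, float, int, float] | None = None  # adj_r2, slope, n, r2
    for start in range(first_start, len(t_pos) - MIN_TERMINAL_POINTS + 1):
        tt, yy = t_pos[start:], log_c[start:]
        n = len(tt)
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot == 0:
            continue  # flat segment: no decline to fit
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0]:
            best = (adj, float(slope), n, r2)
    if best is None or best[1] >= 0:
        return HalfLifeEstimate(
            float("nan"), float("nan"), 0, float("nan"), False,
            "no declining terminal phase",
        )
    _, slope, n, r2 = best
    lam = -slope
    return HalfLifeEstimate(
        half_life=math.log(2) / lam,
        lambda_z=lam,
        n_points=n,
        r_squared=r2,
        reliable=r2 >= MIN_TERMINAL_R2,
        reason="" if r2 >= MIN_TERMINAL_R2 else f"terminal R^2 {r2:.3f} < 0.8",
    )


def clearance(dose: float, auc: float) -> float:
    """CL = dose / AUC; mg/kg over ug/mL*h (= mg*h/L) gives L/h/kg."""
    if auc <= 0:
        raise InvalidInputError("AUC must be positive")
    if dose <= 0:
        raise InvalidInputError("dose must be positive")
    return dose / auc


def c0_extrapolate(times, concentrations) -> float | None:
    """Back-extrapolated concentration at t = 0 after an IV bolus.

    Log-linear extrapolation through the first two positive observations;
    None when the profile does not decline between them.
    """
    t, c = _validate_profile(times, concentrations)
    pos = np.flatnonzero(c > 0)
    if len(pos) < 2:
        return None
    i, j = pos[0], pos[1]
    if c[j] >= c[i]:
        return None
    slope = (math.log(c[j]) - math.log(c[i])) / (t[j] - t[i])
    return float(math.exp(math.log(c[i]) - slope * t[i]))


def dose_proportionality_slope(doses, aucs) -> float:
    """Least-squares slope of AUC vs dose constrained through the origin:
    slope = sum(d*AUC) / sum(d^2), in ug/mL*h per mg/kg."""
    d = np.asarray(doses, dtype=float)
    a = np.asarray(aucs, dtype=float)
    if d.shape != a.shape or d.ndim != 1 or len(d) < 1:
        raise InvalidInputError("doses and AUCs must be aligned 1-D arrays")
    denom = float(np.sum(d**2))
    if denom == 0:
        raise InvalidInputError("all doses are zero")
    return float(np.sum(d * a)) / denom


def relative_exposure(released_dnauc: float, unconjugated_dnauc: float) -> float:
    """Dose-normalized exposure of nanoparticle-released API relative to the
    conventional (unconjugated) formulation, as a percentage."""
    if unconjugated_dnauc <= 0:
        raise InvalidInputError("unconjugated dose-normalized AUC must be positive")
    if released_dnauc <= 0:
        raise InvalidInputError("released dose-normalized AUC must be positive")
    return 100.0 * released_dnauc / unconjugated_dnauc


def nca_profile(
    times,
    concentrations,
    dose: float,
    route: str = "bolus",
    auc_method: str = "linuplogdown",
) -> NcaResult:
    """Full NCA of one profile: AUC_last (used for CL), AUC_inf when the
    terminal phase is estimable, half-life, CL and dose-normalized AUC."""
    t, c = _validate_profile(times, concentrations)
    if np.count_nonzero(c > 0) < 2:
        raise InvalidInputError("profile needs at least two positive concentrations")
    auc_last = auc_trapezoid(t, c, auc_method)
    hl = terminal_half_life(t, c)
    auc_inf = None
    if hl.estimable:
        c_last = c[c > 0][-1]
        auc_inf = auc_last + float(c_last) / hl.lambda_z
    c0 = c0_extrapolate(t, c) if route == "bolus" else None
    return NcaResult(
        dose=dose,
        AUC_last=auc_last,
        AUC_inf=auc_inf,
        half_life=hl.half_life,
        half_life_reliable=hl.reliable,
        CL=clearance(dose, auc_last),
        C0=c0,
        dose_normalized_AUC=auc_last / dose,
    )


def nca_table(data: pd.DataFrame, auc_method: str = "linuplogdown") -> pd.DataFrame:
    """NCA report over a tidy concentration table.

    Expects columns subject_id, species, matrix, analyte, time_h,
    concentration_ug_per_ml, dose_mg_per_kg (the CSV dialect emitted by the
    simulator and the synthetic-study generator); censored rows (column
    ``censored`` truthy) are dropped.  Returns one row per
    subject x matrix x analyte.
    """
    required = {
        "species", "matrix", "analyte", "time_h",
        "concentration_ug_per_ml", "dose_mg_per_kg",
    }
    missing = required - set(data.columns)
    if missing:
        raise InvalidInputError(f"concentration table lacks columns {sorted(missing)}")
    df = data.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    if "subject_id" not in df.columns:
        df["subject_id"] = "profile"
    rows = []
    keys = ["species", "subject_id", "dose_mg_per_kg", "matrix", "analyte"]
    for (species, subject, dose, matrix, analyte), grp in df.groupby(keys):
        grp = grp.sort_values("time_h")
        grp = grp.groupby("time_h", as_index=False)["concentration_ug_per_ml"].mean()
        if len(grp) < 2 or (grp["concentration_ug_per_ml"] > 0).sum() < 2:
            continue
        res = nca_profile(
            grp["time_h"].to_numpy(),
            grp["concentration_ug_per_ml"].to_numpy(),
            dose=float(dose),
            auc_method=auc_method,
        )
        rows.append(
            {
                "species": species,
                "subject_id": subject,
                "matrix": matrix,
                "analyte": analyte,
                "dose_mg_per_kg": res.dose,
                "AUC_last": res.AUC_last,
                "AUC_inf": res.AUC_inf,
                "half_life_h": res.half_life,
                "half_life_reliable": res.half_life_reliable,
                "CL_L_h_kg": res.CL,
                "dose_normalized_AUC": res.dose_normalized_AUC,
            }
        )
    return pd.DataFrame(rows)
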