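"""Non-compartmental analysis (NCA).

Model-free PK parameters from a concentration-time profile: linear
trapezoidal AUC, terminal log-linear regression for lambda_z (best
adjusted-r2 over all suffixes of >= 3 post-Cmax points, ties broken toward
more points), AUC/AUMC extrapolation to infinity, MRT, clearance and
volumes, and relative bioavailability between formulations.

BLQ policy: records below the LLOQ that precede the first quantifiable
observation are set to 0; embedded and trailing BLQ records are excluded.
Both choices are the common NCA defaults and are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SubjectDataset
from .structural import ROUTE_IV, ConcentrationProfile

__all__ = [
    "NCAError",
    "LambdaZFit",
    "NCAResult",
    "auc_trapezoid",
    "fit_lambda_z",
    "nca_subject",
    "relative_bioavailability",
    "nca_group_summary",
]


class NCAError(ValueError):
    """Raised for NCA inputs that cannot be analysed."""


def auc_trapezoid(profile: ConcentrationProfile, t_start: float | None = None,
                  t_end: float | None = None) -> float:
    """Linear-trapezoidal AUC over the observed points in [t_start, t_end]."""
    t, c = profile.times, profile.values
    if t_start is not None or t_end is not None:
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        m = (t >= lo) & (t <= hi)
        t, c = t[m], c[m]
    if t.size < 2:
        raise NCAError("AUC needs at least 2 points in the requested window")
    return float(np.trapezoid(c, t))


def _aumc_trapezoid(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(t * c, t))


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float
    r2_adj: float
    n_points: int
    ok: bool

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.lambda_z if self.ok else math.nan


def fit_lambda_z(profile: ConcentrationProfile) -> LambdaZFit:
    """Terminal elimination rate constant by log-linear least squares.

    Candidate point sets are the suffixes of the strictly-post-Cmax
    positive observations; the suffix with the best adjusted r2 wins,
    with ties going to the longer suffix.  A fit with a non-negative
    slope is rejected; if no suffix yields lambda_z > 0 the result is
    flagged (``ok=False``) and infinity-extrapolated quantities are
    omitted downstream.
    """
    t, c = profile.times, profile.values
    imax = int(np.argmax(c))
    t, c = t[imax + 1:], c[imax + 1:]
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 3:
        return LambdaZFit(math.nan, math.nan, 0, False)
    logc = np.log(c)
    best: tuple[float, int, float] | None = None  # (r2_adj, n, lambda_z)
    for start in range(t.size - 2):
        ts, ys = t[start:], logc[start:]
        n = ts.size
        slope, intercept = np.polyfit(ts, ys, 1)
        if slope >= 0:
            continue
        resid = ys - (slope * ts + intercept)
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        # ties (to 1e-10) go to the suffix with more points; suffixes are
        # scanned longest-first, so strictly-better is required to switch
        if best is None or r2_adj > best[0] + 1e-10:
            best = (r2_adj, n, -slope)
    if best is None:
        return LambdaZFit(math.nan, math.nan, 0, False)
    r2_adj, n, lz = best
    return LambdaZFit(float(lz), float(r2_adj), int(n), True)


@dataclass(frozen=True)
class NCAResult:
    """Per-subject NCA parameter set (units as in the package convention:
    ng.h/mL, 1/h, h, L/h/kg, L/kg)."""

    subject_id: int
    group: int
    route: str
    dose: float
    auc0_last: float
    auc0_inf: float
    pct_extrapolated: float
    lambda_z: float
    t_half: float
    cmax: float
    tmax: float
    mrt: float
    cl: float            # Cl (IV) or Cl/F (oral), L/h/kg
    vdss: float          # IV only; NaN for oral
    vdz: float           # Vdz (IV) or Vdz/F (oral), L/kg
    auc_over_dose: float  # (ng.h/mL)/(mg/kg)
    n_lambda_points: int
    r2_adj: float
    extrapolation_flag: bool  # True when > 20% of AUC0-INF is extrapolated


def _quantifiable_profile(subject: SubjectDataset, blq_policy: str) -> ConcentrationProfile:
    """Apply the BLQ policy and return the analysable profile."""
    if blq_policy not in ("leading-zero", "exclude-all"):
        raise NCAError(f"unknown BLQ policy {blq_policy!r}")
    t, dv, blq = subject.times, subject.dv, subject.blq
    quant_idx = np.flatnonzero(~blq)
    if quant_idx.size == 0:
        raise NCAError(f"subject {subject.subject_id} has no quantifiable observations")
    first = quant_idx[0]
    keep_t, keep_c = [], []
    for i in range(t.size):
        if not blq[i]:
            keep_t.append(t[i]); keep_c.append(dv[i])
        elif blq_policy == "leading-zero" and i < first:
            keep_t.append(t[i]); keep_c.append(0.0)
        # embedded/trailing BLQ: excluded
    return ConcentrationProfile(times=np.array(keep_t), values=np.array(keep_c))


def nca_subject(subject: SubjectDataset, blq_policy: str = "leading-zero") -> NCAResult:
    """Full NCA for one subject.

    AUC0-INF = AUC0-last + C_last/lambda_z; AUMC tail is
    C_last*(t_last/lambda_z + 1/lambda_z^2); MRT = AUMC0-INF/AUC0-INF;
    Cl (= 1000*dose/AUC0-INF) and Vdz = Cl/lambda_z are apparent (over F)
    after oral dosing; Vdss = Cl*MRT is reported for IV only.  Cmax/Tmax is
    the global maximum (double peaks allowed).
    """
    if subject.dose.amount <= 0:
        raise NCAError("NCA requires a positive dose")
    profile = _quantifiable_profile(subject, blq_policy)
    n_quant = int(np.sum(~subject.blq))
    if n_quant < 3:
        raise NCAError(f"subject {subject.subject_id} has fewer than 3 quantifiable points")
    t, c = profile.times, profile.values
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = auc_trapezoid(profile)
    lz = fit_lambda_z(profile)
    dose = subject.dose.amount
    if lz.ok:
        c_last, t_last = float(c[-1]), float(t[-1])
        auc_inf = auc_last + c_last / lz.lambda_z
        aumc_inf = (_aumc_trapezoid(t, c)
                    + c_last * (t_last / lz.lambda_z + 1.0 / lz.lambda_z ** 2))
        mrt = aumc_inf / auc_inf
        cl = 1000.0 * dose / auc_inf
        vdz = cl / lz.lambda_z
        vdss = cl * mrt if subject.dose.route == ROUTE_IV else math.nan
        pct_extrap = 100.0 * (auc_inf - auc_last) / auc_inf
    else:
        auc_inf = aumc_inf = mrt = cl = vdz = vdss = pct_extrap = math.nan
    return NCAResult(
        subject_id=subject.subject_id,
        group=subject.group,
        route=subject.dose.route,
        dose=dose,
        auc0_last=auc_last,
        auc0_inf=auc_inf,
        pct_extrapolated=pct_extrap,
        lambda_z=lz.lambda_z,
        t_half=lz.t_half,
        cmax=cmax,
        tmax=tmax,
        mrt=mrt,
        cl=cl,
        vdss=vdss,
        vdz=vdz,
        auc_over_dose=auc_inf / dose,
        n_lambda_points=lz.n_points,
        r2_adj=lz.r2_adj,
        extrapolation_flag=bool(lz.ok and pct_extrap > 20.0),
    )


def relative_bioavailability(auc_test: float, dose_test: float,
                             auc_ref: float, dose_ref: float) -> float:
    """Dose-normalised AUC ratio of a test formulation to a reference:
    Frel = (AUC_test/AUC_ref) * (dose_ref/dose_test).  Extract doses enter
    as rutin equivalents."""
    for name, v in (("auc_test", auc_test), ("dose_test", dose_test),
                    ("auc_ref", auc_ref), ("dose_ref", dose_ref)):
        if not np.isfinite(v) or v <= 0:
            raise NCAError(f"{name} must be positive and finite, got {v!r}")
    return (auc_test / auc_ref) * (dose_ref / dose_test)


_SUMMARY_FIELDS = ("auc0_last", "auc0_inf", "pct_extrapolated", "lambda_z",
                   "t_half", "cmax", "tmax", "mrt", "cl", "vdss", "vdz",
                   "auc_over_dose")


def nca_group_summary(results: list[NCAResult]) -> pd.DataFrame:
    """Arithmetic mean +/- sample SD per parameter (SD reported as 0 with an
    n=1 flag for singleton groups); AUC/dose is computed per subject and
    then averaged."""
    if not results:
        raise NCAError("at least one NCA result is required")
    rows = []
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(np.mean(vals)) if n else math.nan
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append({"parameter": name, "mean": mean, "sd": sd, "n": n,
                     "single_subject": n == 1})
    return pd.DataFrame(rows).set_index("parameter")
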