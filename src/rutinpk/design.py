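"""Synthetic rat studies with the published trial design.

The design comprises 10 groups of 5 rats: pure rutin IV (1.45, 2.9 mg/kg),
pure rutin oral (75, 100 mg/kg), calyx-extract IV (250, 500, 1000 mg/kg)
and calyx-extract oral (500, 750, 1000 mg/kg).  Extract groups are dosed,
in the model, with the rutin-equivalent amount (extract dose x 14.8 ug/mg
rutin content); the extract matrix acts purely through the covariate betas.

Sampling is 0-12 h (14 points) for IV and 0-24 h (14 points) for oral;
concentrations below the assay's lower limit of quantification
(LLOQ = 100 ng/mL) are emitted as flagged BLQ records rather than dropped,
so downstream censoring policies stay testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .population import PopulationModel
from .structural import (
    ROUTE_IV,
    ROUTE_ORAL,
    DoseEvent,
    iv_conc,
    oral_conc,
)

__all__ = [
    "RUTIN_CONTENT",
    "IV_SAMPLING_TIMES",
    "ORAL_SAMPLING_TIMES",
    "StudyGroup",
    "StudyDesign",
    "SubjectDataset",
    "default_design",
    "simulate_study",
]

#: rutin content of the calyx extract, mg rutin per mg extract (14.8 ug/mg)
RUTIN_CONTENT = 0.0148

IV_SAMPLING_TIMES = (0.0, 0.05, 0.166, 0.333, 0.5, 0.75, 1.0, 1.5, 2.0,
                     3.0, 4.0, 6.0, 8.0, 12.0)
#: the 0.30 h point is kept exactly as specified in the sampling protocol
ORAL_SAMPLING_TIMES = (0.0, 0.083, 0.25, 0.30, 0.75, 1.0, 2.0, 3.0, 4.0,
                       6.0, 8.0, 10.0, 12.0, 24.0)


class DesignError(ValueError):
    """Raised for invalid study designs or design/model mismatches."""


@dataclass(frozen=True)
class StudyGroup:
    """One intervention arm: group number, label, route, source (RU = pure
    rutin, HEE = hydroalcoholic extract), administered dose, the
    rutin-equivalent dose actually entering the model, the covariate level,
    and the number of rats."""

    number: int
    label: str
    route: str
    source: str
    admin_dose: float
    rutin_eq_dose: float
    level: str
    n: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DesignError("each group needs at least one rat")
        if self.route not in (ROUTE_IV, ROUTE_ORAL):
            raise DesignError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Groups plus per-route sampling schedules and the LLOQ (ng/mL)."""

    groups: tuple[StudyGroup, ...]
    iv_times: tuple[float, ...] = IV_SAMPLING_TIMES
    oral_times: tuple[float, ...] = ORAL_SAMPLING_TIMES
    lloq: float = 100.0

    def __post_init__(self) -> None:
        for times in (self.iv_times, self.oral_times):
            if np.any(np.diff(times) <= 0):
                raise DesignError("sampling schedules must be strictly increasing")
        if self.lloq < 0:
            raise DesignError("LLOQ must be >= 0")

    def times_for(self, route: str) -> np.ndarray:
        return np.asarray(self.iv_times if route == ROUTE_IV else self.oral_times)

    def subset(self, routes=None, groups=None) -> "StudyDesign":
        """Restrict to given routes and/or group numbers."""
        keep = tuple(
            g for g in self.groups
            if (routes is None or g.route in routes)
            and (groups is None or g.number in groups)
        )
        if not keep:
            raise DesignError("subset selects no groups")
        return replace(self, groups=keep)


@dataclass(frozen=True)
class SubjectDataset:
    """Longitudinal record for one rat: dosing event plus the observation
    stream (time h, DV ng/mL with NaN where BLQ, BLQ flags)."""

    subject_id: int
    group: int
    source: str
    level: str
    dose: DoseEvent
    times: np.ndarray
    dv: np.ndarray
    blq: np.ndarray
    lloq: float = 100.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dv = np.asarray(self.dv, dtype=float)
        blq = np.asarray(self.blq, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dv", dv)
        object.__setattr__(self, "blq", blq)
        if not (times.shape == dv.shape == blq.shape):
            raise DesignError("times, dv and blq must have equal shapes")
        if times.size == 0:
            raise DesignError(f"subject {self.subject_id} has no observations")
        if np.any(np.diff(times) <= 0):
            raise DesignError("observation times must be strictly increasing")
        if np.any(~blq & ~np.isfinite(dv)):
            raise DesignError("non-BLQ observations must carry a numeric DV")
        if np.any(~blq & (dv < self.lloq)):
            raise DesignError("numeric DV below the LLOQ must be flagged BLQ")

    @property
    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of the non-BLQ observations."""
        m = ~self.blq
        return self.times[m], self.dv[m]


def default_design() -> StudyDesign:
    """The 10-group, 5-rats-per-group rat study design."""
    def ext(dose):  # rutin equivalent of an extract dose
        return round(dose * RUTIN_CONTENT, 4)

    groups = (
        StudyGroup(1, "pure rutin 1.45 mg/kg i.v.", ROUTE_IV, "RU", 1.45, 1.45, "RU"),
        StudyGroup(2, "pure rutin 2.9 mg/kg i.v.", ROUTE_IV, "RU", 2.9, 2.9, "RU"),
        StudyGroup(3, "pure rutin 75 mg/kg p.o.", ROUTE_ORAL, "RU", 75.0, 75.0, "D75"),
        StudyGroup(4, "pure rutin 100 mg/kg p.o.", ROUTE_ORAL, "RU", 100.0, 100.0, "D100"),
        StudyGroup(5, "extract 250 mg/kg i.v.", ROUTE_IV, "HEE", 250.0, ext(250.0), "GEXT"),
        StudyGroup(6, "extract 500 mg/kg i.v.", ROUTE_IV, "HEE", 500.0, ext(500.0), "GEXT"),
        StudyGroup(7, "extract 1000 mg/kg i.v.", ROUTE_IV, "HEE", 1000.0, ext(1000.0), "GEXT"),
        StudyGroup(8, "extract 500 mg/kg p.o.", ROUTE_ORAL, "HEE", 500.0, ext(500.0), "D500"),
        StudyGroup(9, "extract 750 mg/kg p.o.", ROUTE_ORAL, "HEE", 750.0, ext(750.0), "D750"),
        StudyGroup(10, "extract 1000 mg/kg p.o.", ROUTE_ORAL, "HEE", 1000.0, ext(1000.0), "D1000"),
    )
    return StudyDesign(groups=groups)


def _group_profiles(group: StudyGroup, pop: PopulationModel, times: np.ndarray,
                    etas: np.ndarray) -> np.ndarray:
    """Noise-free profiles (n, T) for every rat in a group."""
    n = etas.shape[0]
    profiles = np.empty((n, times.size))
    for i in range(n):
        params = pop.individual_parameters(group.level, etas[i])
        if pop.structural == "iv":
            profiles[i] = iv_conc(params.V, params.k, params.k12, params.k21,
                                  group.rutin_eq_dose, times)
        else:
            profiles[i] = oral_conc(params.ka1, params.ka2, params.F1, params.Tlag2,
                                    params.V, params.k, params.k12, params.k21,
                                    group.rutin_eq_dose, times)
    return np.maximum(profiles, 0.0)


def simulate_study(design: StudyDesign, pop_iv: PopulationModel | None,
                   pop_oral: PopulationModel | None, seed) -> list[SubjectDataset]:
    """Simulate every rat of a study design.

    Per rat: draw eta, form individual parameters at the rat's covariate
    level, evaluate the profile at the scheduled times, add combined
    residual noise, and flag values below the LLOQ as BLQ.  Fully
    reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectDataset] = []
    sid = 0
    for group in design.groups:
        pop = pop_iv if group.route == ROUTE_IV else pop_oral
        if pop is None:
            raise DesignError(f"no population model supplied for route {group.route!r}")
        if (pop.structural == "iv") != (group.route == ROUTE_IV):
            raise DesignError(
                f"group {group.number} has route {group.route!r} but the model "
                f"is {pop.structural!r}"
            )
        if group.level not in pop.levels:
            raise DesignError(
                f"group {group.number} level {group.level!r} is not declared in the "
                f"model (levels: {list(pop.levels)})"
            )
        times = design.times_for(group.route)
        etas = pop.sample_etas(group.n, rng)
        profiles = _group_profiles(group, pop, times, etas)
        eps = rng.standard_normal(profiles.shape)
        y = profiles + pop.error.sd(profiles) * eps
        blq = y < design.lloq
        dv = np.where(blq, np.nan, y)
        for i in range(group.n):
            sid += 1
            subjects.append(SubjectDataset(
                subject_id=sid,
                group=group.number,
                source=group.source,
                level=group.level,
                dose=DoseEvent(route=group.route, amount=group.rutin_eq_dose),
                times=times.copy(),
                dv=dv[i],
                blq=blq[i],
                lloq=design.lloq,
            ))
    return subjects
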