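"""Dataset and configuration I/O.

The dataset dialect is a NONMEM-style longitudinal CSV with header
``ID,TIME,DV,BLQ,AMT,ROUTE,SOURCE,DOSEGRP,GROUP``: one dose row per subject
at TIME 0 (AMT set, DV empty) followed by observation rows carrying either
a numeric DV or BLQ=1, never both.  Times are hours, DV is ng/mL, AMT is
mg/kg rutin-equivalent, ROUTE is ``iv``/``oral``, SOURCE is ``RU``/``HEE``,
DOSEGRP is the covariate level and GROUP the study group number.

Run configuration is a flat INI file (sections ``model``, ``estimation``,
``design``, ``output``) read with :mod:`configparser`; no code-bearing
config.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SubjectDataset
from .structural import ROUTE_IV, ROUTE_ORAL, DoseEvent

__all__ = [
    "DATASET_COLUMNS",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "dataset_fingerprint",
    "RunConfig",
    "read_config",
    "write_config",
]

DATASET_COLUMNS = ("ID", "TIME", "DV", "BLQ", "AMT", "ROUTE", "SOURCE",
                   "DOSEGRP", "GROUP")

_ROUTE_TO_CSV = {ROUTE_IV: "iv", ROUTE_ORAL: "oral"}
_CSV_TO_ROUTE = {"iv": ROUTE_IV, "oral": ROUTE_ORAL}


class DatasetError(ValueError):
    """Raised for malformed dataset files."""


def write_dataset(subjects: list[SubjectDataset], path) -> None:
    """Write subjects in the dataset CSV dialect (dose row first, then
    observations in time order; full float precision)."""
    lines = [",".join(DATASET_COLUMNS)]
    for s in subjects:
        route = _ROUTE_TO_CSV[s.dose.route]
        lines.append(
            f"{s.subject_id},{float(s.dose.time)!r},,0,{float(s.dose.amount)!r},"
            f"{route},{s.source},{s.level},{s.group}"
        )
        for t, dv, blq in zip(s.times, s.dv, s.blq):
            dv_str = "" if blq else repr(float(dv))
            lines.append(
                f"{s.subject_id},{float(t)!r},{dv_str},{int(blq)},,"
                f"{route},{s.source},{s.level},{s.group}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dataset(path, lloq: float = 100.0) -> list[SubjectDataset]:
    """Parse a dataset CSV into validated subjects (times sorted).

    Round-trips with :func:`write_dataset` to an equal in-memory structure.
    Raises :class:`DatasetError` naming unknown columns, and row-level
    errors (with line numbers) when DV and BLQ are both set.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in DATASET_COLUMNS]
    if unknown:
        raise DatasetError(f"unknown column(s) {unknown}; expected {list(DATASET_COLUMNS)}")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s) {missing}")

    subjects: list[SubjectDataset] = []
    for sid, sub in df.groupby("ID", sort=False):
        dose_rows = sub[sub["AMT"] != ""]
        if len(dose_rows) != 1:
            raise DatasetError(f"subject {sid}: expected exactly one dose row, "
                               f"found {len(dose_rows)}")
        drow = dose_rows.iloc[0]
        if float(drow["TIME"]) != 0.0:
            raise DatasetError(f"subject {sid}: dose row must be at TIME 0")
        route = _CSV_TO_ROUTE.get(drow["ROUTE"])
        if route is None:
            raise DatasetError(f"subject {sid}: unknown ROUTE {drow['ROUTE']!r}")
        obs = sub[sub["AMT"] == ""]
        if obs.empty:
            raise DatasetError(f"subject {sid}: no observation rows")
        times, dv, blq = [], [], []
        for idx, row in obs.iterrows():
            line_no = idx + 2  # header is line 1
            has_dv = row["DV"] != ""
            is_blq = row["BLQ"] == "1"
            if has_dv and is_blq:
                raise DatasetError(f"line {line_no}: DV and BLQ=1 are mutually exclusive")
            if not has_dv and not is_blq:
                raise DatasetError(f"line {line_no}: observation needs DV or BLQ=1")
            times.append(float(row["TIME"]))
            dv.append(float(row["DV"]) if has_dv else np.nan)
            blq.append(is_blq)
        order = np.argsort(times, kind="stable")
        subjects.append(SubjectDataset(
            subject_id=int(sid),
            group=int(drow["GROUP"]),
            source=drow["SOURCE"],
            level=drow["DOSEGRP"],
            dose=DoseEvent(route=route, amount=float(drow["AMT"]),
                           time=float(drow["TIME"])),
            times=np.asarray(times)[order],
            dv=np.asarray(dv)[order],
            blq=np.asarray(blq)[order],
            lloq=lloq,
        ))
    if not subjects:
        raise DatasetError("dataset contains no subjects")
    return subjects


def dataset_fingerprint(subjects: list[SubjectDataset]) -> str:
    """Stable content hash of a dataset (used to guard model comparisons)."""
    h = hashlib.sha256()
    for s in sorted(subjects, key=lambda s: s.subject_id):
        h.update(str(s.subject_id).encode())
        h.update(s.level.encode())
        h.update(np.ascontiguousarray(s.times).tobytes())
        h.update(np.ascontiguousarray(np.nan_to_num(s.dv, nan=-1.0)).tobytes())
        h.update(np.ascontiguousarray(s.blq).tobytes())
        h.update(repr(s.dose.amount).encode())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Flat key/value run configuration."""

    model: str = "iv"                 # structural model: iv | oral
    error_form: str = "linear"        # residual form: linear | quadratic
    blq_policy: str = "exclude"       # estimation BLQ handling: exclude | censored
    n_burn: int = 300
    n_smooth: int = 200
    mh_steps: int = 5
    n_is: int = 500
    n_sim: int = 1000                 # VPC replicates
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)


def read_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    cfg = RunConfig()
    if cp.has_section("model"):
        cfg.model = cp.get("model", "structural", fallback=cfg.model)
        cfg.error_form = cp.get("model", "error_form", fallback=cfg.error_form)
        cfg.blq_policy = cp.get("model", "blq_policy", fallback=cfg.blq_policy)
    if cp.has_section("estimation"):
        cfg.n_burn = cp.getint("estimation", "n_burn", fallback=cfg.n_burn)
        cfg.n_smooth = cp.getint("estimation", "n_smooth", fallback=cfg.n_smooth)
        cfg.mh_steps = cp.getint("estimation", "mh_steps", fallback=cfg.mh_steps)
        cfg.n_is = cp.getint("estimation", "n_is", fallback=cfg.n_is)
        cfg.seed = cp.getint("estimation", "seed", fallback=cfg.seed)
    if cp.has_section("design"):
        cfg.n_sim = cp.getint("design", "n_sim", fallback=cfg.n_sim)
    if cp.has_section("output"):
        cfg.out_dir = cp.get("output", "dir", fallback=cfg.out_dir)
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["model"] = {"structural": cfg.model, "error_form": cfg.error_form,
                   "blq_policy": cfg.blq_policy}
    cp["estimation"] = {"n_burn": str(cfg.n_burn), "n_smooth": str(cfg.n_smooth),
                        "mh_steps": str(cfg.mh_steps), "n_is": str(cfg.n_is),
                        "seed": str(cfg.seed)}
    cp["design"] = {"n_sim": str(cfg.n_sim)}
    cp["output"] = {"dir": cfg.out_dir}
    with open(path, "w", encoding="utf-8") as fh:
        cp.write(fh)


def config_hash(cfg: RunConfig) -> str:
    payload = repr(sorted(cfg.__dict__.items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
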