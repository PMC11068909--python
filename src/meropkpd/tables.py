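"""Packaged study tables: clinical covariates and per-patient PK parameters.

The cohort is 12 adults with abdominal septic shock after gastrointestinal
perforation, split by renal function into a creatinine-clearance-normal
subgroup (CrCl > 50 mL/min, n = 9) and an abnormal subgroup (n = 3).  The two
fixture CSVs carry the per-patient clinical covariates and the NCA-derived PK
parameters (first 1 g / 30 min meropenem dose), so every downstream stage —
correlations, Monte Carlo simulation, reporting — runs without external data.

Procalcitonin values reported as "> 100 ug/L" are stored as 100 with a
``pct_censored`` flag rather than coerced silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "PatientPK",
    "load_patients",
    "load_pk",
    "write_patients",
    "write_pk",
    "summarize",
    "subgroup_pk_summary",
]

N_PATIENTS = 12
SUBGROUPS = ("crcl_normal", "crcl_abnormal")
CRCL_CUTOFF = 50.0  # mL/min; normal renal function means CrCl above this

_PATIENT_COLUMNS = [
    "patient_id", "subgroup", "age_years", "sex", "bmi_kg_m2", "apache2",
    "sofa", "crcl_ml_min", "map_mmhg", "wbc_10e9_L", "pct_ug_L",
    "pct_censored", "pathogens",
]
_PK_COLUMNS = [
    "patient_id", "auc_mg_h_L", "cl_L_h", "vd_L", "cmax_mg_L", "tmax_h",
    "t_half_h",
]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    subgroup: str
    age: float
    sex: str
    bmi: float
    apache2: int
    sofa: int
    crcl: float
    map_mmhg: float
    wbc: float
    pct: float
    pct_censored: bool
    pathogens: str


@dataclass(frozen=True)
class PatientPK:
    patient_id: int
    auc: float
    cl: float
    vd: float
    cmax: float
    tmax: float
    t_half: float


def _default(name: str):
    return resources.files("meropkpd.data").joinpath(name)


def _read_csv(path_or_default, default_name: str) -> pd.DataFrame:
    src = _default(default_name) if path_or_default is None else path_or_default
    return pd.read_csv(src, comment="#")


def _check_ids(df: pd.DataFrame) -> None:
    if len(df) != N_PATIENTS:
        raise ValueError(f"expected {N_PATIENTS} patients, got {len(df)}")
    ids = df["patient_id"].tolist()
    seen: set[int] = set()
    for row, pid in enumerate(ids, start=1):
        if pd.isna(pid):
            raise ValueError(f"missing patient_id at row {row}")
        if pid in seen:
            raise ValueError(f"duplicate patient_id {pid} at row {row}")
        seen.add(pid)


def load_patients(path_or_default=None) -> list[PatientRecord]:
    """Load clinical covariate records (the packaged fixture by default).

    Validates cardinality (exactly 12), unique ids, known subgroup labels,
    and the subgroup-membership rule CrCl > 50 mL/min iff ``crcl_normal``.
    Records are returned ordered by patient_id.
    """
    df = _read_csv(path_or_default, "patients.csv")
    missing = set(_PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patients CSV missing columns: {sorted(missing)}")
    _check_ids(df)
    df = df.sort_values("patient_id")
    records = []
    for _, r in df.iterrows():
        if r["subgroup"] not in SUBGROUPS:
            raise ValueError(f"unknown subgroup label {r['subgroup']!r} for patient {r['patient_id']}")
        normal = float(r["crcl_ml_min"]) > CRCL_CUTOFF
        if normal != (r["subgroup"] == "crcl_normal"):
            raise ValueError(
                f"patient {r['patient_id']}: CrCl {r['crcl_ml_min']} inconsistent "
                f"with subgroup {r['subgroup']} (cutoff {CRCL_CUTOFF} mL/min)"
            )
        records.append(
            PatientRecord(
                patient_id=int(r["patient_id"]),
                subgroup=str(r["subgroup"]),
                age=float(r["age_years"]),
                sex=str(r["sex"]),
                bmi=float(r["bmi_kg_m2"]),
                apache2=int(r["apache2"]),
                sofa=int(r["sofa"]),
                crcl=float(r["crcl_ml_min"]),
                map_mmhg=float(r["map_mmhg"]),
                wbc=float(r["wbc_10e9_L"]),
                pct=float(r["pct_ug_L"]),
                pct_censored=bool(r["pct_censored"]),
                pathogens=str(r["pathogens"]),
            )
        )
    counts = {s: sum(r.subgroup == s for r in records) for s in SUBGROUPS}
    if counts != {"crcl_normal": 9, "crcl_abnormal": 3}:
        raise ValueError(f"unexpected subgroup sizes: {counts}")
    return records


def load_pk(path_or_default=None) -> list[PatientPK]:
    """Load per-patient PK parameter records; all values must be positive."""
    df = _read_csv(path_or_default, "pk_params.csv")
    missing = set(_PK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PK CSV missing columns: {sorted(missing)}")
    _check_ids(df)
    df = df.sort_values("patient_id")
    records = []
    for _, r in df.iterrows():
        vals = {c: float(r[c]) for c in _PK_COLUMNS[1:]}
        bad = [c for c, v in vals.items() if not v > 0]
        if bad:
            raise ValueError(f"patient {r['patient_id']}: non-positive {bad}")
        records.append(
            PatientPK(
                patient_id=int(r["patient_id"]),
                auc=vals["auc_mg_h_L"],
                cl=vals["cl_L_h"],
                vd=vals["vd_L"],
                cmax=vals["cmax_mg_L"],
                tmax=vals["tmax_h"],
                t_half=vals["t_half_h"],
            )
        )
    return records


def _patients_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({
            "patient_id": d["patient_id"], "subgroup": d["subgroup"],
            "age_years": d["age"], "sex": d["sex"], "bmi_kg_m2": d["bmi"],
            "apache2": d["apache2"], "sofa": d["sofa"],
            "crcl_ml_min": d["crcl"], "map_mmhg": d["map_mmhg"],
            "wbc_10e9_L": d["wbc"], "pct_ug_L": d["pct"],
            "pct_censored": d["pct_censored"], "pathogens": d["pathogens"],
        })
    return pd.DataFrame(rows, columns=_PATIENT_COLUMNS)


def write_patients(records: Iterable[PatientRecord], path) -> None:
    _patients_frame(records).to_csv(path, index=False)


def write_pk(records: Iterable[PatientPK], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id, "auc_mg_h_L": r.auc,
                "cl_L_h": r.cl, "vd_L": r.vd, "cmax_mg_L": r.cmax,
                "tmax_h": r.tmax, "t_half_h": r.t_half,
            }
            for r in records
        ],
        columns=_PK_COLUMNS,
    )
    df.to_csv(path, index=False)


def summarize(values: Sequence[float], style: str = "mean_sd"):
    """Summary statistic tuple for a list of values.

    ``mean_sd`` returns (mean, sample SD with n-1 denominator) and needs at
    least two values; ``median_range`` returns (median, min, max).  Rounding
    to the one-decimal display convention is left to the presentation layer.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    if style == "mean_sd":
        if vals.size < 2:
            raise ValueError("mean_sd needs at least 2 values")
        return float(vals.mean()), float(vals.std(ddof=1))
    if style == "median_range":
        return float(median(vals)), float(vals.min()), float(vals.max())
    raise ValueError(f"unknown summary style {style!r}")


def subgroup_pk_summary(
    pk: Sequence[PatientPK], patients: Sequence[PatientRecord]
) -> pd.DataFrame:
    """Mean +/- SD of each PK parameter per subgroup and overall.

    Rows ``crcl_normal``, ``crcl_abnormal``, ``total``; columns
    ``<param>_mean`` / ``<param>_sd`` for auc, cl, vd, cmax, t_half, plus n.
    """
    group_of = {p.patient_id: p.subgroup for p in patients}
    missing = [r.patient_id for r in pk if r.patient_id not in group_of]
    if missing:
        raise ValueError(f"PK records without matching patient: {missing}")
    rows = {}
    for label in (*SUBGROUPS, "total"):
        sel = [r for r in pk if label == "total" or group_of[r.patient_id] == label]
        row = {"n": len(sel)}
        for param in ("auc", "cl", "vd", "cmax", "t_half"):
            m, s = summarize([getattr(r, param) for r in sel], "mean_sd")
            row[f"{param}_mean"], row[f"{param}_sd"] = m, s
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")
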