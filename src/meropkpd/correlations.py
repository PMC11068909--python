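"""Spearman rank correlation of clinical covariates against CL and Vd,
plus the Cockcroft-Gault creatinine-clearance estimate.

With n = 12 patients the analysis is exploratory: rank correlation makes no
linearity assumption and is insensitive to the exact magnitude of the one
censored procalcitonin value (stored as 100 with a flag), since ranks only
see that it exceeds the next-largest value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .tables import PatientPK, PatientRecord

__all__ = [
    "CorrelationResult",
    "COVARIATES",
    "spearman",
    "correlation_table",
    "cockcroft_gault",
]


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    parameter: str  # "cl" or "vd"
    rho: float
    p_value: float
    n: int

    @property
    def flag(self) -> str:
        """Display flag: ``**`` for p < 0.01, ``*`` for p < 0.05."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Ties get average ranks; rho is the Pearson correlation of the rank
    vectors (equal to 1 - 6*sum(d^2)/(n(n^2-1)) when tie-free) and the
    p-value comes from the t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation: constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# Covariate extractors, in report order.  Sex is coded male=1/female=0; the
# coding direction affects only the sign of that one coefficient.
COVARIATES: tuple[tuple[str, Callable[[PatientRecord], float]], ...] = (
    ("age", lambda r: r.age),
    ("gender", lambda r: 1.0 if r.sex == "male" else 0.0),
    ("bmi", lambda r: r.bmi),
    ("apache2", lambda r: float(r.apache2)),
    ("sofa", lambda r: float(r.sofa)),
    ("crcl", lambda r: r.crcl),
    ("map", lambda r: r.map_mmhg),
    ("wbc", lambda r: r.wbc),
    ("pct", lambda r: r.pct),
)


def correlation_table(
    patients: Sequence[PatientRecord],
    pk: Sequence[PatientPK],
    parameter: str,
) -> list[CorrelationResult]:
    """Correlate each clinical covariate against one PK parameter.

    ``parameter`` is ``"cl"`` or ``"vd"``; records are joined on patient_id
    and every patient must appear in both tables.
    """
    if parameter not in ("cl", "vd"):
        raise ValueError(f"parameter must be 'cl' or 'vd', got {parameter!r}")
    pk_by_id = {r.patient_id: r for r in pk}
    pairs = [(p, pk_by_id[p.patient_id]) for p in patients if p.patient_id in pk_by_id]
    if not pairs:
        raise ValueError("empty join between patients and PK records")
    y = [getattr(k, parameter) for _, k in pairs]
    out = []
    for name, extract in COVARIATES:
        x = [extract(p) for p, _ in pairs]
        rho, p_val = spearman(x, y)
        out.append(CorrelationResult(name, parameter, rho, p_val, len(pairs)))
    return out


def cockcroft_gault(age: float, weight_kg: float, scr_mg_dl: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance estimate (mL/min).

    CrCl = (140 - age) * weight / (72 * Scr), times 0.85 for females.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not (age > 0 and weight_kg > 0 and scr_mg_dl > 0):
        raise ValueError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise ValueError("age must be below 140 years")
    crcl = (140.0 - age) * weight_kg / (72.0 * scr_mg_dl)
    if sex == "female":
        crcl *= 0.85
    return crcl
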