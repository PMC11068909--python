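"""Non-compartmental analysis of single-dose infusion concentration profiles.

Standard NCA: trapezoidal AUC/AUMC to the last quantifiable sample, terminal
log-linear regression for the elimination rate constant lambda_z, and
extrapolation to infinity.  Clearance and volumes follow from the usual
identities CL = Dose/AUCinf, Vz = Dose/(lambda_z * AUCinf), Vss = CL * MRT,
with the mean residence time corrected for the infusion duration
(MRT = AUMCinf/AUCinf - tinf/2).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTimeProfile",
    "NCAResult",
    "TerminalPhaseError",
    "STUDY_SCHEDULE",
    "fit_lambda_z",
    "auc_aumc",
    "run_nca",
    "read_profiles_csv",
    "results_to_frame",
]

#: First-dose sampling schedule used throughout: hours after infusion start.
STUDY_SCHEDULE: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.5, 3.5, 5.5, 7.5)


class TerminalPhaseError(ValueError):
    """Raised when no valid terminal log-linear phase can be estimated."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's dose event and timed plasma concentrations.

    Times are hours after the start of a ``dose_mg`` infusion lasting
    ``tinf_h``; concentrations are total plasma levels in mg/L.  Samples with
    concentration below ``lloq`` (if set) are excluded from analysis.
    """

    subject_id: str
    dose_mg: float
    tinf_h: float
    samples: tuple[tuple[float, float], ...]
    lloq: float | None = None

    def __post_init__(self) -> None:
        if not self.dose_mg > 0 or not self.tinf_h > 0:
            raise ValueError("dose and infusion duration must be positive")
        if len(self.samples) < 4:
            raise ValueError(f"need at least 4 samples, got {len(self.samples)}")
        t = np.array([s[0] for s in self.samples], dtype=float)
        c = np.array([s[1] for s in self.samples], dtype=float)
        if not np.all(t > 0) or not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing and positive")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "samples", tuple((float(a), float(b)) for a, b in self.samples))

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def concs(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)

    def quantifiable(self) -> "ConcentrationTimeProfile":
        """Copy with below-LLOQ samples dropped (standard bioanalytical
        handling: censored values are excluded, not zeroed)."""
        if self.lloq is None:
            return self
        keep = tuple(s for s in self.samples if s[1] >= self.lloq)
        return dataclasses.replace(self, samples=keep)

    def scaled(self, factor: float) -> "ConcentrationTimeProfile":
        """Copy with all concentrations multiplied by ``factor``."""
        return dataclasses.replace(
            self, samples=tuple((t, c * factor) for t, c in self.samples)
        )


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    lambda_z: float
    lambda_z_r2_adj: float
    n_points_lambda_z: int
    auc_last: float
    auc_inf: float
    aumc_inf: float
    cl: float
    vz: float
    vss: float
    mrt: float
    t_half: float
    cmax: float
    tmax: float
    pct_extrapolated: float


def _terminal_candidates(profile: ConcentrationTimeProfile):
    """Positive-concentration samples strictly after Tmax (Cmax excluded)."""
    t, c = profile.times, profile.concs
    imax = int(np.argmax(c))  # argmax takes the earliest on ties
    mask = (np.arange(len(t)) > imax) & (c > 0)
    return t[mask], c[mask]


def _loglin(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and adjusted R^2 of log(c) on t."""
    logc = np.log(c)
    slope, intercept = np.polyfit(t, logc, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    n = len(t)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), r2_adj


def fit_lambda_z(
    profile: ConcentrationTimeProfile, strategy: str | int = "best_adj_r2"
) -> tuple[float, float, int]:
    """Estimate the terminal elimination rate constant lambda_z (1/h).

    ``strategy="best_adj_r2"`` regresses log-concentration on time over the
    last k points for every k from 3 up to all post-Tmax samples and keeps
    the fit with the largest adjusted R^2, preferring more points on ties.
    An integer strategy uses exactly the last k post-Tmax points.

    Returns ``(lambda_z, r2_adj, n_points)``; raises
    :class:`TerminalPhaseError` if fewer than 3 usable points exist or no
    candidate fit has a negative slope.
    """
    t, c = _terminal_candidates(profile.quantifiable())
    if len(t) < 3:
        raise TerminalPhaseError("terminal phase not estimable")
    if isinstance(strategy, int):
        ks: Sequence[int] = [strategy]
        if not 3 <= strategy <= len(t):
            raise TerminalPhaseError("terminal phase not estimable")
    elif strategy == "best_adj_r2":
        ks = range(3, len(t) + 1)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    best: tuple[float, float, int] | None = None
    for k in ks:
        slope, r2_adj = _loglin(t[-k:], c[-k:])
        if slope >= 0:
            continue
        if best is None or r2_adj >= best[1]:  # >= so ties keep more points
            best = (-slope, r2_adj, k)
    if best is None:
        raise TerminalPhaseError("terminal phase not estimable")
    return best


def _segment_auc_aumc(t1, c1, t2, c2, log_down: bool) -> tuple[float, float]:
    if log_down and c1 > c2 > 0:
        k = math.log(c1 / c2) / (t2 - t1)
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    else:
        auc = (t2 - t1) * (c1 + c2) / 2.0
        aumc = (t2 - t1) * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def auc_aumc(
    profile: ConcentrationTimeProfile, method: str = "linear_up_log_down"
) -> tuple[float, float]:
    """Trapezoidal AUC and AUMC from time zero to the last quantifiable sample.

    The interval before the first sample is linear from C(0) = 0 (the drug is
    infused from t = 0).  ``linear_up_log_down`` applies the log trapezoid on
    strictly decreasing positive segments — exact on mono-exponential decay —
    and the linear trapezoid elsewhere; ``linear`` is linear throughout.
    """
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    p = profile.quantifiable()
    t = np.concatenate([[0.0], p.times])
    c = np.concatenate([[0.0], p.concs])
    log_down = method == "linear_up_log_down"
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        a, m = _segment_auc_aumc(t[i], c[i], t[i + 1], c[i + 1], log_down)
        auc += a
        aumc += m
    return auc, aumc


def run_nca(
    profile: ConcentrationTimeProfile,
    method: str = "linear_up_log_down",
    strategy: str | int = "best_adj_r2",
) -> NCAResult:
    """Full NCA of one single-dose profile.

    AUC and AUMC are extrapolated beyond the last sample with the fitted
    terminal slope:  AUCinf = AUClast + Clast/lz  and
    AUMCinf = AUMClast + Clast*tlast/lz + Clast/lz^2.
    """
    p = profile.quantifiable()
    lz, r2_adj, npts = fit_lambda_z(p, strategy=strategy)
    auc_last, aumc_last = auc_aumc(p, method=method)
    t, c = p.times, p.concs
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    t_last, c_last = float(t[-1]), float(c[-1])
    auc_inf = auc_last + c_last / lz
    aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz**2
    cl = p.dose_mg / auc_inf
    vz = p.dose_mg / (lz * auc_inf)
    mrt = aumc_inf / auc_inf - p.tinf_h / 2.0
    return NCAResult(
        subject_id=p.subject_id,
        lambda_z=lz,
        lambda_z_r2_adj=r2_adj,
        n_points_lambda_z=npts,
        auc_last=auc_last,
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        cl=cl,
        vz=vz,
        vss=cl * mrt,
        mrt=mrt,
        t_half=math.log(2) / lz,
        cmax=cmax,
        tmax=tmax,
        pct_extrapolated=100.0 * (auc_inf - auc_last) / auc_inf,
    )


def read_profiles_csv(
    path,
    dose_mg: float = 1000.0,
    tinf_h: float = 0.5,
    lloq: float | None = None,
) -> list[ConcentrationTimeProfile]:
    """Read long-format profiles (columns subject_id, time_h, conc_mg_L).

    ``dose_mg`` and ``tinf_h`` apply to every subject unless the CSV also
    carries per-row ``dose_mg`` / ``tinf_h`` columns.
    """
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "time_h", "conc_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profiles CSV missing columns: {sorted(missing)}")
    profiles = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_h")
        dose = float(grp["dose_mg"].iloc[0]) if "dose_mg" in grp else dose_mg
        tinf = float(grp["tinf_h"].iloc[0]) if "tinf_h" in grp else tinf_h
        samples = tuple(zip(grp["time_h"].astype(float), grp["conc_mg_L"].astype(float)))
        profiles.append(
            ConcentrationTimeProfile(str(sid), dose, tinf, samples, lloq=lloq)
        )
    return profiles


def results_to_frame(results: Sequence[NCAResult]) -> pd.DataFrame:
    """One row per subject, columns = NCAResult fields."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
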