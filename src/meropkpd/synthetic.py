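"""Synthetic concentration-time profiles and virtual PK cohorts.

The study's raw plasma concentrations are not published, so testable inputs
are generated from the same kinetic model the analysis assumes: a first dose
of 1000 mg infused over 0.5 h into one compartment, sampled at the study's
eight time points between 0.25 and 7.5 h.  Observed concentrations carry a
combined proportional (CV 10%) plus additive (SD 0.05 mg/L) error emulating
an LC-MS/MS assay qualitatively, with values below the quantification limit
dropped.  The per-subject true (CL, Vd) are returned alongside, so parameter
recovery through the NCA engine can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nca import STUDY_SCHEDULE, ConcentrationTimeProfile
from .pta import ParameterDraws, SimDistribution, sample_parameters

__all__ = [
    "SyntheticSpec",
    "single_dose_conc",
    "simulate_profiles",
    "simulate_cohort_pk",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the profile generator; defaults mirror the study
    design (1 g over 30 min, eight samples to 7.5 h)."""

    n_subjects: int
    dist: SimDistribution
    dose_mg: float = 1000.0
    tinf_h: float = 0.5
    schedule: tuple[float, ...] = STUDY_SCHEDULE
    error_cv: float = 0.10
    error_add_sd: float = 0.05
    lloq: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.dose_mg > 0 and self.tinf_h > 0):
            raise ValueError("dose and infusion duration must be positive")
        sched = np.asarray(self.schedule, dtype=float)
        if not np.all(sched > 0) or not np.all(np.diff(sched) > 0):
            raise ValueError("schedule must be strictly increasing positive times")
        if self.error_cv < 0 or self.error_add_sd < 0 or self.lloq < 0:
            raise ValueError("error magnitudes and LLOQ must be non-negative")


def single_dose_conc(t, cl: float, vd: float, dose_mg: float = 1000.0, tinf_h: float = 0.5):
    """Noise-free first-dose concentration: zero-order infusion then
    mono-exponential decay from the end-of-infusion peak."""
    t = np.asarray(t, dtype=float)
    ke = cl / vd
    r0_cl = dose_mg / tinf_h / cl
    rising = r0_cl * (1.0 - np.exp(-ke * np.minimum(t, tinf_h)))
    out = rising * np.exp(-ke * np.maximum(t - tinf_h, 0.0))
    return out if out.ndim else float(out)


def simulate_profiles(
    spec: SyntheticSpec,
) -> tuple[list[ConcentrationTimeProfile], pd.DataFrame]:
    """Generate noisy first-dose profiles plus the generating truth table.

    Observation model: c_obs = c*(1+e1) + e2 with e1 ~ N(0, error_cv) and
    e2 ~ N(0, error_add_sd); observations below LLOQ are omitted from the
    profile (censored, not zeroed).  Returns ``(profiles, truth)`` where
    ``truth`` has columns subject_id, cl, vd, fu.
    """
    rng = np.random.default_rng(spec.seed)
    draws = sample_parameters(spec.dist, spec.n_subjects, rng)
    sched = np.asarray(spec.schedule, dtype=float)
    profiles = []
    for i in range(spec.n_subjects):
        c = single_dose_conc(sched, draws.cl[i], draws.vd[i], spec.dose_mg, spec.tinf_h)
        eps_p = rng.normal(0.0, spec.error_cv, size=len(sched)) if spec.error_cv else 0.0
        eps_a = rng.normal(0.0, spec.error_add_sd, size=len(sched)) if spec.error_add_sd else 0.0
        obs = c * (1.0 + eps_p) + eps_a
        keep = obs >= spec.lloq
        samples = tuple(zip(sched[keep], obs[keep]))
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=f"S{i + 1:03d}",
                dose_mg=spec.dose_mg,
                tinf_h=spec.tinf_h,
                samples=samples,
                lloq=spec.lloq or None,
            )
        )
    truth = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "cl": draws.cl,
            "vd": draws.vd,
            "fu": draws.fu,
        }
    )
    return profiles, truth


def simulate_cohort_pk(
    dist: SimDistribution,
    n: int,
    seed: int = 0,
    dose_mg: float = 1000.0,
    tinf_h: float = 0.5,
    age_range: tuple[float, float] = (18.0, 90.0),
    crcl_range: tuple[float, float] = (20.0, 170.0),
) -> pd.DataFrame:
    """Schema-complete virtual PK records derived from sampled (CL, Vd).

    AUC = dose/CL and t1/2 = ln2 * Vd/CL follow from the one-compartment
    model; Cmax is the end-of-infusion first-dose peak and Tmax = tinf.
    Ages and CrCl are uniform draws from the given ranges (no causal link to
    the PK parameters).  Columns match the packaged ``pk_params.csv`` plus
    ``age_years`` and ``crcl_ml_min``.
    """
    rng = np.random.default_rng(seed)
    draws = sample_parameters(dist, n, rng)
    cmax = np.array(
        [single_dose_conc(tinf_h, c, v, dose_mg, tinf_h) for c, v in zip(draws.cl, draws.vd)]
    )
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "auc_mg_h_L": dose_mg / draws.cl,
            "cl_L_h": draws.cl,
            "vd_L": draws.vd,
            "cmax_mg_L": cmax,
            "tmax_h": np.full(n, tinf_h),
            "t_half_h": np.log(2.0) * draws.vd / draws.cl,
            "age_years": rng.uniform(*age_range, size=n),
            "crcl_ml_min": rng.uniform(*crcl_range, size=n),
        }
    )


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format frame (subject_id, time_h, conc_mg_L, dose_mg, tinf_h)."""
    rows = [
        {
            "subject_id": p.subject_id,
            "time_h": t,
            "conc_mg_L": c,
            "dose_mg": p.dose_mg,
            "tinf_h": p.tinf_h,
        }
        for p in profiles
        for t, c in p.samples
    ]
    return pd.DataFrame(rows)
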