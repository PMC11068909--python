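# Methods

## Scope and data flow

The package reconstructs a complete meropenem PK/PD workflow for abdominal
septic shock from three inputs: the packaged 12-patient study tables
(clinical covariates and per-patient NCA parameters), user-supplied
concentration–time CSVs, and simulation configuration. The stages are
independent library modules — `tables`, `nca`, `infusion`, `pta`,
`correlations`, `synthetic`, `reporting` — wired together by a thin click
CLI. Raw plasma concentrations for the original cohort are not available,
so the NCA engine is validated on synthetic profiles with known generating
parameters rather than against the per-patient table values, which are
kept as fixtures only.

## Packaged study tables

`patients.csv` and `pk_params.csv` hold one row per patient. The subgroup
rule (CrCl > 50 mL/min ⇔ `crcl_normal`, 9 vs 3 patients) is enforced at
load time, as are cardinality (exactly 12), id uniqueness, and positivity
of PK values. One procalcitonin value is right-censored at 100 µg/L and
stored as 100 with a `pct_censored` flag; the rank-based correlation is
insensitive to the exact magnitude of a single value already larger than
every other, so it enters the Spearman analysis as 100. Summary statistics
use the sample SD (n−1); every subgroup mean ± SD recomputed from the
per-patient rows reproduces the reported summary at one-decimal rounding,
with a single exception: the pooled AUC SD recomputes to 47.0 rather than
47.1 mg·h/L (a rounding artefact in the source summary; the mean, 140.5,
is exact).

## Non-compartmental analysis

- **λz.** Log-linear least squares over the last k samples strictly after
  Tmax (the Cmax point excluded, a minimum of 3 points — the conventional
  choice). The default strategy searches k and keeps the largest adjusted
  R², preferring more points on ties; a fixed k can be forced. A
  non-negative slope raises `TerminalPhaseError`.
- **AUC/AUMC.** Default `linear_up_log_down`: log trapezoid on strictly
  decreasing positive segments (exact on mono-exponential decay), linear
  otherwise, matching common practice for infusion data. The interval
  [0, t₁] is linear from C(0) = 0 since the drug is infused from t = 0.
  AUMC uses the trapezoid of t·C on linear segments and the closed-form
  moment integral on log segments.
- **Extrapolation.** AUC∞ = AUClast + Clast/λz;
  AUMC∞ = AUMClast + Clast·tlast/λz + Clast/λz². MRT subtracts Tinf/2 to
  correct for the infusion; Vss = CL·MRT. Values below the LLOQ are
  dropped before fitting (standard bioanalytical handling), never zeroed.
- **Accuracy.** On noise-free one-compartment profiles sampled at the
  study's 8 time points, the only error is the linear chord during the
  infusion rise; recovered CL and Vz stay within 1% of truth across the
  plausible parameter range (tested to a 3% bound, and to a ±5% median
  bias bound under 10% proportional noise with n = 200).

## Steady-state infusion model and %fT>threshold

Steady state — not the first dose — is simulated. Under a first dose
C(0) = 0, so any 100%fT target would be unattainable by construction,
contradicting the attainment the simulation is meant to measure; steady
state is also the standard PTA setting. With ke = CL/Vd, R₀ = Dose/Tinf:

- during infusion: C(t) = R₀/CL − (R₀/CL − Ctrough)·e^(−ke·t)
- after infusion: C(t) = Cmax,ss·e^(−ke·(t−Tinf))
- Cmax,ss = (R₀/CL)·(1−e^(−ke·Tinf))/(1−e^(−ke·τ)),
  Ctrough = Cmax,ss·e^(−ke·(τ−Tinf))

The curve is continuous at Tinf and periodic over τ; Tinf = τ is treated
as an exact continuous infusion C = Dose/(τ·CL), avoiding the 0/0 of the
general branch. Protein binding enters as a free fraction f multiplying
the total concentration.

%fT>threshold is computed analytically: the within-interval minimum is
the trough and the maximum is the end-of-infusion peak, so the attained
set is either everything, nothing, or the span between one rising
crossing (log-solved during infusion) and one falling crossing (after).
The comparison is strict (f·C > threshold); the boundary has measure
zero, so the choice only fixes determinism. A dense-grid counting oracle
(`ft_above_grid_oracle`) exists purely for testing and agrees with the
analytic value within 100·step/τ percentage points on 1,000 random draws.

## Monte Carlo PTA

Per subgroup, CL and Vd are drawn independently from normal distributions
truncated to positive values by rejection resampling (at the study means
the truncation correction is ~10⁻⁵ of the mean), and f ~ U(0.85, 0.98).
Defaults: n_sim = 10,000 with an explicit seed (numpy `default_rng`). The
same draws are reused across every regimen × MIC × target cell, making
between-regimen comparisons paired; this choice (the alternative —
fresh draws per cell — is equally defensible) changes only the variance,
not the expectation. A draw attains a target when its %fT ≥ the target
percentage; each cell reports PTA with a Wilson 95% binomial CI
(clamped to bracket the point estimate at the 0/1 boundaries). The
adequacy rule "PTA > 90%" is applied as ≥ 90.0 after rounding to one
decimal, again fixing a measure-zero boundary deterministically.

Independence of CL and Vd is a documented simplification: the source
summary gives no correlation, though physiologically the two are likely
positively correlated in shock; a positive correlation would mainly
widen the spread of ke and slightly lower PTA at strict targets.

## Correlations

Spearman's ρ via average ranks (scipy), with the two-sided p-value from
the t approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 df — this reproduces
the reported headline values (ρ(age, CL) = −0.608, p = 0.036;
ρ(CrCl, CL) = 0.727, p = 0.007; ρ(age, Vd) = −0.643, p = 0.024) exactly
at three decimals. Exact permutation inference is impractical at n = 12
(12! ≈ 4.8×10⁸). Sex is coded male = 1/female = 0; the coding direction
affects only the sign of that coefficient, and the sex and WBC rows are
not treated as reproduction targets (see limitations). Cockcroft–Gault:
CrCl = (140−age)·weight/(72·Scr), ×0.85 for females, rejecting
age ≥ 140.

## Synthetic cohort generator

Profiles emulate the study design: 1000 mg over 0.5 h, sampled at
{0.25, 0.5, 1, 1.5, 2.5, 3.5, 5.5, 7.5} h, per-subject (CL, Vd, f) drawn
from the subgroup distributions above. Observation noise is combined
proportional + additive, c_obs = c·(1+ε₁)+ε₂ with ε₁ ~ N(0, 0.10) and
ε₂ ~ N(0, 0.05 mg/L), and an LLOQ of 0.05 mg/L below which samples are
dropped — magnitudes chosen once as qualitatively representative of a
validated LC–MS/MS assay (≈10% CV mid-range, sub-0.1 mg/L sensitivity),
not as estimates of the study assay. The generator returns the truth
table alongside, so pipeline tests measure parameter recovery directly.

What the generator does **not** emulate: two-compartment distribution
kinetics, time-varying clearance during resuscitation, covariate–PK
causal structure (ages and CrCl in `simulate_cohort_pk` are independent
draws), correlated CL–Vd, or assay failures. Passing recovery tests
therefore show the NCA engine is correct for the assumed kinetic model
at the study's sampling design — not that the model captures every
feature of real septic-shock data.

## Problem sizes and numerics

Tests run the full 10,000-draw, both-subgroup, full-grid PTA simulation
(≈0.4 s vectorised) and n = 200 noisy NCA recoveries; the grid-oracle
comparison uses step = τ/2000 over 1,000 draws. Logs in masked `np.where`
branches are guarded by clipping to 10⁻³⁰⁰. Ties in Cmax take the
earliest time; ties in the λz point search keep the larger point count.

## Known limitations

- Whether the source per-patient AUC column is AUClast or AUC∞ (and Vd
  is Vz or Vss) cannot be reconciled from the printed values
  (e.g. Dose/AUC ≠ CL for patient 1), so the NCA engine reports both
  AUC variants and no per-patient equality with the fixture table is
  asserted anywhere.
- The reported WBC–CL coefficient (+0.413) matches the fixture
  recomputation in magnitude but not sign (−0.413), and the reported sex
  coefficients match under neither 0/1 coding; these three rows are
  reported by `correlation_table` but excluded from reproduction checks.
- PTA is simulated at steady state; no first-dose PTA mode exists yet.
- No MIC-distribution-weighted cumulative fraction of response; PTA is
  reported per fixed MIC only.
- One-compartment, linear elimination only.
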