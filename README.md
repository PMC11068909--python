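# meropkpd

Meropenem pharmacokinetic/pharmacodynamic (PK/PD) analysis for critically
ill patients with abdominal septic shock, built around three stages:

1. **Non-compartmental analysis (NCA)** of first-dose concentration–time
   profiles (1 g infused over 30 min, eight samples between 0.25 and
   7.5 h): trapezoidal AUC/AUMC, terminal log-linear λz, and the derived
   parameters CL = Dose/AUC∞, Vz = Dose/(λz·AUC∞), Vss = CL·MRT,
   t½ = ln 2/λz.
2. **Steady-state infusion modelling and %fT>MIC.** For a one-compartment
   model with elimination rate ke = CL/Vd and infusion rate R₀ = Dose/Tinf,
   the steady-state peak is

   Cmax,ss = (R₀/CL) · (1 − e^(−ke·Tinf)) / (1 − e^(−ke·τ)),

   the trough is Cmax,ss·e^(−ke·(τ−Tinf)), and the fraction of the dosing
   interval with free concentration f·C(t) above a threshold (MIC or
   4×MIC) is solved analytically from the two log-form crossing times.
   Meropenem is time-dependent, so %fT>MIC is the efficacy driver.
3. **Monte Carlo probability of target attainment (PTA).** Virtual patients
   are drawn per renal-function subgroup — CL ~ N(7.7, 1.8²) L/h,
   Vd ~ N(22.6, 5.1²) L for normal creatinine clearance (CrCl > 50 mL/min);
   CL ~ N(4.4, 1.1²) L/h, Vd ~ N(17.2, 5.8²) L for abnormal — truncated to
   positive values, with free fraction f ~ U(0.85, 0.98). PTA is the
   percentage of 10,000 draws attaining a target
   ({40, 60, 80, 100}%fT>MIC or >4MIC) for each regimen
   (0.5 g q6h, 1 g q8h, 1 g q6h, 2 g q12h; infused over 0.5, 3 or 6 h)
   across MIC 0.25–64 mg/L. A regimen is considered adequate at a MIC when
   PTA ≥ 90%.

The package also ships the 12-patient study tables (clinical covariates
and per-patient PK parameters) as versioned fixtures, Spearman rank
correlations of covariates against CL and Vd, a Cockcroft–Gault CrCl
utility, and a synthetic-cohort generator (one-compartment kinetics plus
proportional + additive assay noise with LLOQ censoring) used to validate
the NCA engine by parameter recovery.

## Worked example

```python
import meropkpd as m

params = m.PKParameters(cl=7.7, vd=22.6, fu=0.9)
reg = m.Regimen(dose_mg=1000, tau_h=8, tinf_h=0.5)
print(round(m.css(0.5, params, reg), 2))                    # 43.54  (Cmax,ss mg/L)
print(round(m.css(0.0, params, reg), 2))                    # 3.38   (trough mg/L)
print(round(m.percent_ft_above(params, reg, mic=8), 1))     # 63.7   (%fT>MIC)

tab = m.compute_pta(m.CRCL_NORMAL, m.STUDY_REGIMENS, n_sim=10_000, seed=42)
ext = m.Regimen(1000, 6, 6)   # 1 g q6h as a continuous 6-h infusion
print(tab.pta(ext, 1.0, m.PDTarget(100, 4)))                # 100.0  (PTA %)
```

The first three numbers describe a typical CrCl-normal patient on 1 g q8h
over 30 min: the steady-state curve peaks at 43.5 mg/L, troughs at
3.4 mg/L, and free drug stays above an 8 mg/L MIC for 63.7% of the
interval. The last line shows that with a 1 g q6h extended (6 h) infusion,
every one of 10,000 simulated normal-CrCl patients keeps free drug above
4×MIC for the entire interval at MIC 1 mg/L — the strictest bactericidal
target; `m.adequacy(tab)` reports 2 mg/L as the highest grid MIC at which
that regimen still reaches PTA ≥ 90%.

The same pipeline is available from the shell:

```sh
meropkpd simulate --n 12 --seed 1 --out-dir sim     # synthetic profiles + truth
meropkpd nca --profiles sim/profiles.csv            # batch NCA
meropkpd pta --n-sim 10000 --seed 1 --figures       # PTA tables and figures
meropkpd correlate                                  # covariate correlations
meropkpd reproduce --out-dir out                    # full pipeline + manifest
```

`meropkpd reproduce` recomputes the subgroup PK summary, both correlation
tables and the full PTA grids from the packaged fixtures, and writes a
pass/fail manifest against the study's reported aggregates, correlations
and PTA adequacy claims.

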