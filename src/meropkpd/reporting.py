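"""End-to-end reporting: recompute every headline result from the packaged
tables and simulation engines, write the artefacts as CSV, and render PTA
figures.  All outputs carry a provenance header (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .correlations import correlation_table
from .infusion import STUDY_REGIMENS, PDTarget, Regimen
from .pta import (
    CRCL_ABNORMAL,
    CRCL_NORMAL,
    MIC_GRID,
    DEFAULT_TARGETS,
    PTATable,
    compute_pta,
)
from .tables import load_patients, load_pk, subgroup_pk_summary

__all__ = [
    "write_csv_with_provenance",
    "render_pta_figures",
    "reproduce_study",
]


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv_with_provenance(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write ``df`` as CSV preceded by ``#`` comment lines recording the
    package version, the seed, and a hash of the run configuration."""
    path = Path(path)
    lines = [f"# meropkpd {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config is not None:
        lines.append(f"# config_hash {_config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def render_pta_figures(table: PTATable, outdir) -> list[Path]:
    """One figure per (subgroup, MIC multiplier): PTA vs MIC curves per
    regimen, one panel per %fT threshold, with the 90% adequacy line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = table.frame
    if f.empty:
        raise ValueError("empty PTA table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (subgroup, mult), sub in f.groupby(["subgroup", "multiplier"]):
        thresholds = sorted(sub["target_pct"].unique())
        fig, axes = plt.subplots(
            1, len(thresholds), figsize=(4 * len(thresholds), 3.5), sharey=True
        )
        axes = [axes] if len(thresholds) == 1 else list(axes)
        for ax, pct in zip(axes, thresholds):
            panel = sub[sub["target_pct"] == pct]
            for (dose, tau, tinf), curve in panel.groupby(["dose_mg", "tau_h", "tinf_h"]):
                curve = curve.sort_values("mic")
                ax.plot(
                    curve["mic"], curve["pta_pct"], marker="o", ms=3,
                    label=Regimen(dose, tau, tinf).label(),
                )
            ax.axhline(90, color="grey", ls="--", lw=1)
            ax.set_xscale("log", base=2)
            mult_lbl = "MIC" if mult == 1 else f"{mult}MIC"
            ax.set_title(f"{pct}%fT>{mult_lbl}")
            ax.set_xlabel("MIC (mg/L)")
        axes[0].set_ylabel("PTA (%)")
        axes[-1].legend(fontsize=6, loc="lower left")
        fig.suptitle(f"{subgroup}, %fT>{'MIC' if mult == 1 else str(mult) + 'MIC'} targets")
        fig.tight_layout()
        path = outdir / f"pta_{subgroup}_x{mult}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths


def _check(name: str, expected: float, observed: float, tol: float) -> dict:
    return {
        "check": name,
        "expected": expected,
        "observed": observed,
        "status": "pass" if abs(observed - expected) <= tol else "fail",
    }


def _check_ge(name: str, bound: float, observed: float) -> dict:
    return {
        "check": name,
        "expected": f">={bound}",
        "observed": observed,
        "status": "pass" if observed >= bound else "fail",
    }


def reproduce_study(
    outdir,
    n_sim: int = 10_000,
    seed: int = 20230101,
    figures: bool = False,
) -> pd.DataFrame:
    """Recompute the full analysis from packaged fixtures and write it out.

    Emits the subgroup PK summary, both correlation tables, full-grid PTA
    tables for both subgroups, and a pass/fail manifest checking the
    recomputed values against the study's reported aggregates, headline
    correlations, and PTA adequacy claims.  Returns the manifest frame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {"n_sim": n_sim, "seed": seed}

    patients = load_patients()
    pk = load_pk()

    summary = subgroup_pk_summary(pk, patients)
    write_csv_with_provenance(summary.reset_index(names="subgroup"), outdir / "pk_summary.csv", seed, config)

    corr_frames = {}
    for param in ("cl", "vd"):
        rows = correlation_table(patients, pk, param)
        df = pd.DataFrame(
            [
                {"covariate": r.covariate, "rho": r.rho, "p_value": r.p_value, "flag": r.flag}
                for r in rows
            ]
        )
        corr_frames[param] = {r.covariate: r for r in rows}
        write_csv_with_provenance(df, outdir / f"correlations_{param}.csv", seed, config)

    tables = {}
    for i, dist in enumerate((CRCL_NORMAL, CRCL_ABNORMAL)):
        tab = compute_pta(
            dist, STUDY_REGIMENS, MIC_GRID, DEFAULT_TARGETS, n_sim=n_sim, seed=seed + i
        )
        tables[dist.label] = tab
        write_csv_with_provenance(tab.frame, outdir / f"pta_{dist.label}.csv", seed + i, config)
        if figures:
            render_pta_figures(tab, outdir / "figures")

    # --- manifest ---------------------------------------------------------
    rows = []
    s = summary
    half = 0.05  # one-decimal reporting tolerance
    rows.append(_check("mean AUC all (mg*h/L)", 140.5, s.loc["total", "auc_mean"], half))
    rows.append(_check("mean AUC crcl_abnormal", 199.4, s.loc["crcl_abnormal", "auc_mean"], half))
    rows.append(_check("mean CL crcl_normal (L/h)", 7.7, s.loc["crcl_normal", "cl_mean"], half))
    rows.append(_check("mean CL crcl_abnormal", 4.4, s.loc["crcl_abnormal", "cl_mean"], half))
    rows.append(_check("mean CL all", 6.9, s.loc["total", "cl_mean"], half))
    rows.append(_check("mean Vd crcl_normal (L)", 22.6, s.loc["crcl_normal", "vd_mean"], half))
    rows.append(_check("mean Vd crcl_abnormal", 17.2, s.loc["crcl_abnormal", "vd_mean"], half))

    tol3 = 0.0005  # three-decimal reporting tolerance
    rows.append(_check("rho(age, CL)", -0.608, corr_frames["cl"]["age"].rho, tol3))
    rows.append(_check("p(age, CL)", 0.036, corr_frames["cl"]["age"].p_value, tol3))
    rows.append(_check("rho(CrCl, CL)", 0.727, corr_frames["cl"]["crcl"].rho, tol3))
    rows.append(_check("p(CrCl, CL)", 0.007, corr_frames["cl"]["crcl"].p_value, tol3))
    rows.append(_check("rho(age, Vd)", -0.643, corr_frames["vd"]["age"].rho, tol3))
    rows.append(_check("p(age, Vd)", 0.024, corr_frames["vd"]["age"].p_value, tol3))

    t40 = PDTarget(40, 1)
    t40x4 = PDTarget(40, 4)
    t100x4 = PDTarget(100, 4)
    q6h_ext = Regimen(1000.0, 6.0, 6.0)
    for label, tab in tables.items():
        min_low_mic = min(
            tab.pta(reg, mic, t40)
            for reg in STUDY_REGIMENS
            for mic in (0.25, 0.5, 1.0, 2.0, 4.0)
        )
        rows.append(_check_ge(f"min PTA {label}, MIC<=4, 40%fT>MIC", 90.0, min_low_mic))
        min_4mic = min(
            tab.pta(reg, mic, t40x4) for reg in STUDY_REGIMENS for mic in (0.25, 0.5)
        )
        rows.append(_check_ge(f"min PTA {label}, MIC<=0.5, 40%fT>4MIC", 90.0, min_4mic))
    rows.append(
        _check_ge(
            "PTA crcl_normal 1g q6h inf 6h, MIC 1, 100%fT>4MIC", 90.0,
            tables["crcl_normal"].pta(q6h_ext, 1.0, t100x4),
        )
    )
    rows.append(
        _check_ge(
            "PTA crcl_abnormal 1g q6h inf 6h, MIC 2, 100%fT>4MIC", 90.0,
            tables["crcl_abnormal"].pta(q6h_ext, 2.0, t100x4),
        )
    )

    manifest = pd.DataFrame(rows)
    write_csv_with_provenance(manifest, outdir / "manifest.csv", seed, config)
    return manifest
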