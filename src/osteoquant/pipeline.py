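"""Study orchestration: generate -> analyze -> compare -> report.

``run_study`` drives the whole synthetic-cohort workflow: it generates raw
artifacts for every animal, runs each modality's analysis stage off the
written files, assembles a per-animal parameter table, and produces the
group-comparison table (mean +/- SD, auto-selected test, p, stars, signed
percent difference), within-group correlations, and the forward stepwise
glycation regressions, all persisted as CSV/JSON with a provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .assay import compute_fage, fit_standard_curve, quantify_hydroxyproline
from .indentation import analyze_nanoindentation, analyze_rpi, segment_cycles
from .mechanics import analyze_bending
from .microct import calibrate_density, cortical_morphometry, trabecular_morphometry
from .spectra import analyze_xrd, compute_ftir_params
from .stats import GroupSample, compare_groups, forward_stepwise, pearson_r
from .synthetic import CohortConfig, generate_cohort

__all__ = ["StudyConfig", "StudyReport", "run_study", "analyze_animal"]

log = logging.getLogger("osteoquant")

#: parameter table columns measured by each modality
MODALITY_PARAMS = {
    "bending": ["f_max_n", "stiffness_n_mm", "work_to_failure_n_mm", "pyd_mm"],
    "rpi": ["id_first_um", "tid_um", "idi_um", "us_first_n_um", "avg_ed_uj"],
    "nano": ["er_gpa", "hardness_gpa"],
    "ftir": [
        "mineral_to_matrix",
        "carbonate_to_phosphate",
        "crystallinity",
        "acid_phosphate",
        "collagen_maturity",
        "ne_xlr",
    ],
    "xrd": ["crystal_length_nm", "crystal_width_nm"],
    "fage": ["fage_ng_mg", "collagen_mg"],
    "microct": [
        "bv_tv_pct",
        "tb_th_mm",
        "tb_sp_mm",
        "tb_n_per_mm",
        "ct_ar_mm2",
        "ct_th_mm",
        "j_mm4",
        "ct_tmd_mg_cc",
    ],
}

COVARIATES = [
    "body_weight_g",
    "fasting_glucose_mg_dl",
    "hba1c_pct",
    "plasma_insulin_miu_l",
    "triglyceride_mg_dl",
    "cholesterol_mg_dl",
]

#: within-group Pearson correlations of interest (x, y)
CORRELATION_PAIRS = [
    ("hba1c_pct", "ne_xlr"),
    ("hba1c_pct", "bv_tv_pct"),
    ("hba1c_pct", "ct_th_mm"),
    ("hba1c_pct", "ct_ar_mm2"),
    ("hba1c_pct", "f_max_n"),
    ("hba1c_pct", "crystal_width_nm"),
    ("fage_ng_mg", "crystal_width_nm"),
    ("ne_xlr", "pyd_mm"),
]


@dataclass
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str = "study_out"
    modalities: tuple = ()  # empty -> all of cohort.modalities
    max_missing_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.modalities:
            self.modalities = tuple(self.cohort.modalities)
        else:
            self.cohort = dataclasses.replace(
                self.cohort, modalities=tuple(self.modalities)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("modalities",):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            d["cohort"] = CohortConfig(**c)
        if isinstance(d.get("modalities"), list):
            d["modalities"] = tuple(d["modalities"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    stepwise: dict
    parameters: pd.DataFrame
    provenance: dict
    missing_fraction: float
    warnings: list[str] = field(default_factory=list)


def analyze_animal(rec: dict, modalities: tuple, base_dir=".") -> dict:
    """Run every enabled analysis stage on one animal's artifact files.

    Paths in ``rec`` are resolved against ``base_dir`` (the cohort's raw
    artifact directory).
    """
    base = Path(base_dir)

    def p(path):
        return base / path

    out: dict[str, float] = {}
    if "bending" in modalities and rec.get("bending_path"):
        res = analyze_bending(oio.read_trace(p(rec["bending_path"])))
        out.update(
            f_max_n=res.F_max,
            stiffness_n_mm=res.stiffness,
            work_to_failure_n_mm=res.work_to_failure,
            pyd_mm=res.PYD,
        )
    if "rpi" in modalities and rec.get("rpi_paths"):
        sites = []
        for path in str(rec["rpi_paths"]).split(";"):
            force, depth, _ = oio.read_rpi(p(path))
            sites.append(segment_cycles(force, depth))
        res = analyze_rpi(sites)
        out.update(
            id_first_um=res.ID_1st,
            tid_um=res.TID,
            idi_um=res.IDI,
            us_first_n_um=res.US_1st,
            avg_ed_uj=res.Avg_ED,
        )
    if "nano" in modalities and rec.get("nano_paths"):
        results = [
            analyze_nanoindentation(oio.read_nano(p(path)))
            for path in str(rec["nano_paths"]).split(";")
        ]
        out.update(
            er_gpa=float(np.mean([r.Er for r in results])),
            hardness_gpa=float(np.mean([r.H for r in results])),
        )
    if "ftir" in modalities and rec.get("ftir_path"):
        res = compute_ftir_params(oio.read_spectrum(p(rec["ftir_path"]), "ftir"))
        out.update(
            mineral_to_matrix=res.mineral_to_matrix,
            carbonate_to_phosphate=res.carbonate_to_phosphate,
            crystallinity=res.crystallinity,
            acid_phosphate=res.acid_phosphate,
            collagen_maturity=res.collagen_maturity,
            ne_xlr=res.NE_xLR,
        )
    if "xrd" in modalities and rec.get("xrd_path"):
        res = analyze_xrd(oio.read_spectrum(p(rec["xrd_path"]), "xrd"))
        out.update(
            crystal_length_nm=res.length_nm, crystal_width_nm=res.width_nm
        )
    if "fage" in modalities and rec.get("plate_quinine_path"):
        quinine = oio.read_plate(p(rec["plate_quinine_path"]), "fluorescence_360_460")
        hyp = oio.read_plate(p(rec["plate_hydroxyproline_path"]), "absorbance_570")
        q_curve = fit_standard_curve(quinine.standards)
        h_curve = fit_standard_curve(hyp.standards)
        volume = float(rec.get("hydrolysate_volume_ml", 1.0))
        _, reading, dil = hyp.samples[0]
        hyp_mg, collagen, _ = quantify_hydroxyproline(
            reading, h_curve, dilution=dil, hydrolysate_volume_mL=volume
        )
        _, f_reading, f_dil = quinine.samples[0]
        fage = compute_fage(
            f_reading,
            q_curve,
            collagen,
            dilution=f_dil,
            hydrolysate_volume_mL=volume,
            hydroxyproline_mg=hyp_mg,
        )
        out.update(fage_ng_mg=fage.fage, collagen_mg=collagen)
    if "microct" in modalities and rec.get("cortical_path"):
        calib = calibrate_density(
            (float(rec["phantom_gray_200"]), float(rec["phantom_gray_800"]))
        )
        cort = cortical_morphometry(oio.read_volume(p(rec["cortical_path"])), calib)
        out.update(
            ct_ar_mm2=cort.ct_ar_mm2,
            ct_th_mm=cort.ct_th_mm,
            j_mm4=cort.j_mm4,
            ct_tmd_mg_cc=cort.tmd_mg_cc,
        )
        trab = trabecular_morphometry(oio.read_volume(p(rec["trabecular_path"])))
        out.update(
            bv_tv_pct=trab.bv_tv_pct,
            tb_th_mm=trab.tb_th_mm,
            tb_sp_mm=trab.tb_sp_mm,
            tb_n_per_mm=trab.tb_n_per_mm,
        )
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all enabled stages and write the consolidated report.

    A failed stage leaves that animal's cells missing and the run
    continues; the report records the overall missing fraction (callers
    may treat > ``max_missing_fraction`` as a failure).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    log.info("generate: cohort of %d animals, seed %d", 2 * config.cohort.n_per_group, config.cohort.seed)
    table = generate_cohort(config.cohort, out / "raw")
    rows = []
    expected = sum(len(MODALITY_PARAMS[m]) for m in config.modalities)
    missing_cells = 0
    for rec in table.to_dict("records"):
        row = {"id": rec["id"], "group": rec["group"]}
        for cov in COVARIATES:
            row[cov] = rec.get(f"true_{cov}", np.nan)
        try:
            measured = analyze_animal(rec, config.modalities, out / "raw")
        except Exception as exc:  # stage failure: mark missing, continue
            log.warning("analyze %s failed: %s", rec["id"], exc)
            warnings_log.append(f"{rec['id']}: analysis failed: {exc}")
            measured = {}
        got = sum(
            1
            for m in config.modalities
            for p in MODALITY_PARAMS[m]
            if measured.get(p) is not None
        )
        missing_cells += expected - got
        row.update(measured)
        rows.append(row)
    params = pd.DataFrame(rows)
    # carry the generator's latent truths alongside the recovered values
    truth_cols = ["id"] + [c for c in table.columns if c.startswith("true_")]
    params = params.merge(table[truth_cols], on="id", how="left")
    params.to_csv(out / "parameters.csv", index=False, float_format="%.8g")

    measured_cols = [
        p
        for m in config.modalities
        for p in MODALITY_PARAMS[m]
        if p in params.columns
    ] + [c for c in COVARIATES if c in params.columns]
    ctrl = params[params["group"] == "control"]
    t2d = params[params["group"] == "t2d"]

    comp_rows = []
    for col in measured_cols:
        x = ctrl[col].dropna().to_numpy()
        y = t2d[col].dropna().to_numpy()
        try:
            res = compare_groups(
                GroupSample(col, "control", x), GroupSample(col, "t2d", y)
            )
            comp_rows.append(
                {
                    "parameter": col,
                    "control_mean": res.mean_control,
                    "control_sd": res.sd_control,
                    "t2d_mean": res.mean_t2d,
                    "t2d_sd": res.sd_t2d,
                    "test": res.test,
                    "p_value": res.p_value,
                    "percent_difference": res.percent_difference,
                    "stars": res.stars,
                    "n_control": res.n_control,
                    "n_t2d": res.n_t2d,
                }
            )
        except Exception as exc:
            warnings_log.append(f"comparison failed for {col}: {exc}")
    log.info("compare: %d parameters", len(comp_rows))
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")

    corr_rows = []
    for group_name, sub in (("control", ctrl), ("t2d", t2d)):
        for xcol, ycol in CORRELATION_PAIRS:
            if xcol not in sub.columns or ycol not in sub.columns:
                continue
            pair = sub[[xcol, ycol]].dropna()
            if len(pair) < 3:
                continue
            try:
                r, p = pearson_r(pair[xcol].to_numpy(), pair[ycol].to_numpy())
            except ValueError:
                continue
            corr_rows.append(
                {"group": group_name, "x": xcol, "y": ycol, "r": r,
                 "r_squared": r * r, "p_value": p}
            )
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(out / "correlations.csv", index=False,
                        float_format="%.6g")

    stepwise_summary = {}
    glycation = [c for c in ("fage_ng_mg", "ne_xlr") if c in params.columns]
    targets = [
        c
        for c in ("f_max_n", "stiffness_n_mm", "work_to_failure_n_mm", "pyd_mm")
        if c in params.columns
    ]
    if glycation and targets:
        sub = t2d[targets + glycation].dropna()
        for target in targets:
            if len(sub) < 4:
                continue
            model = forward_stepwise(
                sub[target].to_numpy(),
                {g: sub[g].to_numpy() for g in glycation},
            )
            stepwise_summary[target] = {
                "entered": model.entered,
                "r_squared": model.r_squared,
                "entry_p_values": model.entry_p_values,
                "coefficients": model.coefficients,
            }

    n_cells = expected * len(params) if expected else 1
    missing_fraction = missing_cells / n_cells
    from . import __version__

    provenance = {
        "seed": config.cohort.seed,
        "config_hash": config.config_hash(),
        "osteoquant_version": __version__,
        "n_per_group": config.cohort.n_per_group,
        "modalities": list(config.modalities),
    }
    report = {
        "provenance": provenance,
        "missing_fraction": missing_fraction,
        "comparisons": comp_rows,
        "correlations": corr_rows,
        "stepwise": stepwise_summary,
        "warnings": warnings_log,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return StudyReport(
        comparisons=comparisons,
        correlations=correlations,
        stepwise=stepwise_summary,
        parameters=params,
        provenance=provenance,
        missing_fraction=missing_fraction,
        warnings=warnings_log,
    )
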