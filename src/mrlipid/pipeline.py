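"""Config-driven orchestration of the full study workflow.

``run_study`` executes, in order: read or simulate summary statistics ->
harmonization -> genome-wide instrument selection per exposure -> confounder
exclusion -> Steiger filtering -> the univariable estimator battery plus
MR-PRESSO per exposure -> pooled multivariable MR (IVW, Egger, Lasso,
conditional F) -> per-drug, per-pair and non-target cis analyses ->
Bonferroni significance flags -> delimited report tables plus a
machine-readable JSON manifest.

Every stochastic stage consumes a named sub-seed derived from the master
seed by hashing the stage name, so adding a stage never perturbs earlier
stages' draws, and two runs with the same master seed are byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .drug_target import (
    DrugTargetSpec,
    combination_mr,
    drug_target_mr,
    non_target_mr,
)
from .estimators import MREstimate, egger, ivw, leave_one_out, median_estimator
from .gwas_io import SummaryRecord, read_summary_stats
from .instruments import (
    ConfounderTable,
    GeneRegion,
    InstrumentSet,
    LDMatrix,
    exclude_confounder_snps,
    instrument_strength,
    read_gene_regions,
    read_ld_matrix,
    select_genomewide,
    steiger_filter,
)
from .mvmr import mr_lasso, mvmr_egger, mvmr_ivw, pool_instruments
from .presso import run_presso
from .synthetic import SimulationConfig, SimulatedStudy, simulate_dataset

__all__ = [
    "StudyConfig",
    "StudyReport",
    "bonferroni_threshold",
    "subseed",
    "run_study",
    "format_p",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m.

    Comparisons always use the unrounded value; the reporting layer rounds
    to 3 decimals for display (0.05/3 -> "0.017", 0.05/4 -> "0.013").
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def subseed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: crc32 of the stage name mixed with master."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


def format_p(p: float) -> str:
    """Display rounding: scientific notation below 0.001, 3 decimals above."""
    if np.isnan(p):
        return "NA"
    return f"{p:.2E}" if p < 1e-3 else f"{p:.3f}"


@dataclass
class StudyConfig:
    """Paths or a simulation config, thresholds, and test-family settings."""

    simulation: SimulationConfig | None = None
    exposure_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_path: str | None = None
    regions_path: str | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    region_r2: dict[str, float] = field(
        default_factory=lambda: {"HMGCR": 0.2, "PCSK9": 0.2, "NPC1L1": 0.3}
    )
    region_drugs: dict[str, str] = field(
        default_factory=lambda: {
            "HMGCR": "statin", "PCSK9": "evolocumab", "NPC1L1": "ezetimibe"
        }
    )
    min_snps: int = 3
    confounder_traits: tuple[str, ...] = ("blood pressure", "hypertension")
    n_boot: int = 1000
    n_sim_presso: int = 1000
    alpha: float = 0.05
    lipid_family_size: int = 3  # Bonferroni family: 3 lipids
    drug_family_size: int = 4  # 3 drug targets + the non-target set
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and (
            not self.exposure_paths or self.outcome_path is None
        ):
            raise ValueError(
                "config needs either a simulation or exposure/outcome paths"
            )
        if self.simulation is not None:
            self.simulation.validate()
        bonferroni_threshold(self.alpha, self.lipid_family_size)
        bonferroni_threshold(self.alpha, self.drug_family_size)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


@dataclass
class StudyReport:
    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    drug_target: pd.DataFrame
    diagnostics: pd.DataFrame
    manifest: dict
    failures: list[dict] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.univariable.to_csv(outdir / "univariable_mr.tsv", sep="\t", index=False)
        self.multivariable.to_csv(
            outdir / "multivariable_mr.tsv", sep="\t", index=False
        )
        self.drug_target.to_csv(outdir / "drug_target_mr.tsv", sep="\t", index=False)
        self.diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _uni_row(exposure: str, est: MREstimate, sig_threshold: float) -> dict:
    o, lo, hi = est.or_scale
    return {
        "exposure": exposure,
        "method": est.method,
        "nsnp": est.nsnp,
        "theta": est.theta,
        "se": est.se,
        "or": round(o, 3),
        "or_ci": est.format_or(),
        "pval": est.pval,
        "pval_display": format_p(est.pval),
        "significant": bool(est.pval < sig_threshold),
    }


def _load_inputs(config: StudyConfig):
    if config.simulation is not None:
        study = simulate_dataset(config.simulation, seed=subseed(config.seed, "simulate"))
        return (
            study.exposures,
            study.outcome,
            study.ld,
            study.regions,
            study.confounders,
            study,
        )
    exposures = {}
    for name, path in config.exposure_paths.items():
        recs, _ = read_summary_stats(path)
        exposures[name] = recs
    outcome, _ = read_summary_stats(config.outcome_path)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    regions = read_gene_regions(config.regions_path) if config.regions_path else []
    return exposures, outcome, ld, regions, ConfounderTable(), None


def run_study(config: StudyConfig, outdir=None, include_timestamp: bool = False) -> StudyReport:
    """Run the full univariable + multivariable + drug-target workflow.

    Per-exposure failures are contained: they surface as rows in the
    ``failures`` block of the manifest, never as a silent skip.  Output is
    deterministic under ``config.seed`` (the manifest records a wall-clock
    timestamp only when ``include_timestamp`` is set, so that default runs
    are byte-identical).
    """
    config.validate()
    exposures, outcome, ld, regions, confounders, study = _load_inputs(config)
    failures: list[dict] = []
    lipid_thr = bonferroni_threshold(config.alpha, config.lipid_family_size)
    drug_thr = bonferroni_threshold(config.alpha, config.drug_family_size)

    uni_rows: list[dict] = []
    diag_rows: list[dict] = []
    selected: dict[str, InstrumentSet] = {}
    accounting: dict[str, dict] = {}

    for name, recs in exposures.items():
        try:
            iset = select_genomewide(
                recs, outcome, ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
                window_kb=config.window_kb,
                exposure_name=name,
            )
            n_selected = iset.nsnp
            iset = exclude_confounder_snps(
                iset, confounders, config.confounder_traits
            )
            n_confounder = n_selected - iset.nsnp
            iset, steiger = steiger_filter(iset)
            n_steiger = n_selected - n_confounder - iset.nsnp
            selected[name] = iset
            accounting[name] = {
                "selected": n_selected,
                "dropped_confounder": n_confounder,
                "dropped_steiger": n_steiger,
                "analysed": iset.nsnp,
            }
            strength = instrument_strength(iset)
            est_fe, het = ivw(iset, model="fixed")
            est_mre, _ = ivw(iset, model="multiplicative_random")
            # report both IVW variants; flag the random-effects one when
            # heterogeneity is detected
            uni_rows.append(_uni_row(name, est_fe, lipid_thr))
            uni_rows.append(_uni_row(name, est_mre, lipid_thr))
            if iset.nsnp >= 3:
                est_eg, pleio, het_eg = egger(iset)
                uni_rows.append(_uni_row(name, est_eg, lipid_thr))
                sm = median_estimator(
                    iset, "simple", n_boot=config.n_boot,
                    seed=subseed(config.seed, f"simple_median:{name}"),
                )
                wm = median_estimator(
                    iset, "weighted", n_boot=config.n_boot,
                    seed=subseed(config.seed, f"weighted_median:{name}"),
                )
                uni_rows.append(_uni_row(name, sm, lipid_thr))
                uni_rows.append(_uni_row(name, wm, lipid_thr))
            else:
                pleio = None
            presso = None
            if iset.nsnp >= 4:
                presso = run_presso(
                    iset, n_sim=config.n_sim_presso,
                    seed=subseed(config.seed, f"presso:{name}"),
                )
                est_presso = (
                    presso.corrected_estimate
                    if presso.corrected_estimate is not None
                    else presso.raw_estimate
                )
                row = _uni_row(name, est_presso, lipid_thr)
                row["method"] = "presso"
                uni_rows.append(row)
            loo = leave_one_out(iset) if iset.nsnp >= 3 else []
            diag_rows.append(
                {
                    "block": "univariable",
                    "exposure": name,
                    "nsnp": iset.nsnp,
                    "aggregate_F": strength["aggregate_F"],
                    "aggregate_r2": strength["aggregate_r2"],
                    "weak_instruments": int(np.sum(strength["weak"])),
                    "steiger_all_forward": bool(all(s.direction_ok for s in steiger)),
                    "Q": het.Q,
                    "Q_pval": het.pval,
                    "egger_intercept": pleio.intercept if pleio else np.nan,
                    "egger_intercept_pval": pleio.pval if pleio else np.nan,
                    "presso_global_pval": presso.global_pval if presso else np.nan,
                    "presso_n_outliers": len(presso.outlier_ids) if presso else 0,
                    "loo_flagged": int(sum(r["flagged"] for r in loo)),
                }
            )
        except Exception as exc:  # contained: other exposures still run
            failures.append({"stage": f"univariable:{name}", "error": str(exc)})

    # multivariable block
    mv_rows: list[dict] = []
    if len(exposures) >= 2:
        try:
            mvset = pool_instruments(
                exposures, outcome, ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
                window_kb=config.window_kb,
            )
            for result in (mvmr_ivw(mvset), mvmr_egger(mvset), mr_lasso(mvset)):
                for exp_name, est in zip(result.exposure_names, result.estimates):
                    row = _uni_row(exp_name, est, lipid_thr)
                    row["method"] = result.method
                    row["nsnp"] = result.nsnp
                    mv_rows.append(row)
                diag_rows.append(
                    {
                        "block": "multivariable",
                        "exposure": result.method,
                        "nsnp": result.nsnp,
                        "Q": result.Q,
                        "Q_pval": result.Q_pval,
                        "egger_intercept": (
                            result.egger_intercept[0]
                            if result.egger_intercept
                            else np.nan
                        ),
                        "egger_intercept_pval": (
                            result.egger_intercept[2]
                            if result.egger_intercept
                            else np.nan
                        ),
                        **{
                            f"conditional_F_{k}": v
                            for k, v in result.conditional_F.items()
                        },
                    }
                )
        except Exception as exc:
            failures.append({"stage": "multivariable", "error": str(exc)})

    # drug-target block (cis analyses use the first exposure, e.g. LDL-C)
    dt_rows: list[dict] = []
    first_exposure = next(iter(exposures)) if exposures else None
    specs = []
    for region in regions:
        specs.append(
            DrugTargetSpec(
                drug=config.region_drugs.get(region.gene, region.gene),
                region=region,
                r2_threshold=config.region_r2.get(region.gene),
            )
        )
    if first_exposure is not None and specs:
        recs = exposures[first_exposure]

        def dt_report(result, label):
            for method, est in result.estimates.items():
                o, lo, hi = est.or_scale
                dt_rows.append(
                    {
                        "analysis": label,
                        "genes": "+".join(result.genes),
                        "drugs": "+".join(result.drugs),
                        "method": method,
                        "nsnp": est.nsnp,
                        "theta": est.theta,
                        "or": round(o, 3),
                        "or_ci": est.format_or(),
                        "pval": est.pval,
                        "pval_display": format_p(est.pval),
                        "significant": bool(est.pval < drug_thr),
                    }
                )
            diag_rows.append(
                {
                    "block": "drug_target",
                    "exposure": label,
                    "nsnp": result.instrument_set.nsnp,
                    "Q": result.heterogeneity.Q,
                    "Q_pval": result.heterogeneity.pval,
                    "egger_intercept": (
                        result.egger_intercept.intercept
                        if result.egger_intercept
                        else np.nan
                    ),
                    "egger_intercept_pval": (
                        result.egger_intercept.pval
                        if result.egger_intercept
                        else np.nan
                    ),
                    "loo_flagged": int(
                        sum(r["flagged"] for r in result.leave_one_out)
                    ),
                    "gls_theta": (
                        result.gls_estimate.theta if result.gls_estimate else np.nan
                    ),
                }
            )

        for spec in specs:
            try:
                res = drug_target_mr(
                    recs, outcome, spec, ld,
                    p_threshold=config.p_threshold,
                    min_snps=config.min_snps,
                    seed=subseed(config.seed, f"drug:{spec.region.gene}"),
                )
                dt_report(res, f"target:{spec.region.gene}")
            except Exception as exc:
                failures.append(
                    {"stage": f"drug_target:{spec.region.gene}", "error": str(exc)}
                )
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                pair = (specs[i], specs[j])
                label = f"combination:{pair[0].region.gene}+{pair[1].region.gene}"
                try:
                    res = combination_mr(
                        recs, outcome, pair, ld,
                        p_threshold=config.p_threshold,
                        min_snps=config.min_snps,
                        seed=subseed(config.seed, label),
                    )
                    dt_report(res, label)
                except Exception as exc:
                    failures.append({"stage": label, "error": str(exc)})
        try:
            res = non_target_mr(
                recs, outcome, regions, ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
                window_kb=config.window_kb,
                genomewide=selected.get(first_exposure),
                seed=subseed(config.seed, "non_target"),
            )
            dt_report(res, "non-target")
        except Exception as exc:
            failures.append({"stage": "non_target", "error": str(exc)})

    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "r2_threshold": config.r2_threshold,
            "window_kb": config.window_kb,
            "region_r2": config.region_r2,
            "min_snps": config.min_snps,
            "bonferroni_lipids": lipid_thr,
            "bonferroni_lipids_display": f"{lipid_thr:.3f}",
            "bonferroni_drug_targets": drug_thr,
            "bonferroni_drug_targets_display": f"{drug_thr:.3f}",
        },
        "estimator_settings": {
            "n_boot": config.n_boot,
            "n_sim_presso": config.n_sim_presso,
        },
        "stage_accounting": accounting,
        "failures": failures,
    }
    if include_timestamp:
        import datetime

        manifest["timestamp"] = datetime.datetime.now().isoformat()
    if study is not None:
        manifest["simulation"] = {
            "theta": list(study.config.theta),
            "n_snps": study.config.n_snps,
            "exposures": study.config.names(),
        }

    report = StudyReport(
        univariable=pd.DataFrame(uni_rows),
        multivariable=pd.DataFrame(mv_rows),
        drug_target=pd.DataFrame(dt_rows),
        diagnostics=pd.DataFrame(diag_rows),
        manifest=manifest,
        failures=failures,
    )
    if outdir is not None:
        report.write(outdir)
    return report
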