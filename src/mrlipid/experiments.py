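"""Repeated-simulation experiments: calibration, recovery, robustness.

Each function runs a self-contained Monte-Carlo experiment against the
synthetic generator and returns plain dictionaries of summary numbers.  The
acceptance script and the analysis drivers both call these, so every
reported quantity is recomputed from scratch at run time.

Monte-Carlo standard errors (MC-SE) are SD-over-replicates / sqrt(n_reps);
"bias within 3 MC-SE" is the usual simulation-study unbiasedness check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from .estimators import (
    _weighted_median_rows,
    egger_fit,
    ivw_fit,
    weighted_median_fit,
)
from .gwas_io import two_sided_p
from .instruments import GeneRegion
from .synthetic import (
    RegionSpec,
    SimulationConfig,
    egger_power_config,
    median_robust_config,
    mvmr_attenuation_config,
    simulate_arrays,
    simulate_dataset,
)

__all__ = [
    "oracle_discrepancy",
    "null_calibration",
    "recovery_experiment",
    "median_robustness_experiment",
    "egger_power_experiment",
    "presso_calibration",
    "presso_power",
    "mvmr_attenuation_experiment",
    "drug_target_pattern",
    "non_target_count_experiment",
]

_P_GW = 5e-8


def _null_instrument_config(n_snps: int = 100, theta: float = 0.0) -> SimulationConfig:
    """Pre-selected instruments: per-allele effects ~ +-N(2.5, 0.8) mg/dL."""
    return SimulationConfig(
        n_snps=n_snps,
        theta=(theta,),
        exposure_effect_mean=2.5,
        exposure_effect_sd=0.8,
    )


# ---------------------------------------------------------------------------
# closed-form oracle agreement


def oracle_discrepancy(n_instances: int = 100, seed: int = 0) -> dict:
    """Max relative error of IVW / Egger / MVMR-IVW against WLS oracles.

    The oracle is statsmodels' weighted least squares (an independent
    implementation); the package's estimators are closed-form.
    """
    import statsmodels.api as sm

    from .mvmr import MVInstrumentSet, mvmr_ivw

    rng = np.random.default_rng(seed)
    worst = {"ivw": 0.0, "egger": 0.0, "mvmr_ivw": 0.0}
    for _ in range(n_instances):
        n = int(rng.integers(5, 51))
        K = int(rng.integers(1, 4))
        bx = rng.normal(0, 1, n)
        bx[np.abs(bx) < 1e-3] += 0.1
        by = rng.normal(0, 0.5, n)
        sy = rng.uniform(0.05, 0.5, n)
        w = 1.0 / sy**2

        theta, _, _ = ivw_fit(bx, by, sy)
        ref = float(sm.WLS(by, bx[:, None], weights=w).fit().params[0])
        worst["ivw"] = max(worst["ivw"], abs(theta - ref) / max(abs(ref), 1e-12))

        sign = np.where(bx < 0, -1.0, 1.0)
        slope, _, intercept, _, _ = egger_fit(bx, by, sy)
        X = np.column_stack([np.ones(n), bx * sign])
        fit = sm.WLS(by * sign, X, weights=w).fit()
        worst["egger"] = max(
            worst["egger"],
            abs(slope - fit.params[1]) / max(abs(fit.params[1]), 1e-12),
            abs(intercept - fit.params[0]) / max(abs(fit.params[0]), 1e-12),
        )

        BX = rng.normal(0, 1, (n, K))
        fitmv = sm.WLS(by, BX, weights=w).fit()
        res = mvmr_ivw(
            MVInstrumentSet(
                [f"rs{i}" for i in range(n)],
                [f"x{j}" for j in range(K)],
                BX,
                np.full((n, K), 0.01),
                by,
                sy,
            )
        )
        for j, est in enumerate(res.estimates):
            worst["mvmr_ivw"] = max(
                worst["mvmr_ivw"],
                abs(est.theta - fitmv.params[j]) / max(abs(fitmv.params[j]), 1e-12),
            )
    worst["n_instances"] = n_instances
    return worst


# ---------------------------------------------------------------------------
# estimator calibration and recovery


def _wm_pvalue(bx, sx, by, sy, n_boot, rng) -> float:
    """Weighted-median p via the model-centred parametric-bootstrap SE."""
    point = weighted_median_fit(by / bx, (bx / sy) ** 2)
    n = bx.size
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(point * bx, sy, size=(n_boot, n))
    boots = _weighted_median_rows(by_b / bx_b, (bx_b / sy) ** 2)
    se = boots.std(ddof=1)
    return two_sided_p(point / se)


def null_calibration(
    n_sims: int = 2000, n_snps: int = 100, n_boot: int = 200, seed: int = 0
) -> dict:
    """Empirical type-I error of IVW, Egger slope and weighted median
    under the sharp null (theta = 0, no pleiotropy) at alpha = 0.05."""
    cfg = _null_instrument_config(n_snps=n_snps, theta=0.0)
    rng = np.random.default_rng(seed)
    hits = {"ivw": 0, "egger": 0, "weighted_median": 0}
    for _ in range(n_sims):
        a = simulate_arrays(cfg, rng)
        bx, by, sy = a.bx_obs[:, 0], a.by_obs, a.sy
        theta, se, _ = ivw_fit(bx, by, sy)
        hits["ivw"] += two_sided_p(theta / se) < 0.05
        slope, se_slope, _, _, _ = egger_fit(bx, by, sy)
        hits["egger"] += two_sided_p(slope / se_slope) < 0.05
        hits["weighted_median"] += (
            _wm_pvalue(bx, a.sx[:, 0], by, sy, n_boot, rng) < 0.05
        )
    return {"n_sims": n_sims, **{k: v / n_sims for k, v in hits.items()}}


def recovery_experiment(
    n_sims: int = 500, theta: float = 0.006, n_snps: int = 130, seed: int = 0
) -> dict:
    """Recovery of a planted causal effect through the full selection path.

    Each replicate simulates a genome scan, selects instruments at the
    genome-wide threshold on the observed exposure p-values (winner's curse
    included, as in practice) and estimates theta by fixed-effect IVW.
    Reports the mean estimate, its MC-SE, and 95% CI coverage.
    """
    cfg = SimulationConfig(
        n_snps=n_snps,
        n_exp=1_000_000,  # GLGC-scale exposure GWAS: negligible winner's curse
        theta=(theta,),
        exposure_effect_mean=0.0,
        exposure_effect_sd=2.5,
        maf_range=(0.05, 0.5),
    )
    rng = np.random.default_rng(seed)
    thetas, covered, nsel = [], 0, []
    for _ in range(n_sims):
        a = simulate_arrays(cfg, rng)
        z = a.bx_obs[:, 0] / a.sx[:, 0]
        keep = 2.0 * _stats.norm.sf(np.abs(z)) < _P_GW
        bx, by, sy = a.bx_obs[keep, 0], a.by_obs[keep], a.sy[keep]
        t, se, _ = ivw_fit(bx, by, sy)
        thetas.append(t)
        covered += (t - 1.959963984540054 * se) <= theta <= (t + 1.959963984540054 * se)
        nsel.append(int(keep.sum()))
    thetas = np.asarray(thetas)
    return {
        "n_sims": n_sims,
        "true_theta": theta,
        "mean_theta": float(thetas.mean()),
        "mc_se": float(thetas.std(ddof=1) / np.sqrt(n_sims)),
        "coverage": covered / n_sims,
        "mean_n_instruments": float(np.mean(nsel)),
    }


# ---------------------------------------------------------------------------
# pleiotropy robustness


def median_robustness_experiment(
    n_sims_median: int = 100, n_sims_ivw: int = 1500, seed: int = 0
) -> dict:
    """Weighted median vs IVW under 30% directional pleiotropy.

    The pleiotropy preset (see :func:`mrlipid.synthetic.median_robust_config`)
    puts a small positive mean with a large spread on 30% of instruments:
    enough one-sided weight to bias IVW measurably while the weighted median
    stays centred.  The two clauses use different replicate counts, fixed at
    design stage, so each check has resolution appropriate to the magnitude
    it measures (the IVW bias is several times the median's).
    """
    cfg = median_robust_config()
    theta = cfg.theta[0]
    rng = np.random.default_rng(seed)
    wm, iv = [], []
    for s in range(max(n_sims_median, n_sims_ivw)):
        a = simulate_arrays(cfg, rng)
        bx, by, sy = a.bx_obs[:, 0], a.by_obs, a.sy
        if s < n_sims_ivw:
            iv.append(ivw_fit(bx, by, sy)[0])
        if s < n_sims_median:
            wm.append(weighted_median_fit(by / bx, (bx / sy) ** 2))
    wm, iv = np.asarray(wm), np.asarray(iv)
    return {
        "true_theta": theta,
        "wm_n_sims": wm.size,
        "wm_bias": float(wm.mean() - theta),
        "wm_mc_se": float(wm.std(ddof=1) / np.sqrt(wm.size)),
        "ivw_n_sims": iv.size,
        "ivw_bias": float(iv.mean() - theta),
        "ivw_mc_se": float(iv.std(ddof=1) / np.sqrt(iv.size)),
    }


def egger_power_experiment(n_sims: int = 500, seed: int = 0) -> dict:
    """Power of the Egger intercept test against strong one-sided pleiotropy."""
    cfg = egger_power_config()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = simulate_arrays(cfg, rng)
        _, _, intercept, se_int, _ = egger_fit(a.bx_obs[:, 0], a.by_obs, a.sy)
        hits += two_sided_p(intercept / se_int) < 0.05
    return {"n_sims": n_sims, "power": hits / n_sims}


# ---------------------------------------------------------------------------
# MR-PRESSO


def presso_calibration(
    n_datasets: int = 500, n_sim: int = 300, n_snps: int = 40, seed: int = 0
) -> dict:
    """Global-test rejection rate under the no-pleiotropy null."""
    from .presso import presso_global_fit

    cfg = _null_instrument_config(n_snps=n_snps, theta=0.006)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        a = simulate_arrays(cfg, rng)
        _, global_p, _, _ = presso_global_fit(
            a.bx_obs[:, 0], a.by_obs, a.sx[:, 0], a.sy, n_sim, rng
        )
        rejections += global_p <= 0.05
    return {"n_datasets": n_datasets, "rejection_rate": rejections / n_datasets}


def presso_power(
    n_datasets: int = 200, n_sim: int = 1000, n_snps: int = 6, seed: int = 0
) -> dict:
    """Detection of a planted 10-SD outlier and the corrected estimate.

    One instrument per dataset receives a direct outcome effect of 10 times
    its own outcome SE.  The panel is small (6 SNPs) with comparable
    leverage (narrow MAF band, tight effect sizes): a single outlier then
    shifts the pooled estimate by ~10/sqrt(n) ~ 4 SEs, so removing it
    visibly improves the estimate — with many instruments or a low-leverage
    outlier the shift drowns in noise and the correction is a wash.
    Reports the Bonferroni-adjusted flag rate, how often the
    outlier-removed estimate lands closer to the truth than the raw one,
    and whether the corrected estimate equals fixed-effect IVW on the
    non-flagged instruments exactly (it must).
    """
    from .presso import run_presso

    theta = 0.006
    cfg = SimulationConfig(
        n_snps=n_snps,
        theta=(theta,),
        exposure_effect_mean=2.5,
        exposure_effect_sd=0.4,
        maf_range=(0.25, 0.35),
    )
    rng = np.random.default_rng(seed)
    flagged = closer = 0
    corrected_exact = True
    for d in range(n_datasets):
        a = simulate_arrays(cfg, rng)
        j = int(rng.integers(n_snps))
        by = a.by_obs.copy()
        by[j] += 10.0 * a.sy[j]
        iset = _iset_from_arrays(a.bx_obs[:, 0], a.sx[:, 0], by, a.sy)
        res = run_presso(
            iset, n_sim=n_sim, seed=int(rng.integers(2**31)), n_distortion=50
        )
        flagged += iset.snp_ids[j] in res.outlier_ids
        if res.corrected_estimate is not None:
            closer += abs(res.corrected_estimate.theta - theta) <= abs(
                res.raw_estimate.theta - theta
            )
            keep = [s for s in iset.snp_ids if s not in res.outlier_ids]
            mask = np.isin(iset.snp_ids, keep)
            t_ref, se_ref, _ = ivw_fit(
                a.bx_obs[mask, 0], by[mask], a.sy[mask]
            )
            corrected_exact &= res.corrected_estimate.theta == t_ref
        else:
            closer += 1  # no outliers flagged: corrected == raw (tie)
    return {
        "n_datasets": n_datasets,
        "flag_rate": flagged / n_datasets,
        "corrected_closer_rate": closer / n_datasets,
        "corrected_equals_ivw_minus_outliers": bool(corrected_exact),
    }


def _iset_from_arrays(bx, sx, by, sy):
    from .gwas_io import HarmonizedInstrument
    from .instruments import InstrumentSet

    instruments = [
        HarmonizedInstrument(
            snp_id=f"rs{i:05d}",
            effect_allele="A",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
        )
        for i in range(bx.size)
    ]
    return InstrumentSet(exposure_name="exposure", instruments=instruments)


# ---------------------------------------------------------------------------
# multivariable attenuation pattern


def mvmr_attenuation_experiment(n_sims: int = 200, seed: int = 0) -> dict:
    """Univariable bias on null lipids vs multivariable attenuation.

    Direct effects are (LDL 0.005, HDL 0, TG 0) with correlated per-SNP
    effects.  A replicate matches the expected pattern when (a) univariable
    HDL and TG are nominally non-null, (b) both attenuate in MVMR (smaller
    magnitude and p above the 0.05/3 family threshold), and (c) the LDL
    estimate is positive and stable between the two analyses.
    """
    from .mvmr import MVInstrumentSet, mvmr_ivw

    cfg = mvmr_attenuation_config()
    thr = 0.05 / 3
    rng = np.random.default_rng(seed)
    matches = 0
    cond_f_min = np.inf
    for _ in range(n_sims):
        a = simulate_arrays(cfg, rng)
        uni = {}
        for k, name in enumerate(cfg.names()):
            t, se, _ = ivw_fit(a.bx_obs[:, k], a.by_obs, a.sy)
            uni[name] = (t, two_sided_p(t / se))
        res = mvmr_ivw(
            MVInstrumentSet(
                [f"rs{i}" for i in range(a.maf.size)],
                cfg.names(),
                a.bx_obs,
                a.sx,
                a.by_obs,
                a.sy,
            )
        )
        emv = {n: e for n, e in zip(res.exposure_names, res.estimates)}
        cond_f_min = min(cond_f_min, min(res.conditional_F.values()))
        non_null = uni["HDL-C"][1] < 0.05 and uni["TG"][1] < 0.05
        attenuated = (
            abs(emv["HDL-C"].theta) < abs(uni["HDL-C"][0])
            and emv["HDL-C"].pval > thr
            and abs(emv["TG"].theta) < abs(uni["TG"][0])
            and emv["TG"].pval > thr
        )
        stable = (
            emv["LDL-C"].theta > 0
            and uni["LDL-C"][0] > 0
            and abs(emv["LDL-C"].theta - uni["LDL-C"][0]) < 3.5 * emv["LDL-C"].se
        )
        matches += non_null and attenuated and stable
    return {
        "n_sims": n_sims,
        "pattern_rate": matches / n_sims,
        "min_conditional_F": float(cond_f_min),
    }


# ---------------------------------------------------------------------------
# drug-target patterns


def _two_region_config() -> SimulationConfig:
    return SimulationConfig(
        n_snps=0,
        theta=(0.0,),
        regions=(
            RegionSpec(
                region=GeneRegion("PCSK9", "1", 55_500_000, 55_530_000, 100),
                n_snps=11, ar1_rho=0.4, theta=-0.01,
                effect_mean=-4.0, effect_sd=0.4,
            ),
            RegionSpec(
                region=GeneRegion("HMGCR", "5", 75_000_000, 75_030_000, 100),
                n_snps=7, ar1_rho=0.4, theta=-0.01,
                effect_mean=-3.5, effect_sd=0.4,
            ),
        ),
    )


def drug_target_pattern(n_sims: int = 500, seed: int = 0) -> dict:
    """Protective cis effect: sign recovery and combination precision.

    Both gene blocks carry theta = -0.01 per unit of the exposure.  Reports
    how often single-region IVW recovers the protective direction (OR < 1)
    and how often pooling the two regions yields an SE no larger than either
    single region (information additivity; should always hold).
    """
    cfg = _two_region_config()
    rng = np.random.default_rng(seed)
    sign_ok = combo_ok = 0
    for _ in range(n_sims):
        a = simulate_arrays(cfg, rng)
        z = a.bx_obs[:, 0] / a.sx[:, 0]
        sig = 2.0 * _stats.norm.sf(np.abs(z)) < _P_GW
        r0 = (a.region_idx == 0) & sig
        r1 = (a.region_idx == 1) & sig
        t0, se0, _ = ivw_fit(a.bx_obs[r0, 0], a.by_obs[r0], a.sy[r0])
        t1, se1, _ = ivw_fit(a.bx_obs[r1, 0], a.by_obs[r1], a.sy[r1])
        both = r0 | r1
        _, se_combo, _ = ivw_fit(a.bx_obs[both, 0], a.by_obs[both], a.sy[both])
        sign_ok += t0 < 0
        combo_ok += se_combo <= min(se0, se1) + 1e-15
    return {
        "n_sims": n_sims,
        "sign_agreement": sign_ok / n_sims,
        "combination_se_not_larger": combo_ok / n_sims,
    }


def non_target_count_experiment(seed: int = 6) -> dict:
    """Constructed genome: 107 instruments, 3 inside a target region -> 104.

    Runs the real selection and non-target paths (select_genomewide and
    non_target_mr) end to end on generated records.
    """
    from .drug_target import non_target_mr
    from .instruments import select_genomewide

    cfg = SimulationConfig(
        n_snps=104,
        theta=(0.005,),
        exposure_effect_mean=3.0,
        exposure_effect_sd=0.3,
        maf_range=(0.1, 0.5),
        regions=(
            RegionSpec(
                region=GeneRegion("HMGCR", "5", 75_000_000, 75_030_000, 100),
                n_snps=3, ar1_rho=0.0, theta=0.005,
                effect_mean=-3.0, effect_sd=0.2, effect_decay=1.0,
            ),
        ),
    )
    study = simulate_dataset(cfg, seed=seed)
    exposure = study.exposures["exposure_1"]
    full = select_genomewide(exposure, study.outcome, study.ld)
    res = non_target_mr(
        study.exposures["exposure_1"], study.outcome, study.regions, study.ld,
        genomewide=full,
    )
    est = res.estimates["ivw_fe"]
    return {
        "genomewide_nsnp": full.nsnp,
        "non_target_nsnp": res.instrument_set.nsnp,
        "non_target_theta": est.theta,
        "non_target_or": est.or_scale[0],
    }
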