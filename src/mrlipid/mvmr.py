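"""Multivariable MR: joint-exposure IVW/Egger, conditional F, and MR-Lasso.

Multivariable MR regresses outcome effects on several exposures' SNP effects
jointly, so each exposure's coefficient is its direct effect conditional on
the others — the device behind the classic observation that HDL-C and TG
associations attenuate toward the null once LDL-C is modelled alongside them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .estimators import EstimatorError, MREstimate, _estimate, ivw_fit
from .instruments import InstrumentSet, LDMatrix, clump
from .gwas_io import SummaryRecord, harmonize

__all__ = [
    "MVInstrumentSet",
    "MVMRResult",
    "mvmr_ivw",
    "mvmr_egger",
    "conditional_f",
    "mr_lasso",
    "pool_instruments",
]


@dataclass
class MVInstrumentSet:
    """Pooled instruments: one row per SNP, K exposure-effect columns."""

    snp_ids: list[str]
    exposure_names: list[str]
    beta_exps: np.ndarray  # (nsnp, K)
    se_exps: np.ndarray  # (nsnp, K)
    beta_out: np.ndarray
    se_out: np.ndarray

    def __post_init__(self) -> None:
        self.beta_exps = np.atleast_2d(np.asarray(self.beta_exps, dtype=float))
        self.se_exps = np.atleast_2d(np.asarray(self.se_exps, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n, k = self.beta_exps.shape
        if k != len(self.exposure_names):
            raise ValueError("exposure_names length does not match beta_exps")
        if n != len(self.snp_ids):
            raise ValueError("snp_ids length does not match beta_exps")
        if np.any(self.se_exps <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def nsnp(self) -> int:
        return self.beta_exps.shape[0]

    @property
    def K(self) -> int:
        return self.beta_exps.shape[1]

    def subset(self, mask: np.ndarray) -> "MVInstrumentSet":
        ids = [s for s, m in zip(self.snp_ids, mask) if m]
        return MVInstrumentSet(
            ids,
            list(self.exposure_names),
            self.beta_exps[mask],
            self.se_exps[mask],
            self.beta_out[mask],
            self.se_out[mask],
        )


@dataclass
class MVMRResult:
    method: str
    exposure_names: list[str]
    estimates: list[MREstimate]
    nsnp: int
    Q: float
    Q_df: int
    Q_pval: float
    conditional_F: dict[str, float] = field(default_factory=dict)
    egger_intercept: tuple[float, float, float] | None = None  # (est, se, p)
    excluded_snps: list[str] = field(default_factory=list)

    def estimate_for(self, exposure: str) -> MREstimate:
        return self.estimates[self.exposure_names.index(exposure)]


def _wls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares; returns (coef, unscaled covariance, Q)."""
    Xw = X * w[:, None]
    A = X.T @ Xw
    rank = np.linalg.matrix_rank(A)
    if rank < X.shape[1]:
        raise EstimatorError(
            "rank-deficient exposure matrix (collinear exposures)"
        )
    cov = np.linalg.inv(A)
    coef = cov @ (Xw.T @ y)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    return coef, cov, Q


def mvmr_ivw(mvset: MVInstrumentSet) -> MVMRResult:
    """Multivariable IVW: WLS of beta_out on the exposure matrix, no intercept.

    SEs come from the weighted information matrix with multiplicative
    inflation max(1, sqrt(Q / (nsnp - K))).
    """
    n, K = mvset.nsnp, mvset.K
    if n <= K:
        raise EstimatorError(f"need nsnp > K ({n} <= {K})")
    w = 1.0 / mvset.se_out**2
    coef, cov, Q = _wls(mvset.beta_exps, mvset.beta_out, w)
    df = n - K
    infl = max(1.0, math.sqrt(Q / df))
    ses = np.sqrt(np.diag(cov)) * infl
    return MVMRResult(
        method="mvmr_ivw",
        exposure_names=list(mvset.exposure_names),
        estimates=[
            _estimate("mvmr_ivw", float(c), float(s), n)
            for c, s in zip(coef, ses)
        ],
        nsnp=n,
        Q=Q,
        Q_df=df,
        Q_pval=float(_stats.chi2.sf(Q, df)),
        conditional_F=conditional_f(mvset),
    )


def mvmr_egger(mvset: MVInstrumentSet, anchor: int = 0) -> MVMRResult:
    """Multivariable Egger: adds a common intercept column.

    SNPs are re-signed so the anchor exposure's betas are all >= 0 (the
    default anchor is the first exposure); the intercept captures average
    directional pleiotropy relative to that orientation.
    """
    n, K = mvset.nsnp, mvset.K
    if n <= K + 1:
        raise EstimatorError(f"Egger needs nsnp > K + 1 ({n} <= {K + 1})")
    sign = np.where(mvset.beta_exps[:, anchor] < 0, -1.0, 1.0)
    X = np.column_stack([mvset.beta_exps * sign[:, None], np.ones(n)])
    y = mvset.beta_out * sign
    w = 1.0 / mvset.se_out**2
    coef, cov, Q = _wls(X, y, w)
    df = n - K - 1
    infl = max(1.0, math.sqrt(Q / df))
    ses = np.sqrt(np.diag(cov)) * infl
    int_est, int_se = float(coef[-1]), float(ses[-1])
    int_p = float(2.0 * _stats.norm.sf(abs(int_est / int_se)))
    return MVMRResult(
        method="mvmr_egger",
        exposure_names=list(mvset.exposure_names),
        estimates=[
            _estimate("mvmr_egger", float(c), float(s), n)
            for c, s in zip(coef[:-1], ses[:-1])
        ],
        nsnp=n,
        Q=Q,
        Q_df=df,
        Q_pval=float(_stats.chi2.sf(Q, df)),
        egger_intercept=(int_est, int_se, int_p),
    )


def conditional_f(mvset: MVInstrumentSet) -> dict[str, float]:
    """Conditional instrument strength per exposure (Q-statistic form).

    For exposure k, its SNP effects are regressed on the other exposures'
    effects (weights 1/se_out^2); the conditional F is the weighted residual
    sum of squares, scaled by the exposure-side variances, divided by the
    instrument count: F_k = sum_j(delta_jk^2 / se_xjk^2) / nsnp.  Values
    below 10 flag conditionally weak instruments.
    """
    n, K = mvset.nsnp, mvset.K
    if K == 1:
        # univariable aggregate: mean per-SNP F
        F = float(np.mean((mvset.beta_exps[:, 0] / mvset.se_exps[:, 0]) ** 2))
        return {mvset.exposure_names[0]: F}
    if n <= K:
        raise EstimatorError(f"need nsnp > K ({n} <= {K})")
    w = 1.0 / mvset.se_out**2
    out: dict[str, float] = {}
    for k, name in enumerate(mvset.exposure_names):
        others = np.delete(mvset.beta_exps, k, axis=1)
        target = mvset.beta_exps[:, k]
        try:
            coef, _, _ = _wls(others, target, w)
            delta = target - others @ coef
        except EstimatorError:
            delta = target
        out[name] = float(np.sum(delta**2 / mvset.se_exps[:, k] ** 2) / n)
    return out


# ---------------------------------------------------------------------------
# MR-Lasso


def _lasso_path_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha0: np.ndarray,
    theta0: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic coordinate descent for per-SNP intercepts with an L1 penalty.

    Objective: sum_j w_j (y_j - alpha_j - X_j theta)^2 + lam * sum_j|alpha_j|.
    The theta update is exact WLS on the alpha-adjusted outcome; the alpha
    update is soft-thresholding of the weighted residual.
    """
    alpha = alpha0.copy()
    theta = theta0.copy()
    for _ in range(max_sweeps):
        theta_new, _, _ = _wls(X, y - alpha, w)
        r = y - X @ theta_new
        alpha_new = np.sign(r) * np.maximum(np.abs(r) - lam / (2.0 * w), 0.0)
        delta = max(
            float(np.max(np.abs(alpha_new - alpha), initial=0.0)),
            float(np.max(np.abs(theta_new - theta), initial=0.0)),
        )
        alpha, theta = alpha_new, theta_new
        if delta < tol:
            break
    return alpha, theta


def mr_lasso(
    mvset: MVInstrumentSet,
    lambda_grid: Sequence[float] | None = None,
    n_lambda: int = 100,
    alpha: float = 0.05,
) -> MVMRResult:
    """MR-Lasso: per-SNP pleiotropy intercepts shrunk by an L1 penalty.

    Valid SNPs are those whose intercept is zeroed.  The penalty is chosen by
    a heterogeneity rule: scanning lambda downward from the smallest value
    zeroing every intercept, stop at the first (largest) lambda whose valid
    set passes Cochran's Q at the ``alpha`` chi-square critical value — i.e.
    exclude as few SNPs as needed to remove detectable heterogeneity.  The
    final estimate is (mv)IVW on the valid set.
    """
    n, K = mvset.nsnp, mvset.K
    if n < K + 3:
        raise EstimatorError(f"MR-Lasso needs nsnp >= K + 3 ({n} < {K + 3})")
    X = mvset.beta_exps
    y = mvset.beta_out
    w = 1.0 / mvset.se_out**2
    theta_full, _, _ = _wls(X, y, w)
    resid = y - X @ theta_full
    lam_max = float(np.max(2.0 * w * np.abs(resid)))
    if lam_max == 0.0:
        lam_max = 1.0  # perfect fit; any lambda keeps everything valid
    if lambda_grid is None:
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if np.any(np.asarray(lambda_grid) <= 0):
        # free intercept for every SNP: nsnp + K parameters for nsnp rows
        raise EstimatorError("lambda = 0 leaves the model unidentified")

    alpha_hat = np.zeros(n)
    theta_hat = theta_full.copy()
    chosen_mask: np.ndarray | None = None
    best_mask: np.ndarray | None = None
    best_size = -1
    for lam in lambda_grid:
        alpha_hat, theta_hat = _lasso_path_fit(X, y, w, lam, alpha_hat, theta_hat)
        valid = np.abs(alpha_hat) < 1e-12
        nv = int(np.sum(valid))
        if nv > best_size:
            best_size, best_mask = nv, valid.copy()
        if nv <= K:
            continue
        sub = mvset.subset(valid)
        _, _, Q = _wls(sub.beta_exps, sub.beta_out, 1.0 / sub.se_out**2)
        crit = float(_stats.chi2.ppf(1.0 - alpha, nv - K))
        if Q <= crit:
            chosen_mask = valid
            break
    if chosen_mask is None:
        warnings.warn(
            "no lambda satisfied the heterogeneity rule; "
            "falling back to the largest valid set",
            stacklevel=2,
        )
        if best_mask is None or best_mask.sum() <= K:
            chosen_mask = np.ones(n, bool)  # keep everything: plain (mv)IVW
        else:
            chosen_mask = best_mask
    sub = mvset.subset(chosen_mask)
    result = mvmr_ivw(sub)
    excluded = [s for s, m in zip(mvset.snp_ids, chosen_mask) if not m]
    return MVMRResult(
        method="mr_lasso",
        exposure_names=result.exposure_names,
        estimates=[
            MREstimate("mr_lasso", e.theta, e.se, e.ci_low, e.ci_high, e.pval, e.nsnp)
            for e in result.estimates
        ],
        nsnp=sub.nsnp,
        Q=result.Q,
        Q_df=result.Q_df,
        Q_pval=result.Q_pval,
        conditional_F=result.conditional_F,
        excluded_snps=excluded,
    )


# ---------------------------------------------------------------------------
# pooled-instrument construction


def pool_instruments(
    exposures: dict[str, Sequence[SummaryRecord]],
    outcome: Sequence[SummaryRecord],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    palindrome_policy: str = "drop_ambiguous",
) -> MVInstrumentSet:
    """Pool genome-wide significant SNPs across exposures for MVMR.

    The union of per-exposure significant SNPs is re-clumped at the
    genome-wide r^2 threshold (p for clumping is each SNP's best p across
    exposures); every exposure's effect is then looked up for every retained
    SNP, and the outcome harmonized to the first exposure's orientation.
    """
    from .gwas_io import two_sided_p

    names = list(exposures)
    by_id: dict[str, dict[str, SummaryRecord]] = {
        name: {r.snp_id: r for r in recs} for name, recs in exposures.items()
    }
    union: dict[str, SummaryRecord] = {}
    best_p: dict[str, float] = {}
    for name, recs in exposures.items():
        for rec in recs:
            p = rec.pval if rec.pval is not None else two_sided_p(rec.beta / rec.se)
            if p < p_threshold and p < best_p.get(rec.snp_id, np.inf):
                union[rec.snp_id] = rec
                best_p[rec.snp_id] = p
    if not union:
        raise EstimatorError("no pooled instruments at threshold")
    pooled = [
        SummaryRecord(
            snp_id=r.snp_id, chrom=r.chrom, pos=r.pos,
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=r.eaf, beta=r.beta, se=r.se, pval=best_p[r.snp_id], n=r.n,
        )
        for r in union.values()
    ]
    retained = clump(pooled, ld, r2_threshold, window_kb)
    # require every exposure and the outcome to carry the SNP
    out_by_id = {r.snp_id: r for r in outcome}
    keep = [
        s for s in retained
        if s in out_by_id and all(s in by_id[name] for name in names)
    ]
    anchor = names[0]
    instruments, _ = harmonize(
        [by_id[anchor][s] for s in keep], list(outcome), palindrome_policy
    )
    rows_bx, rows_sx, ids = [], [], []
    by_out, se_out = [], []
    for h in instruments:
        bx_row, sx_row = [], []
        for name in names:
            rec = by_id[name][h.snp_id]
            sign = 1.0 if rec.effect_allele == h.effect_allele else -1.0
            if rec.effect_allele not in (h.effect_allele,):
                # resolve orientation against the anchor exposure's allele
                anchor_rec = by_id[anchor][h.snp_id]
                sign = 1.0 if rec.effect_allele == anchor_rec.effect_allele else -1.0
            bx_row.append(sign * rec.beta)
            sx_row.append(rec.se)
        rows_bx.append(bx_row)
        rows_sx.append(sx_row)
        ids.append(h.snp_id)
        by_out.append(h.beta_out)
        se_out.append(h.se_out)
    return MVInstrumentSet(
        snp_ids=ids,
        exposure_names=names,
        beta_exps=np.array(rows_bx),
        se_exps=np.array(rows_sx),
        beta_out=np.array(by_out),
        se_out=np.array(se_out),
    )
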