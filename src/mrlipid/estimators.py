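"""Univariable two-sample MR estimators and their diagnostics.

Every estimator consumes harmonized per-SNP summary effects: exposure betas
``bx`` (with SEs ``sx``) and outcome betas ``by`` on the log-odds scale (SEs
``sy``).  The causal effect ``theta`` is reported on log-odds per exposure
unit and exponentiated to an odds ratio for display.

Low-level ``*_fit`` functions operate on plain arrays (used by the simulation
and MR-PRESSO machinery); the public wrappers accept an
:class:`~mrlipid.instruments.InstrumentSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .gwas_io import HarmonizedInstrument
from .instruments import InstrumentSet

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "PleiotropyResult",
    "EstimatorError",
    "wald_ratio",
    "ivw",
    "ivw_fit",
    "egger",
    "egger_fit",
    "median_estimator",
    "weighted_median_fit",
    "leave_one_out",
    "scatter_funnel_tables",
]

_Z95 = 1.959963984540054


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate: log-OR per unit of exposure, with 95% CI."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — elementwise exp of (theta, ci)."""
        return (math.exp(self.theta), math.exp(self.ci_low), math.exp(self.ci_high))

    def format_or(self, digits: int = 3) -> str:
        o, lo, hi = self.or_scale
        return f"{o:.{digits}f} ({lo:.{digits}f},{hi:.{digits}f})"


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


def _normal_p(z: float) -> float:
    return float(2.0 * _stats.norm.sf(abs(z)))


def _estimate(method: str, theta: float, se: float, nsnp: int) -> MREstimate:
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - _Z95 * se),
        ci_high=float(theta + _Z95 * se),
        pval=_normal_p(theta / se) if se > 0 else 1.0,
        nsnp=int(nsnp),
    )


# ---------------------------------------------------------------------------
# Wald ratio


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Per-SNP ratio estimate with the first-order delta-method SE.

    theta = beta_out / beta_exp, se = se_out / |beta_exp|.  A second-order SE
    (adding exposure-side uncertainty) is available via ``second_order``
    keyword on :func:`wald_ratio_value`.
    """
    if instrument.beta_exp == 0:
        raise EstimatorError(f"{instrument.snp_id}: null instrument (beta_exp = 0)")
    theta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return _estimate("wald", theta, se, 1)


def wald_ratio_value(
    bx: float, by: float, sx: float, sy: float, second_order: bool = False
) -> tuple[float, float]:
    if bx == 0:
        raise EstimatorError("null instrument (beta_exp = 0)")
    theta = by / bx
    se = sy / abs(bx)
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return theta, se


# ---------------------------------------------------------------------------
# IVW


def ivw_fit(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float]:
    """Closed-form IVW: weighted regression of by on bx through the origin.

    Returns (theta, fixed-effect SE, Cochran Q).  Weights are 1/sy^2; this is
    algebraically identical to the inverse-variance-weighted mean of Wald
    ratios.
    """
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sxx = float(np.sum(w * bx * bx))
    if sxx <= 0:
        raise EstimatorError("all exposure effects are zero")
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    Q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, Q


def ivw(
    iset: InstrumentSet, model: str = "fixed"
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate, the primary MR method.

    ``model="fixed"`` uses the fixed-effect SE; ``"multiplicative_random"``
    inflates it by max(1, sqrt(Q / (nsnp - 1))).  With a single instrument
    this delegates to the Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW model {model!r}")
    n = iset.nsnp
    if n == 0:
        raise EstimatorError("empty instrument set")
    if n == 1:
        est = wald_ratio(iset.instruments[0])
        return (
            MREstimate("ivw_fe" if model == "fixed" else "ivw_mre",
                       est.theta, est.se, est.ci_low, est.ci_high, est.pval, 1),
            HeterogeneityResult(0.0, 0, 1.0),
        )
    bx, _, by, sy = iset.arrays()
    theta, se, Q = ivw_fit(bx, by, sy)
    df = n - 1
    if model == "multiplicative_random":
        se *= max(1.0, math.sqrt(Q / df))
        label = "ivw_mre"
    else:
        label = "ivw_fe"
    het = HeterogeneityResult(Q, df, float(_stats.chi2.sf(Q, df)))
    return _estimate(label, theta, se, n), het


# ---------------------------------------------------------------------------
# MR-Egger


def egger_fit(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Weighted regression of by on bx with a free intercept.

    Instruments are re-oriented so all bx >= 0 (the estimate is invariant to
    the arbitrary allele orientation only after this convention).  Returns
    (slope, slope SE, intercept, intercept SE, Q); both SEs carry the
    multiplicative inflation max(1, sqrt(Q / (n - 2))).
    """
    bx = np.asarray(bx, dtype=float).copy()
    by = np.asarray(by, dtype=float).copy()
    sy = np.asarray(sy, dtype=float)
    n = bx.size
    if n < 3:
        raise EstimatorError("Egger requires >=3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx *= sign
    by *= sign
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimatorError("degenerate design (constant exposure effects)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    Q = float(np.sum(w * resid**2))
    infl = max(1.0, math.sqrt(Q / (n - 2)))
    se_slope = math.sqrt(sw / det) * infl
    se_int = math.sqrt(swxx / det) * infl
    return slope, se_slope, intercept, se_int, Q


def egger(
    iset: InstrumentSet, ci: str = "normal"
) -> tuple[MREstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger regression: pleiotropy-adjusted slope plus intercept test.

    The intercept estimates the average directional pleiotropic effect; a
    two-sided test against zero is reported.  CIs use the normal
    approximation by default (``ci="t"`` switches to t with nsnp-2 df).
    """
    n = iset.nsnp
    bx, _, by, sy = iset.arrays()
    slope, se_slope, intercept, se_int, Q = egger_fit(bx, by, sy)
    df = n - 2
    if ci == "t":
        crit = float(_stats.t.ppf(0.975, df))
        p_slope = float(2.0 * _stats.t.sf(abs(slope / se_slope), df))
        p_int = float(2.0 * _stats.t.sf(abs(intercept / se_int), df))
    elif ci == "normal":
        crit = _Z95
        p_slope = _normal_p(slope / se_slope)
        p_int = _normal_p(intercept / se_int)
    else:
        raise EstimatorError(f"unknown ci type {ci!r}")
    est = MREstimate(
        "egger", slope, se_slope,
        slope - crit * se_slope, slope + crit * se_slope, p_slope, n,
    )
    pleio = PleiotropyResult(intercept, se_int, p_int)
    het = HeterogeneityResult(Q, df, float(_stats.chi2.sf(Q, df)))
    return est, pleio, het


# ---------------------------------------------------------------------------
# medians


def weighted_median_fit(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of standardized cumulative
    weights s_j = (cumsum(w) - w/2) / sum(w), evaluated at 0.5."""
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (n_samples, nsnp) arrays (bootstrap)."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cw = np.cumsum(w, axis=1)
    s = (cw - 0.5 * w) / cw[:, -1:]
    # per-row linear interpolation at 0.5
    idx = np.sum(s < 0.5, axis=1)
    idx = np.clip(idx, 1, s.shape[1] - 1)
    rows = np.arange(s.shape[0])
    s0 = s[rows, idx - 1]
    s1 = s[rows, idx]
    r0 = r[rows, idx - 1]
    r1 = r[rows, idx]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out = r0 + frac * (r1 - r0)
    # rows where 0.5 falls outside the s grid take the boundary ratio
    out = np.where(s[rows, 0] >= 0.5, r[rows, 0], out)
    out = np.where(s[rows, -1] < 0.5, r[rows, -1], out)
    return out


def median_estimator(
    iset: InstrumentSet,
    weighting: str = "weighted",
    n_boot: int = 1000,
    seed: int = 0,
    bootstrap: str = "model",
) -> MREstimate:
    """Simple or weighted median of per-SNP Wald ratios.

    ``simple`` uses equal weights; ``weighted`` uses inverse-variance weights
    of the ratios.  The SE comes from a parametric bootstrap (seeded;
    ``n_boot=0`` skips it and reports NaN SE for point-estimate-only uses).

    ``bootstrap="model"`` (default) resamples the outcome betas around the
    fitted homogeneous model, by* ~ normal(theta_hat * beta_exp, se_out).
    Centering draws on the observed betas instead (``bootstrap="observed"``)
    convolves the sampling noise twice: the cross-sectional spread of the
    resampled ratios is ~sqrt(2) too wide near the median, which inflates
    the median's bootstrap SE by ~15-20% and makes its test measurably
    conservative.  Exposure betas are resampled around their observed
    values under both schemes.
    """
    if weighting not in ("simple", "weighted"):
        raise EstimatorError(f"unknown weighting {weighting!r}")
    if bootstrap not in ("model", "observed"):
        raise EstimatorError(f"unknown bootstrap centering {bootstrap!r}")
    n = iset.nsnp
    if n < 3:
        raise EstimatorError("median estimators require >=3 instruments")
    bx, sx, by, sy = iset.arrays()
    theta = _median_point(bx, by, sy, weighting)
    if n_boot <= 0:
        return MREstimate(
            f"{weighting}_median", float(theta), float("nan"),
            float("nan"), float("nan"), float("nan"), n,
        )
    rng = np.random.default_rng(seed)
    centre = theta * bx if bootstrap == "model" else by
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(centre, sy, size=(n_boot, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by_b / bx_b
        if weighting == "simple":
            weights = np.ones_like(ratios)
        else:
            weights = (bx_b / sy) ** 2
    boots = _weighted_median_rows(ratios, weights)
    se = float(np.std(boots, ddof=1))
    return _estimate(f"{weighting}_median", theta, se, n)


def _median_point(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, weighting: str
) -> float:
    ratios = by / bx
    if weighting == "simple":
        weights = np.ones_like(ratios)
    else:
        weights = (bx / sy) ** 2  # inverse variance of the ratio (first order)
    return weighted_median_fit(ratios, weights)


# ---------------------------------------------------------------------------
# leave-one-out and plot tables


def leave_one_out(iset: InstrumentSet, model: str = "fixed") -> list[dict]:
    """IVW recomputed with each SNP excluded in turn.

    Each row carries the excluded SNP, the re-estimate, and a flag set when
    the exclusion changes the sign of theta or moves it by more than the
    full-set CI half-width.
    """
    n = iset.nsnp
    if n < 3:
        raise EstimatorError("leave-one-out requires >=3 instruments")
    full, _ = ivw(iset, model=model)
    half_width = (full.ci_high - full.ci_low) / 2.0
    bx, _, by, sy = iset.arrays()
    rows = []
    for j, snp in enumerate(iset.snp_ids):
        mask = np.arange(n) != j
        theta, se, Q = ivw_fit(bx[mask], by[mask], sy[mask])
        if model == "multiplicative_random":
            se *= max(1.0, math.sqrt(Q / (n - 2)))
        est = _estimate(full.method, theta, se, n - 1)
        flagged = (
            math.copysign(1, est.theta) != math.copysign(1, full.theta)
            or abs(est.theta - full.theta) > half_width
        )
        rows.append(
            {
                "excluded_snp": snp,
                "theta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "delta_theta": est.theta - full.theta,
                "flagged": flagged,
            }
        )
    return rows


def scatter_funnel_tables(
    iset: InstrumentSet, estimates: list[MREstimate] | None = None
) -> tuple["pd.DataFrame", "pd.DataFrame", "pd.DataFrame"]:
    """Plot-ready tables: per-SNP scatter, funnel, and fitted method lines."""
    import pandas as pd

    if iset.nsnp == 0:
        raise EstimatorError("empty instrument set")
    bx, sx, by, sy = iset.arrays()
    ratios = by / bx
    ratio_se = sy / np.abs(bx)
    scatter = pd.DataFrame(
        {
            "snp_id": iset.snp_ids,
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": by,
            "se_out": sy,
        }
    )
    funnel = pd.DataFrame(
        {
            "snp_id": iset.snp_ids,
            "ratio": ratios,
            "precision": 1.0 / ratio_se,
        }
    )
    if estimates is None:
        est, _ = ivw(iset)
        estimates = [est]
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.theta for e in estimates],
        }
    )
    return scatter, funnel, lines
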