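"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a lipid-exposure /
binary-outcome MR study: per-SNP exposure effects (multivariate across K
correlated lipid traits, in the traits' native units, e.g. mg/dL), a planted
causal effect on the outcome's log-odds, balanced or directional pleiotropy,
outlier SNPs with large direct effects, block-structured LD at the
effect-correlation level, gene-region (cis) blocks tagging a shared causal
variant, and a PhenoScanner-style confounder lookup.

Standard errors follow the usual summary-statistic approximations:

    se_x = trait_sd / sqrt(2 maf (1-maf) n_exp)
    se_y = 1 / sqrt(2 maf (1-maf) n_out phi (1-phi))

with ``phi`` the outcome case fraction.  Observed betas are drawn normal
around the truth with those SEs; the ground-truth identity
``beta_y = sum_k theta_k beta_x_k + alpha`` holds exactly for the true
effects.  Everything is deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .gwas_io import SummaryRecord
from .instruments import ConfounderTable, GeneRegion, LDMatrix

__all__ = [
    "PleiotropySpec",
    "RegionSpec",
    "SimulationConfig",
    "SimTruth",
    "SimulatedStudy",
    "simulate_arrays",
    "simulate_dataset",
    "paper_like_config",
    "median_robust_config",
    "mvmr_attenuation_config",
    "egger_power_config",
    "AMI_CASE_FRACTION",
]

#: case proportion of the emulated outcome GWAS (3,927 cases / 337,199 total)
AMI_CASE_FRACTION = 3927 / 337199

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct (non-mediated) SNP effects on the outcome.

    ``kind``: "none", "balanced" (zero-mean) or "directional" (non-zero
    mean).  ``proportion`` of SNPs are affected.  When ``oriented`` the
    pleiotropic effect is aligned with the exposure-increasing allele of the
    first exposure, which is what makes a non-zero mean *directional* for
    estimators that re-orient instruments.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    proportion: float = 0.0
    oriented: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must be in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy has zero mean")


@dataclass(frozen=True)
class RegionSpec:
    """A cis block: n_snps tagging one causal variant with AR(1) LD decay.

    ``effect_decay`` controls how fast true exposure effects shrink away
    from the block centre; it is deliberately slower than the LD decay
    (``ar1_rho``) so that a realistic number of block SNPs clears the
    genome-wide threshold while clumping still thins the block.
    """

    region: GeneRegion
    n_snps: int
    ar1_rho: float = 0.4
    theta: float | None = None  # overrides the first exposure's causal effect
    effect_mean: float = -3.0  # lead per-allele effect on exposure 1 (units)
    effect_sd: float = 0.3
    effect_decay: float = 0.85

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("region must contain at least one SNP")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if not (0.0 < self.effect_decay <= 1.0):
            raise ValueError("effect_decay must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sample dataset."""

    n_snps: int = 100
    n_exp: int = 300_000
    n_out: int = 337_199
    case_fraction: float = AMI_CASE_FRACTION
    theta: tuple[float, ...] = (0.006,)
    exposure_names: tuple[str, ...] | None = None
    trait_sd: tuple[float, ...] = (38.67,)  # one SD of each trait, in units
    exposure_effect_mean: tuple[float, ...] | float = 0.0
    exposure_effect_sd: tuple[float, ...] | float = 2.5
    exposure_corr: np.ndarray | None = None
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    n_outliers: int = 0
    outlier_effect: float = 0.0
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    regions: tuple[RegionSpec, ...] = ()
    confounder_fraction: float = 0.0
    confounder_labels: tuple[str, ...] = ("hypertension", "systolic blood pressure")
    palindromic_fraction: float = 0.0
    seed: int | None = None

    @property
    def K(self) -> int:
        return len(self.theta)

    def names(self) -> list[str]:
        if self.exposure_names is not None:
            return list(self.exposure_names)
        return [f"exposure_{k + 1}" for k in range(self.K)]

    def _vec(self, value, name: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.K,)).copy()
        return arr

    def validate(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if self.n_snps == 0 and not self.regions:
            raise ValueError("infeasible config: no SNPs at all")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if len(self.trait_sd) != self.K:
            raise ValueError("trait_sd length must match theta")
        if np.any(self._vec(self.exposure_effect_sd, "sd") < 0):
            raise ValueError("exposure_effect_sd must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.exposure_corr is not None:
            C = np.asarray(self.exposure_corr, dtype=float)
            if C.shape != (self.K, self.K):
                raise ValueError("exposure_corr must be K x K")
            if not np.allclose(C, C.T):
                raise ValueError("exposure_corr must be symmetric")
            if np.min(np.linalg.eigvalsh(C)) <= 0:
                raise ValueError("exposure_corr must be positive definite")
        if not (0.0 <= self.confounder_fraction <= 1.0):
            raise ValueError("confounder_fraction must be in [0, 1]")
        if self.n_outliers > self.n_snps:
            raise ValueError("infeasible config: more outliers than SNPs")


@dataclass
class SimTruth:
    """Ground truth against which estimator recovery is tested."""

    theta: tuple[float, ...]
    region_theta: dict[str, float]
    snp_ids: list[str]
    alpha: np.ndarray
    outlier_ids: list[str]
    beta_x: np.ndarray  # (n, K) true per-allele exposure effects
    beta_y: np.ndarray  # (n,) true outcome effects
    effective_theta: np.ndarray  # (n, K) per-SNP causal coefficients

    def identity_residual(self) -> np.ndarray:
        """beta_y - (sum_k effective_theta_k * beta_x_k + alpha) (exactly 0)."""
        mediated = np.sum(self.effective_theta * self.beta_x, axis=1)
        return self.beta_y - (mediated + self.alpha)


@dataclass
class SimArrays:
    maf: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    bx_true: np.ndarray  # (n, K)
    bx_obs: np.ndarray
    sx: np.ndarray
    by_true: np.ndarray
    by_obs: np.ndarray
    sy: np.ndarray
    alpha: np.ndarray
    outlier_idx: np.ndarray
    region_idx: np.ndarray  # -1 for background SNPs
    effective_theta: np.ndarray


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    exposures: dict[str, list[SummaryRecord]]
    outcome: list[SummaryRecord]
    ld: LDMatrix
    regions: list[GeneRegion]
    confounders: ConfounderTable
    truth: SimTruth
    arrays: SimArrays


def _block_sizes(n: int, ld_blocks: Sequence[tuple[int, float]]):
    """Tile the configured (size, rho) blocks across n background SNPs."""
    if not ld_blocks:
        return [(1, 0.0)] * n
    out = []
    total = 0
    i = 0
    while total < n:
        size, rho = ld_blocks[i % len(ld_blocks)]
        size = min(size, n - total)
        out.append((size, rho))
        total += size
        i += 1
    return out


def _ar1(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_arrays(config: SimulationConfig, rng: np.random.Generator) -> SimArrays:
    """Core array-level simulation (no record objects; fast path for sims)."""
    config.validate()
    K = config.K
    n_bg = config.n_snps
    region_sizes = [r.n_snps for r in config.regions]
    n = n_bg + sum(region_sizes)

    maf = rng.uniform(*config.maf_range, size=n)
    het = 2.0 * maf * (1.0 - maf)
    trait_sd = np.asarray(config.trait_sd, dtype=float)
    sx = trait_sd[None, :] / np.sqrt(het[:, None] * config.n_exp)
    phi = config.case_fraction
    sy = 1.0 / np.sqrt(het * config.n_out * phi * (1.0 - phi))

    # true exposure effects: background SNPs multivariate across K
    mean = config._vec(config.exposure_effect_mean, "mean")
    sd = config._vec(config.exposure_effect_sd, "sd")
    C = (
        np.eye(K)
        if config.exposure_corr is None
        else np.asarray(config.exposure_corr, dtype=float)
    )
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((n_bg, K)) @ L.T
    signs = rng.choice([-1.0, 1.0], size=n_bg)
    bx_true = np.zeros((n, K))
    bx_true[:n_bg] = signs[:, None] * (mean[None, :] + sd[None, :] * z)

    # positions: background SNPs round-robin over autosomes, 1 Mb apart
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=int)
    for i in range(n_bg):
        chrom[i] = str(i % 22 + 1)
        pos[i] = 10_000_000 + (i // 22) * 1_000_000

    # region blocks: each SNP tags a shared causal variant with AR(1) decay
    region_idx = np.full(n, -1, dtype=int)
    effective_theta = np.tile(np.asarray(config.theta, float), (n, 1))
    offset = n_bg
    for ri, rspec in enumerate(config.regions):
        m = rspec.n_snps
        rows = slice(offset, offset + m)
        region_idx[offset:offset + m] = ri
        lead = rng.normal(rspec.effect_mean, rspec.effect_sd)
        center = m // 2
        decay = rspec.effect_decay ** np.abs(np.arange(m) - center)
        bx_true[rows, 0] = lead * decay
        reg = rspec.region
        pos[rows] = np.sort(
            rng.integers(reg.start, reg.end + 1, size=m)
        )
        chrom[offset:offset + m] = reg.chrom
        if rspec.theta is not None:
            effective_theta[rows, 0] = rspec.theta
        offset += m

    # pleiotropy and outliers (background SNPs only; cis blocks stay clean)
    alpha = np.zeros(n)
    pl = config.pleiotropy
    if pl.kind != "none" and pl.proportion > 0 and n_bg > 0:
        n_pleio = int(round(pl.proportion * n_bg))
        idx = rng.choice(n_bg, size=n_pleio, replace=False)
        draws = rng.normal(pl.mean, pl.sd, size=n_pleio)
        if pl.oriented:
            s = np.sign(bx_true[idx, 0])
            s[s == 0] = 1.0
            draws = draws * s
        alpha[idx] = draws
    outlier_idx = np.array([], dtype=int)
    if config.n_outliers > 0:
        outlier_idx = rng.choice(n_bg, size=config.n_outliers, replace=False)
        alpha[outlier_idx] = alpha[outlier_idx] + config.outlier_effect

    by_true = np.sum(effective_theta * bx_true, axis=1) + alpha

    # observed effects: noise correlated within LD blocks (effect-level LD)
    blocks = _block_sizes(n_bg, config.ld_blocks) + [
        (r.n_snps, r.ar1_rho) for r in config.regions
    ]
    bx_obs = np.empty_like(bx_true)
    by_obs = np.empty_like(by_true)
    start = 0
    for size, rho in blocks:
        rows = slice(start, start + size)
        if size == 1 or rho == 0.0:
            ex = rng.standard_normal((size, K))
            ey = rng.standard_normal(size)
        else:
            Lb = np.linalg.cholesky(_ar1(size, rho))
            ex = Lb @ rng.standard_normal((size, K))
            ey = Lb @ rng.standard_normal(size)
        bx_obs[rows] = bx_true[rows] + ex * sx[rows]
        by_obs[rows] = by_true[rows] + ey * sy[rows]
        start += size

    return SimArrays(
        maf=maf, chrom=chrom, pos=pos,
        bx_true=bx_true, bx_obs=bx_obs, sx=sx,
        by_true=by_true, by_obs=by_obs, sy=sy,
        alpha=alpha, outlier_idx=outlier_idx, region_idx=region_idx,
        effective_theta=effective_theta,
    )


def _ld_matrix(config: SimulationConfig, snp_ids: list[str]) -> LDMatrix:
    n_bg = config.n_snps
    blocks = _block_sizes(n_bg, config.ld_blocks) + [
        (r.n_snps, r.ar1_rho) for r in config.regions
    ]
    n = len(snp_ids)
    R = np.eye(n)
    start = 0
    for size, rho in blocks:
        if size > 1 and rho != 0.0:
            R[start:start + size, start:start + size] = _ar1(size, rho)
        start += size
    return LDMatrix(snp_ids, R)


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedStudy:
    """Generate a full synthetic study: records, LD, regions, truth.

    The outcome records are presented with randomized allele orientation
    (identical, swapped, or strand-complemented relative to the exposure
    file) so that harmonization is genuinely exercised end-to-end.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    arr = simulate_arrays(config, rng)
    n = arr.maf.size
    K = config.K
    names = config.names()
    snp_ids = [f"rs{100000 + i}" for i in range(n)]

    # allele pairs
    pairs = []
    for i in range(n):
        if arr.region_idx[i] < 0 and rng.uniform() < config.palindromic_fraction:
            pairs.append(_PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))])
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])

    eaf_out = np.clip(
        arr.maf + rng.normal(0.0, 0.005, size=n), 0.001, 0.999
    )

    exposures: dict[str, list[SummaryRecord]] = {name: [] for name in names}
    outcome: list[SummaryRecord] = []
    z_out = arr.by_obs / arr.sy
    p_out = 2.0 * _stats.norm.sf(np.abs(z_out))
    for k, name in enumerate(names):
        zk = arr.bx_obs[:, k] / arr.sx[:, k]
        pk = 2.0 * _stats.norm.sf(np.abs(zk))
        sd_note = f"1 SD = {config.trait_sd[k]:g} units"
        for i in range(n):
            ea, oa = pairs[i]
            exposures[name].append(
                SummaryRecord(
                    snp_id=snp_ids[i], chrom=str(arr.chrom[i]), pos=int(arr.pos[i]),
                    effect_allele=ea, other_allele=oa,
                    eaf=float(arr.maf[i]),
                    beta=float(arr.bx_obs[i, k]), se=float(arr.sx[i, k]),
                    pval=float(max(pk[i], 5e-324)), n=config.n_exp,
                    sd_units=sd_note,
                )
            )
    presentation = rng.integers(0, 3, size=n)  # 0 same, 1 swapped, 2 complement
    for i in range(n):
        ea, oa = pairs[i]
        beta, eaf = float(arr.by_obs[i]), float(eaf_out[i])
        mode = presentation[i]
        if ea == _COMPLEMENT[oa]:
            mode = 0  # palindromic: present as-is; policies handle ambiguity
        if mode == 1:
            ea, oa = oa, ea
            beta, eaf = -beta, 1.0 - eaf
        elif mode == 2:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        outcome.append(
            SummaryRecord(
                snp_id=snp_ids[i], chrom=str(arr.chrom[i]), pos=int(arr.pos[i]),
                effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=beta, se=float(arr.sy[i]),
                pval=float(max(p_out[i], 5e-324)), n=config.n_out,
            )
        )

    confounders: dict[str, list[str]] = {}
    if config.confounder_fraction > 0:
        n_conf = int(round(config.confounder_fraction * n))
        for i in rng.choice(n, size=n_conf, replace=False):
            label = config.confounder_labels[
                rng.integers(len(config.confounder_labels))
            ]
            confounders[snp_ids[i]] = [label]

    truth = SimTruth(
        theta=tuple(config.theta),
        region_theta={
            r.region.gene: (r.theta if r.theta is not None else config.theta[0])
            for r in config.regions
        },
        snp_ids=snp_ids,
        alpha=arr.alpha,
        outlier_ids=[snp_ids[i] for i in arr.outlier_idx],
        beta_x=arr.bx_true,
        beta_y=arr.by_true,
        effective_theta=arr.effective_theta,
    )
    return SimulatedStudy(
        config=config,
        exposures=exposures,
        outcome=outcome,
        ld=_ld_matrix(config, snp_ids),
        regions=[r.region for r in config.regions],
        confounders=ConfounderTable(confounders),
        truth=truth,
        arrays=arr,
    )


# ---------------------------------------------------------------------------
# named study conditions


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """A three-lipid study shaped like the emulated design.

    Background effect-size scales are set so that genome-wide selection at
    p < 5e-8 / r^2 < 0.001 lands near 107 (LDL-C), 106 (HDL-C) and 68 (TG)
    instruments, and the three cis blocks near 5 (HMGCR), 11 (PCSK9) and
    3 (NPC1L1) SNPs at their per-gene clumping thresholds — the counts are
    emergent from selection, not hard-coded.
    """
    regions = (
        RegionSpec(
            region=GeneRegion("HMGCR", "5", 75_000_000, 75_030_000, 100),
            n_snps=9, ar1_rho=0.5, effect_mean=-3.0, effect_sd=0.3,
        ),
        RegionSpec(
            region=GeneRegion("PCSK9", "1", 55_500_000, 55_530_000, 100),
            n_snps=11, ar1_rho=0.4, effect_mean=-4.0, effect_sd=0.4,
        ),
        RegionSpec(
            region=GeneRegion("NPC1L1", "7", 44_550_000, 44_580_000, 100),
            n_snps=3, ar1_rho=0.5, effect_mean=-2.5, effect_sd=0.3,
        ),
    )
    corr = np.array(
        [
            [1.0, -0.5, 0.45],
            [-0.5, 1.0, -0.45],
            [0.45, -0.45, 1.0],
        ]
    )
    return SimulationConfig(
        n_snps=132,
        n_exp=300_000,
        n_out=337_199,
        case_fraction=AMI_CASE_FRACTION,
        theta=(0.005, 0.0, 0.0),
        exposure_names=("LDL-C", "HDL-C", "TG"),
        trait_sd=(38.67, 15.51, 90.72),
        exposure_effect_mean=0.0,
        exposure_effect_sd=(2.5, 1.2, 2.2),
        exposure_corr=corr,
        pleiotropy=PleiotropySpec("none"),
        maf_range=(0.05, 0.5),
        regions=regions,
        confounder_fraction=0.02,
        palindromic_fraction=0.0,
        seed=seed,
    )


def median_robust_config(n_snps: int = 100) -> SimulationConfig:
    """Directional-pleiotropy conditions for the median-robustness check.

    30% of instruments carry oriented direct effects with a small positive
    mean and a large spread.  A design-stage power calculation (see docs)
    places this in the regime where the IVW mean is measurably biased while
    the weighted median, which down-weights the dispersed invalid ratios,
    stays centred on the truth.  Effects are drawn as +-N(2.5, 0.8) per
    allele, mimicking instruments that already passed genome-wide selection.
    """
    return SimulationConfig(
        n_snps=n_snps,
        theta=(0.006,),
        exposure_effect_mean=2.5,
        exposure_effect_sd=0.8,
        pleiotropy=PleiotropySpec(
            "directional", mean=0.0045, sd=0.085, proportion=0.3, oriented=True
        ),
    )


def mvmr_attenuation_config(n_snps: int = 150) -> SimulationConfig:
    """Three correlated lipid exposures with direct effects (0.005, 0, 0).

    Per-SNP effects across the three traits share a random sign and have
    non-zero mean magnitudes, so every instrument's HDL-like and TG-like
    effects are aligned with its LDL-like effect — the structure that makes
    univariable MR on the null exposures pick up the first exposure's signal
    and that multivariable MR removes.  The exposure panel is GLGC-sized
    (n = 1e6) and the outcome panel balanced case-control, so conditional
    instrument strength is high and the attenuation contrast reflects the
    estimator, not sampling noise.
    """
    corr = np.array(
        [
            [1.0, -0.3, 0.3],
            [-0.3, 1.0, -0.3],
            [0.3, -0.3, 1.0],
        ]
    )
    return SimulationConfig(
        n_snps=n_snps,
        n_exp=1_000_000,
        n_out=400_000,
        case_fraction=0.5,
        theta=(0.005, 0.0, 0.0),
        exposure_names=("LDL-C", "HDL-C", "TG"),
        trait_sd=(38.67, 15.51, 90.72),
        exposure_effect_mean=(2.5, 1.5, 3.2),
        exposure_effect_sd=(0.8, 0.5, 1.0),
        exposure_corr=corr,
    )


def egger_power_config(n_snps: int = 100) -> SimulationConfig:
    """Strong one-sided pleiotropy conditions for the Egger intercept test.

    30% of instruments carry oriented direct effects of ~0.10 on the
    log-odds scale; with ~100 instruments of dispersed strength this gives
    the intercept test around 90% power at alpha = 0.05 (design-stage
    calculation in docs).
    """
    return SimulationConfig(
        n_snps=n_snps,
        theta=(0.006,),
        exposure_effect_mean=0.0,
        exposure_effect_sd=2.5,
        pleiotropy=PleiotropySpec(
            "directional", mean=0.10, sd=0.02, proportion=0.3, oriented=True
        ),
    )
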