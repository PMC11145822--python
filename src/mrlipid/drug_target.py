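"""Drug-target (cis) MR: per-gene instruments, combinations, non-target set.

Variants at or near a drug's target gene proxy pharmacological modulation of
the target: HMGCR for statins, PCSK9 for evolocumab, NPC1L1 for ezetimibe.
Each gene gets its own relaxed clumping threshold so that at least three
variants remain; combinations pool two genes' instruments; the non-target
analysis removes every region instrument from the genome-wide set to probe
pathways outside the drug targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .estimators import (
    EstimatorError,
    HeterogeneityResult,
    MREstimate,
    PleiotropyResult,
    _estimate,
    egger,
    ivw,
    leave_one_out,
    median_estimator,
)
from .gwas_io import SummaryRecord
from .instruments import (
    GeneRegion,
    InstrumentSet,
    LDMatrix,
    select_genomewide,
    select_region,
    steiger_filter,
)

__all__ = [
    "DrugTargetSpec",
    "DrugTargetResult",
    "DEFAULT_REGION_R2",
    "drug_target_mr",
    "combination_mr",
    "non_target_mr",
    "ivw_gls",
]

#: per-gene clumping thresholds: r^2 < 0.2 for HMGCR/PCSK9, < 0.3 for NPC1L1
DEFAULT_REGION_R2 = {"HMGCR": 0.2, "PCSK9": 0.2, "NPC1L1": 0.3}


@dataclass(frozen=True)
class DrugTargetSpec:
    drug: str  # statin | evolocumab | ezetimibe | ...
    region: GeneRegion
    r2_threshold: float | None = None

    @property
    def clump_r2(self) -> float:
        if self.r2_threshold is not None:
            return self.r2_threshold
        return DEFAULT_REGION_R2.get(self.region.gene, 0.2)


@dataclass
class DrugTargetResult:
    drugs: list[str]
    genes: list[str]
    instrument_set: InstrumentSet
    estimates: dict[str, MREstimate]
    heterogeneity: HeterogeneityResult
    egger_intercept: PleiotropyResult | None
    leave_one_out: list[dict]
    gls_estimate: MREstimate | None = None
    notes: list[str] = field(default_factory=list)


def ivw_gls(iset: InstrumentSet, ld: LDMatrix) -> MREstimate:
    """IVW with the instruments' residual LD in the weight matrix.

    Generalized weighted least squares with Omega_ij = se_i se_j rho_ij; with
    an identity LD matrix this reduces exactly to the independent-instrument
    IVW.  Clumping at relaxed cis thresholds leaves residual correlation that
    inflates the independent-mode precision, so the difference between the
    two modes is itself a diagnostic.
    """
    bx, _, by, sy = iset.arrays()
    sub = ld.submatrix(iset.snp_ids)
    omega = np.outer(sy, sy) * sub.r
    oinv = np.linalg.inv(omega)
    denom = float(bx @ oinv @ bx)
    if denom <= 0:
        raise EstimatorError("degenerate GLS system")
    theta = float(bx @ oinv @ by) / denom
    se = denom**-0.5
    return _estimate("ivw_gls", theta, se, iset.nsnp)


def _battery(
    iset: InstrumentSet,
    seed: int = 0,
    n_boot: int = 1000,
) -> tuple[dict[str, MREstimate], HeterogeneityResult, PleiotropyResult | None, list[dict], list[str]]:
    """IVW always; Egger/medians/leave-one-out where nsnp permits."""
    notes: list[str] = []
    estimates: dict[str, MREstimate] = {}
    est_ivw, het = ivw(iset, model="fixed")
    estimates["ivw_fe"] = est_ivw
    est_mre, _ = ivw(iset, model="multiplicative_random")
    estimates["ivw_mre"] = est_mre
    pleio = None
    if iset.nsnp >= 3:
        est_egger, pleio, _ = egger(iset)
        estimates["egger"] = est_egger
    else:
        notes.append(f"Egger skipped: {iset.nsnp} < 3 instruments")
    if iset.nsnp >= 4:
        estimates["simple_median"] = median_estimator(
            iset, "simple", n_boot=n_boot, seed=seed
        )
        estimates["weighted_median"] = median_estimator(
            iset, "weighted", n_boot=n_boot, seed=seed + 1
        )
    else:
        notes.append(
            f"median estimators skipped: {iset.nsnp} instruments give an "
            "uninformative median"
        )
    loo = leave_one_out(iset) if iset.nsnp >= 3 else []
    return estimates, het, pleio, loo, notes


def drug_target_mr(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    spec: DrugTargetSpec,
    ld: LDMatrix,
    correlation_mode: str = "independent",
    p_threshold: float = 5e-8,
    min_snps: int = 3,
    apply_steiger: bool = True,
    seed: int = 0,
) -> DrugTargetResult:
    """Cis MR for one drug target: select_region -> Steiger -> estimators.

    ``correlation_mode="independent"`` ignores residual LD between the
    clumped cis instruments (mirroring common practice); ``"gls"`` reports
    the LD-aware IVW alongside.  The GLS estimate is attached whenever an LD
    matrix is available, regardless of mode.
    """
    if correlation_mode not in ("independent", "gls"):
        raise EstimatorError(f"unknown correlation_mode {correlation_mode!r}")
    iset = select_region(
        exposure,
        outcome,
        spec.region,
        ld,
        p_threshold=p_threshold,
        r2_threshold=spec.clump_r2,
        min_snps=min_snps,
        exposure_name=spec.region.gene,
    )
    if apply_steiger:
        filtered, _ = steiger_filter(iset)
        if filtered.nsnp >= min_snps:
            iset = filtered
    estimates, het, pleio, loo, notes = _battery(iset, seed=seed)
    gls = ivw_gls(iset, ld)
    if correlation_mode == "gls":
        notes.append("primary mode: GLS with residual cis LD")
    return DrugTargetResult(
        drugs=[spec.drug],
        genes=[spec.region.gene],
        instrument_set=iset,
        estimates=estimates,
        heterogeneity=het,
        egger_intercept=pleio,
        leave_one_out=loo,
        gls_estimate=gls,
        notes=notes,
    )


def combination_mr(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    specs: tuple[DrugTargetSpec, DrugTargetSpec],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    min_snps: int = 3,
    seed: int = 0,
) -> DrugTargetResult:
    """Joint cis MR for a pair of drug targets (combination therapy proxy).

    The union of the two per-region clumped sets is analysed together;
    cross-region LD is re-checked at the stricter of the two thresholds and
    duplicate SNPs are deduplicated with a note.
    """
    spec_a, spec_b = specs
    sets = []
    for spec in (spec_a, spec_b):
        iset = select_region(
            exposure, outcome, spec.region, ld,
            p_threshold=p_threshold, r2_threshold=spec.clump_r2,
            min_snps=min_snps, exposure_name=spec.region.gene,
        )
        sets.append(iset)
    notes: list[str] = []
    seen: set[str] = set()
    pooled = []
    for iset in sets:
        for h in iset.instruments:
            if h.snp_id in seen:
                notes.append(f"duplicate SNP across regions deduplicated: {h.snp_id}")
                continue
            seen.add(h.snp_id)
            pooled.append(h)
    # cross-region LD re-check at the stricter threshold
    strict_r2 = min(spec_a.clump_r2, spec_b.clump_r2)
    kept = []
    for h in pooled:
        ok = True
        for other in kept:
            if h.chrom == other.chrom and h.snp_id in ld and other.snp_id in ld:
                if ld.r2(h.snp_id, other.snp_id) >= strict_r2:
                    ok = False
                    notes.append(
                        f"{h.snp_id} dropped: cross-region r2 with "
                        f"{other.snp_id} above {strict_r2}"
                    )
                    break
        if ok:
            kept.append(h)
    iset = InstrumentSet(
        exposure_name=f"{spec_a.region.gene}+{spec_b.region.gene}",
        instruments=kept,
        selection_params={
            "regions": [spec_a.region.gene, spec_b.region.gene],
            "r2_thresholds": [spec_a.clump_r2, spec_b.clump_r2],
        },
    )
    estimates, het, pleio, loo, batt_notes = _battery(iset, seed=seed)
    return DrugTargetResult(
        drugs=[spec_a.drug, spec_b.drug],
        genes=[spec_a.region.gene, spec_b.region.gene],
        instrument_set=iset,
        estimates=estimates,
        heterogeneity=het,
        egger_intercept=pleio,
        leave_one_out=loo,
        gls_estimate=ivw_gls(iset, ld),
        notes=notes + batt_notes,
    )


def non_target_mr(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    regions: Sequence[GeneRegion],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    genomewide: InstrumentSet | None = None,
    seed: int = 0,
) -> DrugTargetResult:
    """Genome-wide MR after removing every instrument inside a target region.

    Probes whether lipid-lowering pathways outside the drug-target genes
    still carry a causal signal.  With an empty region list this is exactly
    the full genome-wide analysis.
    """
    if genomewide is None:
        genomewide = select_genomewide(
            exposure, outcome, ld,
            p_threshold=p_threshold, r2_threshold=r2_threshold,
            window_kb=window_kb, exposure_name="non-target",
        )
    kept = [
        h
        for h in genomewide.instruments
        if not any(r.contains(h.chrom, h.pos) for r in regions)
    ]
    removed = genomewide.nsnp - len(kept)
    if not kept:
        raise EstimatorError("no instruments remain outside the target regions")
    iset = InstrumentSet(
        exposure_name=genomewide.exposure_name,
        instruments=kept,
        selection_params={
            **genomewide.selection_params,
            "regions_excluded": [r.gene for r in regions],
            "n_removed_in_regions": removed,
        },
    )
    estimates, het, pleio, loo, notes = _battery(iset, seed=seed)
    notes.append(f"{removed} in-region instruments removed")
    return DrugTargetResult(
        drugs=["non-target"],
        genes=[r.gene for r in regions],
        instrument_set=iset,
        estimates=estimates,
        heterogeneity=het,
        egger_intercept=pleio,
        leave_one_out=loo,
        notes=notes,
    )
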