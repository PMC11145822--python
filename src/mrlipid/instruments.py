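"""Instrument construction: thresholding, LD clumping, cis windows, filters.

Genome-wide instruments follow the conventional two-sample MR recipe
(p < 5e-8, pairwise LD r^2 < 0.001).  Drug-target (cis) instruments are taken
from a gene region plus a symmetric flank and clumped at a relaxed r^2 so that
at least a handful of variants remain for sensitivity analyses.

Gene windows are closed intervals on 1-based coordinates.  The gene-region
file format is a 4-column table (gene, chrom, start, end); note this is
1-based inclusive, deliberately diverging from BED's 0-based half-open
convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gwas_io import (
    HarmonizedInstrument,
    SummaryRecord,
    harmonize,
    two_sided_p,
)

__all__ = [
    "LDMatrix",
    "GeneRegion",
    "InstrumentSet",
    "SteigerResult",
    "ConfounderTable",
    "InstrumentSelectionError",
    "clump",
    "select_genomewide",
    "select_region",
    "exclude_confounder_snps",
    "instrument_strength",
    "steiger_filter",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_regions",
]


class InstrumentSelectionError(ValueError):
    pass


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) keyed by SNP identifier."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene locus with a symmetric flank for cis extraction."""

    gene: str
    chrom: str
    start: int
    end: int
    window_kb: int = 100

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.window_kb < 0:
            raise ValueError(f"{self.gene}: window_kb must be >= 0")

    @property
    def window_start(self) -> int:
        return self.start - self.window_kb * 1000

    @property
    def window_end(self) -> int:
        return self.end + self.window_kb * 1000

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.window_start <= pos <= self.window_end


class ConfounderTable:
    """snp_id -> set of trait labels, emulating a PhenoScanner-style lookup."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._table: dict[str, set[str]] = {
            k: set(v) for k, v in (mapping or {}).items()
        }

    def traits_for(self, snp_id: str) -> set[str]:
        return self._table.get(snp_id, set())

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()


@dataclass(frozen=True)
class SteigerResult:
    snp_id: str
    r2_exp: float
    r2_out: float
    z: float
    pval: float
    direction_ok: bool


@dataclass
class InstrumentSet:
    """A selected, harmonized instrument set with its selection provenance."""

    exposure_name: str
    instruments: list[HarmonizedInstrument]
    selection_params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def nsnp(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [h.snp_id for h in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([h.beta_exp for h in self.instruments])
        sx = np.array([h.se_exp for h in self.instruments])
        by = np.array([h.beta_out for h in self.instruments])
        sy = np.array([h.se_out for h in self.instruments])
        return bx, sx, by, sy

    def subset(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        keep = set(snp_ids)
        return InstrumentSet(
            exposure_name=self.exposure_name,
            instruments=[h for h in self.instruments if h.snp_id in keep],
            selection_params=dict(self.selection_params),
            diagnostics=dict(self.diagnostics),
        )


# ---------------------------------------------------------------------------
# clumping


def clump(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float,
    window_kb: int,
    missing_ld: str = "drop",
) -> list[str]:
    """Greedy p-value clumping: retain index SNPs, retire LD partners.

    Records are sorted ascending by p (ties broken by ascending snp_id); the
    best unretired SNP is accepted and every SNP on the same chromosome within
    ``window_kb`` with r^2 >= ``r2_threshold`` against it is retired.  The
    returned identifiers are mutually below the threshold, independent of
    input order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if missing_ld not in ("drop", "keep", "error"):
        raise ValueError("missing_ld must be drop|keep|error")

    usable: list[SummaryRecord] = []
    for rec in records:
        if rec.snp_id not in ld:
            if missing_ld == "error":
                raise InstrumentSelectionError(
                    f"{rec.snp_id} absent from LD reference"
                )
            if missing_ld == "drop":
                warnings.warn(
                    f"{rec.snp_id} absent from LD reference; dropped from clumping",
                    stacklevel=2,
                )
                continue
        usable.append(rec)

    def sort_key(rec: SummaryRecord):
        p = rec.pval if rec.pval is not None else two_sided_p(rec.beta / rec.se)
        return (p, rec.snp_id)

    ordered = sorted(usable, key=sort_key)
    retired: set[str] = set()
    retained: list[str] = []
    for rec in ordered:
        if rec.snp_id in retired:
            continue
        retained.append(rec.snp_id)
        for other in ordered:
            if other.snp_id == rec.snp_id or other.snp_id in retired:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_kb * 1000:
                continue
            if rec.snp_id in ld and other.snp_id in ld:
                if ld.r2(rec.snp_id, other.snp_id) >= r2_threshold:
                    retired.add(other.snp_id)
    return retained


# ---------------------------------------------------------------------------
# selection


def _filter_p(records: Sequence[SummaryRecord], p_threshold: float):
    out = []
    for rec in records:
        p = rec.pval if rec.pval is not None else two_sided_p(rec.beta / rec.se)
        if p < p_threshold:
            out.append(rec)
    return out


def select_genomewide(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    exposure_name: str = "exposure",
    palindrome_policy: str = "drop_ambiguous",
) -> InstrumentSet:
    """Genome-wide significant, LD-independent, harmonized instruments."""
    significant = _filter_p(exposure, p_threshold)
    if not significant:
        raise InstrumentSelectionError(
            f"no instruments at threshold p < {p_threshold:g}"
        )
    retained = clump(significant, ld, r2_threshold, window_kb)
    by_id = {r.snp_id: r for r in significant}
    instruments, _ = harmonize(
        [by_id[s] for s in retained], list(outcome), palindrome_policy
    )
    if not instruments:
        raise InstrumentSelectionError("no instruments survived harmonization")
    return InstrumentSet(
        exposure_name=exposure_name,
        instruments=instruments,
        selection_params={
            "p_threshold": p_threshold,
            "r2_threshold": r2_threshold,
            "window_kb": window_kb,
            "scope": "genome-wide",
        },
    )


def select_region(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.2,
    min_snps: int = 3,
    exposure_name: str = "exposure",
    palindrome_policy: str = "drop_ambiguous",
) -> InstrumentSet:
    """Cis (drug-target) instruments from a gene region +- its flank.

    Within-region clumping uses the region span itself as the clumping
    window.  Raises if fewer than ``min_snps`` survive: weak cis sets are a
    diagnostic, never silently analysed.
    """
    in_window = [
        rec for rec in exposure if region.contains(rec.chrom, rec.pos)
    ]
    significant = _filter_p(in_window, p_threshold)
    span_kb = max(1, math.ceil((region.window_end - region.window_start) / 1000))
    retained = clump(significant, ld, r2_threshold, span_kb) if significant else []
    if len(retained) < min_snps:
        raise InstrumentSelectionError(
            f"insufficient cis instruments for {region.gene}: "
            f"{len(retained)} retained, {min_snps} required"
        )
    by_id = {r.snp_id: r for r in significant}
    instruments, _ = harmonize(
        [by_id[s] for s in retained], list(outcome), palindrome_policy
    )
    if len(instruments) < min_snps:
        raise InstrumentSelectionError(
            f"insufficient cis instruments for {region.gene} after harmonization: "
            f"{len(instruments)} retained, {min_snps} required"
        )
    return InstrumentSet(
        exposure_name=exposure_name,
        instruments=instruments,
        selection_params={
            "p_threshold": p_threshold,
            "r2_threshold": r2_threshold,
            "region": region,
            "scope": "cis",
        },
    )


def exclude_confounder_snps(
    iset: InstrumentSet,
    table: ConfounderTable,
    traits: Iterable[str],
    mode: str = "substring",
) -> InstrumentSet:
    """Drop instruments annotated with confounder traits (e.g. blood pressure).

    ``substring`` mode matches case-insensitively in either direction, so a
    SNP tagged "Systolic Blood Pressure" is dropped for the query trait
    "blood pressure".  ``exact`` mode requires identical lower-cased labels.
    SNPs absent from the table are retained.
    """
    if mode not in ("substring", "exact"):
        raise ValueError("mode must be substring|exact")
    queries = [t.lower() for t in traits]

    def hits(labels: set[str]) -> bool:
        for label in labels:
            ll = label.lower()
            for q in queries:
                if mode == "exact":
                    if ll == q:
                        return True
                elif q in ll or ll in q:
                    return True
        return False

    dropped = [
        h.snp_id for h in iset.instruments if hits(table.traits_for(h.snp_id))
    ]
    kept = [h for h in iset.instruments if h.snp_id not in set(dropped)]
    out = InstrumentSet(
        exposure_name=iset.exposure_name,
        instruments=kept,
        selection_params=dict(iset.selection_params),
        diagnostics=dict(iset.diagnostics),
    )
    out.selection_params["confounder_dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# strength and directionality diagnostics


def _r2_from_t(t2: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Variance explained from a squared t statistic: r^2 = t^2/(t^2 + n - 2).

    Works without allele frequencies; the EAF-based alternative
    2 beta^2 eaf (1-eaf) is available via ``r2_from_eaf``.
    """
    return t2 / (t2 + n - 2.0)


def r2_from_eaf(beta: float, eaf: float, trait_var: float = 1.0) -> float:
    return 2.0 * beta**2 * eaf * (1.0 - eaf) / trait_var


def instrument_strength(iset: InstrumentSet) -> dict:
    """Per-SNP and aggregate instrument strength (F statistic, r^2).

    Per-SNP F = (beta_exp/se_exp)^2 and r^2 = F/(F + n - 2).  The aggregate
    r^2 sums per-SNP values over the (independent) instruments and the
    aggregate F is r^2 (n - k - 1) / ((1 - r^2) k) for k instruments.
    F < 10 flags a weak instrument by the usual convention.
    """
    bx, sx, _, _ = iset.arrays()
    n_exp = np.array(
        [h.n_exp if h.n_exp is not None else -1 for h in iset.instruments],
        dtype=float,
    )
    if np.any(n_exp <= 2):
        raise InstrumentSelectionError("instrument_strength requires n_exp > 2")
    F = (bx / sx) ** 2
    r2 = _r2_from_t(F, n_exp)
    k = iset.nsnp
    total_r2 = float(np.sum(r2))
    n_eff = float(np.median(n_exp))
    aggregate_F = total_r2 * (n_eff - k - 1.0) / ((1.0 - total_r2) * k)
    return {
        "snp_id": iset.snp_ids,
        "F": F,
        "r2": r2,
        "weak": F < 10.0,
        "aggregate_r2": total_r2,
        "aggregate_F": float(aggregate_F),
        "aggregate_weak": bool(aggregate_F < 10.0),
    }


def steiger_filter(
    iset: InstrumentSet,
    alpha: float = 0.05,
    require_significance: bool = False,
) -> tuple[InstrumentSet, list[SteigerResult]]:
    """Directionality screen: keep SNPs explaining more exposure variance.

    Per SNP, variance explained is the t-based pseudo-r^2 on each side
    (the outcome side is a log-odds-scale approximation); the z statistic
    compares Fisher-transformed |r| values with independent-samples variance
    1/(n_exp - 3) + 1/(n_out - 3).  By default retention is on direction
    alone (r2_exp > r2_out), matching the use of Steiger filtering as a
    pass/fail screen; set ``require_significance`` to demand p < alpha too.
    """
    results: list[SteigerResult] = []
    for h in iset.instruments:
        if h.n_exp is None or h.n_out is None or h.n_exp <= 3 or h.n_out <= 3:
            raise InstrumentSelectionError(
                f"{h.snp_id}: Steiger filtering needs n > 3 on both sides"
            )
        t2_exp = (h.beta_exp / h.se_exp) ** 2
        t2_out = (h.beta_out / h.se_out) ** 2
        r2_exp = float(_r2_from_t(np.array(t2_exp), np.array(float(h.n_exp))))
        r2_out = float(_r2_from_t(np.array(t2_out), np.array(float(h.n_out))))
        r_exp = math.sqrt(r2_exp)
        r_out = math.sqrt(r2_out)
        denom = math.sqrt(1.0 / (h.n_exp - 3) + 1.0 / (h.n_out - 3))
        z = (math.atanh(min(r_exp, 1 - 1e-15)) - math.atanh(min(r_out, 1 - 1e-15))) / denom
        pval = two_sided_p(z)
        direction_ok = r2_exp > r2_out
        results.append(
            SteigerResult(h.snp_id, r2_exp, r2_out, z, pval, direction_ok)
        )
    keep = [
        r.snp_id
        for r in results
        if r.direction_ok and (not require_significance or r.pval < alpha)
    ]
    return iset.subset(keep), results


# ---------------------------------------------------------------------------
# file formats


def read_ld_matrix(path) -> LDMatrix:
    """Square tab-delimited matrix of r values with a header row of SNP ids."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = [h for h in header if h]
        rows = [
            [float(x) for x in line.rstrip("\n").split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    return LDMatrix(ids, np.array(rows))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(ld.snp_ids) + "\n")
        for sid, row in zip(ld.snp_ids, ld.r):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gene_regions(path, window_kb: int = 100) -> list[GeneRegion]:
    """4-column (gene, chrom, start, end) table; 1-based inclusive, NOT BED."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, chrom, start, end = line.split()[:4]
            regions.append(
                GeneRegion(gene, chrom, int(start), int(end), window_kb)
            )
    return regions
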