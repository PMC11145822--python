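"""Data model and I/O for GWAS summary statistics, plus allele harmonization.

Two-sample Mendelian randomization combines per-SNP association summaries from
an exposure GWAS (here: blood lipids) and an outcome GWAS (here: acute
myocardial infarction on the log-odds scale).  Before any estimation the two
sources must be expressed on a common effect allele; this module owns that
harmonization step, including strand-complement resolution and palindromic
(A/T, C/G) SNP policies.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy import stats as _stats

__all__ = [
    "SummaryRecord",
    "HarmonizedInstrument",
    "HarmonizeReport",
    "ReadReport",
    "DEFAULT_DIALECT",
    "read_summary_stats",
    "write_summary_stats",
    "write_harmonized",
    "harmonize",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column-name mapping for tab-delimited summary-statistics files
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se")


class SummaryStatsError(ValueError):
    """Configuration or content error in a summary-statistics file."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele association: for quantitative exposures
    in the unit recorded in ``sd_units`` (e.g. mg/dL), for a binary outcome on
    the log-odds scale.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None
    sd_units: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in _VALID_ALLELES:
            raise SummaryStatsError(
                f"{self.snp_id}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise SummaryStatsError(
                f"{self.snp_id}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryStatsError(f"{self.snp_id}: alleles must differ")
        if not (self.se > 0):
            raise SummaryStatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: eaf {self.eaf} outside [0,1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: pval {self.pval} outside (0,1]")
        if self.n is not None and self.n <= 0:
            raise SummaryStatsError(f"{self.snp_id}: n must be positive")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def pval_consistent(self, rtol: float = 0.10) -> bool:
        """Check the stored p against the two-sided normal p of beta/se."""
        if self.pval is None:
            return True
        expected = two_sided_p(self.beta / self.se)
        if expected == 0.0:  # beyond float resolution; compare on log scale
            return self.pval < 1e-300
        return abs(self.pval - expected) <= rtol * expected


def two_sided_p(z: float) -> float:
    """Two-sided normal p-value for a z statistic."""
    return float(2.0 * _stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    p_exp: float | None = None
    n_exp: int | None = None
    n_out: int | None = None
    chrom: str = ""
    pos: int = 0
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise SummaryStatsError(f"{self.snp_id}: standard errors must be > 0")

    def reoriented(self) -> "HarmonizedInstrument":
        """Flip the arbitrary choice of effect allele (both betas negate)."""
        return replace(
            self,
            effect_allele=self.other_strand_label(),
            beta_exp=-self.beta_exp,
            beta_out=-self.beta_out,
            eaf_exp=None if self.eaf_exp is None else 1.0 - self.eaf_exp,
            eaf_out=None if self.eaf_out is None else 1.0 - self.eaf_out,
        )

    def other_strand_label(self) -> str:
        # label bookkeeping only; estimators never read the allele letter
        return _COMPLEMENT[self.effect_allele]


@dataclass
class ReadReport:
    """Row-level accounting for a summary-statistics read."""

    n_rows: int = 0
    n_records: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    pval_inconsistent: list[str] = field(default_factory=list)


@dataclass
class HarmonizeReport:
    n_input: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    n_unmatched: int = 0

    def check(self) -> bool:
        return (
            self.n_matched
            + self.n_dropped_palindromic
            + self.n_dropped_incompatible
            + self.n_unmatched
            == self.n_input
        )


def _parse_float(text: str, line_no: int, col: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise SummaryStatsError(f"line {line_no}: unparseable {col} {text!r}") from exc


def read_summary_stats(
    path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> tuple[list[SummaryRecord], ReadReport]:
    """Read delimited summary statistics into :class:`SummaryRecord` rows.

    Rows violating hard invariants (e.g. non-positive SE) are rejected and
    listed, with 1-based line numbers, in the returned :class:`ReadReport`.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    report = ReadReport()
    records: list[SummaryRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for key in _MANDATORY:
            if mapping[key] not in header:
                raise SummaryStatsError(
                    f"missing mandatory column {mapping[key]!r} (for {key})"
                )
        have = {k: (v in header) for k, v in mapping.items()}
        for line_no, row in enumerate(reader, start=2):
            report.n_rows += 1

            def get(key: str) -> str | None:
                if not have[key]:
                    return None
                value = row[mapping[key]]
                return None if value in ("", "NA", "NaN", ".") else value

            try:
                rec = SummaryRecord(
                    snp_id=str(get("snp_id")),
                    chrom=str(get("chrom") or ""),
                    pos=int(float(get("pos"))) if get("pos") is not None else 0,
                    effect_allele=str(get("effect_allele")),
                    other_allele=str(get("other_allele")),
                    eaf=(
                        _parse_float(get("eaf"), line_no, "eaf")
                        if get("eaf") is not None
                        else None
                    ),
                    beta=_parse_float(get("beta"), line_no, "beta"),
                    se=_parse_float(get("se"), line_no, "se"),
                    pval=(
                        _parse_float(get("pval"), line_no, "pval")
                        if get("pval") is not None
                        else None
                    ),
                    n=int(float(get("n"))) if get("n") is not None else None,
                )
            except SummaryStatsError as exc:
                report.rejected.append((line_no, str(exc)))
                continue
            if not rec.pval_consistent():
                report.pval_inconsistent.append(rec.snp_id)
            records.append(rec)
            report.n_records += 1
    return records, report


def write_summary_stats(
    records: Iterable[SummaryRecord],
    path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> None:
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    cols = list(mapping)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([mapping[c] for c in cols])
        for rec in records:
            writer.writerow(
                [
                    rec.snp_id,
                    rec.chrom,
                    rec.pos,
                    rec.effect_allele,
                    rec.other_allele,
                    "" if rec.eaf is None else repr(rec.eaf),
                    repr(rec.beta),
                    repr(rec.se),
                    "" if rec.pval is None else repr(rec.pval),
                    "" if rec.n is None else rec.n,
                ]
            )


def write_harmonized(instruments: Iterable[HarmonizedInstrument], path) -> None:
    """Export a harmonized set in the standard dialect plus flag columns."""
    cols = [
        "SNP", "CHR", "BP", "EA",
        "BETA_EXP", "SE_EXP", "EAF_EXP", "P_EXP", "N_EXP",
        "BETA_OUT", "SE_OUT", "EAF_OUT", "N_OUT",
        "FLIPPED", "PALINDROMIC",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for h in instruments:
            writer.writerow(
                [
                    h.snp_id, h.chrom, h.pos, h.effect_allele,
                    repr(h.beta_exp), repr(h.se_exp),
                    "" if h.eaf_exp is None else repr(h.eaf_exp),
                    "" if h.p_exp is None else repr(h.p_exp),
                    "" if h.n_exp is None else h.n_exp,
                    repr(h.beta_out), repr(h.se_out),
                    "" if h.eaf_out is None else repr(h.eaf_out),
                    "" if h.n_out is None else h.n_out,
                    int(h.flipped), int(h.palindromic),
                ]
            )


def _orientation(exp: SummaryRecord, out: SummaryRecord) -> str | None:
    """Classify outcome alleles against the exposure orientation.

    Returns ``"same"``, ``"swapped"`` or ``None`` (incompatible), trying a
    strand complement before giving up (summary files differ in strand
    convention).  Palindromic SNPs are handled by the caller: for them
    complementing is indistinguishable from swapping.
    """
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return "same"
    if o == (e[1], e[0]):
        return "swapped"
    oc = (_COMPLEMENT[o[0]], _COMPLEMENT[o[1]])
    if oc == e:
        return "same"
    if oc == (e[1], e[0]):
        return "swapped"
    return None


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_policy: str = "drop_ambiguous",
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[HarmonizedInstrument], HarmonizeReport]:
    """Express exposure and outcome effects on a common effect allele.

    For each SNP shared between the two sources: if the outcome alleles match
    the exposure orientation the outcome effect is copied; if they are swapped
    the outcome beta is negated and its EAF reflected; if neither (after
    strand-complement resolution) the SNP is dropped as incompatible.

    Palindromic (A/T, C/G) SNPs cannot be resolved by allele labels.  Policies:

    ``drop_ambiguous``
        drop when either side's EAF lies in ``ambiguity_band`` (or is
        missing); otherwise infer orientation by EAF concordance.
    ``infer_by_eaf``
        always infer by EAF concordance; drop only when EAF is missing.
    ``keep``
        trust the allele labels at face value.
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    out_by_id = {rec.snp_id: rec for rec in outcome}
    report = HarmonizeReport(n_input=len(exposure))
    instruments: list[HarmonizedInstrument] = []
    lo, hi = ambiguity_band

    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            report.n_unmatched += 1
            continue
        palindromic = exp.is_palindromic
        if palindromic:
            if out.is_palindromic is False or _orientation(exp, out) is None:
                report.n_dropped_incompatible += 1
                continue
            if palindrome_policy == "keep":
                flipped = out.effect_allele != exp.effect_allele
            else:
                if exp.eaf is None or out.eaf is None:
                    report.n_dropped_palindromic += 1
                    continue
                if palindrome_policy == "drop_ambiguous" and (
                    lo <= exp.eaf <= hi or lo <= out.eaf <= hi
                ):
                    report.n_dropped_palindromic += 1
                    continue
                # orient so that effect-allele frequencies agree in side of 0.5
                flipped = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
        else:
            orient = _orientation(exp, out)
            if orient is None:
                report.n_dropped_incompatible += 1
                continue
            flipped = orient == "swapped"

        beta_out = -out.beta if flipped else out.beta
        eaf_out = None
        if out.eaf is not None:
            eaf_out = 1.0 - out.eaf if flipped else out.eaf
        instruments.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                p_exp=exp.pval,
                n_exp=exp.n,
                n_out=out.n,
                chrom=exp.chrom,
                pos=exp.pos,
                flipped=flipped,
                palindromic=palindromic,
            )
        )
        report.n_matched += 1
        report.n_flipped += int(flipped)

    if report.n_matched == 0 and report.n_input > 0 and report.n_unmatched == report.n_input:
        raise SummaryStatsError("no overlapping instruments")
    return instruments, report
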