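"""Somatic-variant consensus filtering.

Candidate somatic mutations (from any upstream caller) are screened with a
set of exclusion criteria commonly applied to tumor/normal exome pairs:
low total depth, low tumor variant-allele frequency, mutant support in the
germline control, single-strand-only mutant support, and membership in a
population variant database.  A call is rejected when *any* enabled
criterion fires; every failed criterion is recorded so rejection tallies
are reproducible regardless of evaluation order.

Two presets are provided: ``human`` (all five criteria) and ``mouse``
(no germline-support or population-database criterion, matching a setting
where no matched normal database is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Consequence",
    "VariantCall",
    "FilterCriteria",
    "FilterReport",
    "HUMAN_PRESET",
    "MOUSE_PRESET",
    "tumor_vaf",
    "apply_somatic_filters",
    "count_nonsynonymous",
    "CRITERION_LABELS",
]

#: Canonical labels for the exclusion criteria, in evaluation order.
CRITERION_LABELS = (
    "total_reads",
    "low_vaf",
    "germline_alt",
    "single_strand",
    "population_db",
)


class Consequence(str, Enum):
    """Coding consequence of a variant, as annotated upstream."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    OTHER = "other"


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic mutation with per-strand tumor allele counts.

    Positions are 1-based (VCF convention).  ``normal_alt``/``normal_total``
    are mutant and total read counts in the matched germline control;
    ``in_population_db`` flags membership in a population variant resource
    (e.g. 1000 Genomes or an in-house normal panel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_alt_fwd: int
    tumor_alt_rev: int
    tumor_ref_fwd: int
    tumor_ref_rev: int
    normal_alt: int = 0
    normal_total: int = 0
    in_population_db: bool = False
    consequence: Optional[Consequence] = None

    def __post_init__(self) -> None:
        counts = (
            self.tumor_alt_fwd,
            self.tumor_alt_rev,
            self.tumor_ref_fwd,
            self.tumor_ref_rev,
            self.normal_alt,
            self.normal_total,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative read count in {self.chrom}:{self.pos}")
        if self.normal_alt > self.normal_total:
            raise ValueError(
                f"normal_alt > normal_total at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multi-allelic record at {self.chrom}:{self.pos}; "
                "split to one alt per row before filtering"
            )

    @property
    def tumor_alt(self) -> int:
        return self.tumor_alt_fwd + self.tumor_alt_rev

    @property
    def tumor_total(self) -> int:
        return (
            self.tumor_alt_fwd
            + self.tumor_alt_rev
            + self.tumor_ref_fwd
            + self.tumor_ref_rev
        )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the somatic exclusion criteria.

    All inequalities are strict, exactly as conventionally printed:
    reject when total tumor reads < ``min_total_reads``, tumor VAF <
    ``min_vaf``, germline mutant reads > ``max_germline_alt_reads``.
    ``max_germline_alt_reads=None`` disables the germline criterion
    (mouse preset).
    """

    min_total_reads: int = 20
    min_vaf: float = 0.05
    max_germline_alt_reads: Optional[int] = 2
    require_both_strands: bool = True
    exclude_population_db: bool = True

    def __post_init__(self) -> None:
        if self.min_total_reads < 0 or self.min_vaf < 0:
            raise ValueError("thresholds must be non-negative")
        if (
            self.max_germline_alt_reads is not None
            and self.max_germline_alt_reads < 0
        ):
            raise ValueError("max_germline_alt_reads must be non-negative")


HUMAN_PRESET = FilterCriteria()
MOUSE_PRESET = FilterCriteria(
    max_germline_alt_reads=None, exclude_population_db=False
)

PRESETS = {"human": HUMAN_PRESET, "mouse": MOUSE_PRESET}


@dataclass
class FilterReport:
    """Outcome of filtering: retained calls, rejected calls with their
    failed-criterion labels, and a per-criterion rejection tally."""

    retained: list = field(default_factory=list)
    rejected: list = field(default_factory=list)  # (VariantCall, frozenset)
    tally: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.rejected)


def tumor_vaf(call: VariantCall) -> float:
    """Tumor variant-allele frequency: alt reads / total reads.

    Raises ``ValueError`` on zero tumor depth; such a call necessarily
    also fails the total-read criterion, so filters never need the VAF
    of a depth-zero call.
    """
    total = call.tumor_total
    if total == 0:
        raise ValueError(f"zero tumor depth at {call.chrom}:{call.pos}")
    return call.tumor_alt / total


def failed_criteria(
    call: VariantCall, criteria: FilterCriteria
) -> frozenset[str]:
    """Evaluate every enabled exclusion criterion for one call.

    Returns the full set of failed criterion labels (no short-circuit).
    """
    failed = set()
    total = call.tumor_total
    if total < criteria.min_total_reads:
        failed.add("total_reads")
    if total > 0 and tumor_vaf(call) < criteria.min_vaf:
        failed.add("low_vaf")
    if (
        criteria.max_germline_alt_reads is not None
        and call.normal_alt > criteria.max_germline_alt_reads
    ):
        failed.add("germline_alt")
    if criteria.require_both_strands and (
        call.tumor_alt_fwd == 0 or call.tumor_alt_rev == 0
    ):
        failed.add("single_strand")
    if criteria.exclude_population_db and call.in_population_db:
        failed.add("population_db")
    return frozenset(failed)


def apply_somatic_filters(
    calls: Iterable[VariantCall],
    criteria: FilterCriteria = HUMAN_PRESET,
) -> FilterReport:
    """Apply the somatic exclusion criteria to a candidate call set.

    A call is rejected iff any enabled criterion fires; the report records
    all failed criteria per rejected call and a label -> count tally.
    """
    report = FilterReport(tally={label: 0 for label in CRITERION_LABELS})
    for call in calls:
        failed = failed_criteria(call, criteria)
        if failed:
            report.rejected.append((call, failed))
            for label in failed:
                report.tally[label] += 1
        else:
            report.retained.append(call)
    return report


def count_nonsynonymous(report: FilterReport) -> int:
    """Count retained nonsynonymous calls (the TMB surrogate)."""
    n = 0
    for call in report.retained:
        if call.consequence is None:
            raise ValueError(
                f"consequence missing on retained call {call.chrom}:{call.pos}"
            )
        if call.consequence == Consequence.NONSYNONYMOUS:
            n += 1
    return n
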