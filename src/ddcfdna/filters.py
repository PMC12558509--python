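"""GATK-style hard filtering of annotated variant calls.

Variants are excluded by fixed thresholds on per-site annotation
statistics, with separate predicate sets for SNPs and INDELs:

* SNPs fail when ``QD < 2.0``, ``QUAL < 30.0``, ``SOR > 3.0``,
  ``FS > 60.0``, ``MQ < 40.0``, ``MQRankSum < -12.5`` or
  ``ReadPosRankSum < -8.0``.
* INDELs fail when ``QD < 2.0``, ``QUAL < 30.0``, ``FS > 200.0`` or
  ``ReadPosRankSum < -20.0``.

All inequalities are strict: a statistic exactly at its threshold
passes.  A missing statistic cannot be evaluated and therefore does
not trigger its predicate; such evaluations are counted so callers
can audit how often the rule set was partially applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

__all__ = [
    "VariantClass",
    "VariantAnnotations",
    "FilterVerdict",
    "FilterSummary",
    "classify_variant",
    "hard_filter_snp",
    "hard_filter_indel",
    "filter_stream",
    "SNP_THRESHOLDS",
    "INDEL_THRESHOLDS",
]

_NUCLEOTIDES = frozenset("ACGT")


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VariantAnnotations:
    """The seven hard-filter statistics for one variant record.

    Any statistic may be ``None`` (absent from the VCF INFO field);
    QUAL comes from the VCF QUAL column.
    """

    variant_class: VariantClass
    QD: Optional[float] = None
    QUAL: Optional[float] = None
    SOR: Optional[float] = None
    FS: Optional[float] = None
    MQ: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.QUAL is not None and self.QUAL < 0:
            raise ValueError(f"QUAL must be non-negative, got {self.QUAL}")
        if self.FS is not None and self.FS < 0:
            raise ValueError(f"FS must be non-negative, got {self.FS}")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_predicates: tuple[str, ...] = ()
    missing_evaluations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_predicates) == 0):
            raise ValueError("pass flag inconsistent with failed predicate list")


# (statistic, direction, threshold): "lt" fails when value < threshold,
# "gt" fails when value > threshold.
SNP_THRESHOLDS: tuple[tuple[str, str, float], ...] = (
    ("QD", "lt", 2.0),
    ("QUAL", "lt", 30.0),
    ("SOR", "gt", 3.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)

INDEL_THRESHOLDS: tuple[tuple[str, str, float], ...] = (
    ("QD", "lt", 2.0),
    ("QUAL", "lt", 30.0),
    ("FS", "gt", 200.0),
    ("ReadPosRankSum", "lt", -20.0),
)


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a ref/alt allele pair as SNP, INDEL or OTHER.

    SNP: both alleles single nucleotides and different.  INDEL: allele
    lengths differ.  Same-length multi-nucleotide substitutions (MNPs)
    fall in neither hard-filter predicate set and are classified OTHER.
    """
    for name, allele in (("ref", ref), ("alt", alt)):
        if not allele or not set(allele) <= _NUCLEOTIDES:
            raise ValueError(
                f"{name} allele {allele!r} is not a non-empty A/C/G/T string"
            )
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise ValueError("ref and alt alleles are identical")
        return VariantClass.SNP
    if len(ref) != len(alt):
        return VariantClass.INDEL
    return VariantClass.OTHER


def _apply_thresholds(
    ann: VariantAnnotations, thresholds: tuple[tuple[str, str, float], ...]
) -> FilterVerdict:
    failed: list[str] = []
    missing: list[str] = []
    for stat, direction, cutoff in thresholds:
        value = getattr(ann, stat)
        if value is None:
            missing.append(stat)
            continue
        if (direction == "lt" and value < cutoff) or (
            direction == "gt" and value > cutoff
        ):
            failed.append(stat)
    return FilterVerdict(
        passed=not failed,
        failed_predicates=tuple(failed),
        missing_evaluations=tuple(missing),
    )


def hard_filter_snp(ann: VariantAnnotations) -> FilterVerdict:
    """Evaluate the seven SNP hard-filter predicates."""
    if ann.variant_class is not VariantClass.SNP:
        raise ValueError(f"hard_filter_snp requires a SNP, got {ann.variant_class}")
    return _apply_thresholds(ann, SNP_THRESHOLDS)


def hard_filter_indel(ann: VariantAnnotations) -> FilterVerdict:
    """Evaluate the four INDEL hard-filter predicates."""
    if ann.variant_class is not VariantClass.INDEL:
        raise ValueError(
            f"hard_filter_indel requires an INDEL, got {ann.variant_class}"
        )
    return _apply_thresholds(ann, INDEL_THRESHOLDS)


def hard_filter(ann: VariantAnnotations) -> FilterVerdict:
    """Dispatch to the predicate set for the record's variant class."""
    if ann.variant_class is VariantClass.SNP:
        return hard_filter_snp(ann)
    if ann.variant_class is VariantClass.INDEL:
        return hard_filter_indel(ann)
    raise ValueError(f"no hard-filter predicate set for class {ann.variant_class}")


@dataclass
class FilterSummary:
    """Counts accumulated over one pass of :func:`filter_stream`."""

    total: int = 0
    passed: int = 0
    failed: int = 0
    malformed: int = 0
    missing_evaluations: int = 0
    failed_by_reason: dict[str, int] = field(default_factory=dict)
    by_class: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "passed": self.passed,
            "failed": self.failed,
            "malformed": self.malformed,
            "missing_evaluations": self.missing_evaluations,
            "failed_by_reason": dict(self.failed_by_reason),
            "by_class": {k: dict(v) for k, v in self.by_class.items()},
        }


def filter_stream(
    records: Iterable, summary: Optional[FilterSummary] = None
) -> Iterator[tuple[object, FilterVerdict]]:
    """Apply the hard filters to a stream of annotated records.

    Each record must either be a :class:`VariantAnnotations` or expose
    one through an ``annotations`` attribute.  Records whose class has
    no predicate set (OTHER) are counted as malformed and yielded with
    a failing verdict naming the reason, never silently dropped.
    Input order is preserved.  Pass a :class:`FilterSummary` to collect
    counts; it is updated in place as the stream is consumed.
    """
    if summary is None:
        summary = FilterSummary()
    for record in records:
        ann = record if isinstance(record, VariantAnnotations) else record.annotations
        summary.total += 1
        try:
            verdict = hard_filter(ann)
        except ValueError:
            summary.malformed += 1
            verdict = FilterVerdict(False, ("unclassifiable",))
            yield record, verdict
            continue
        cls = ann.variant_class.value
        cls_counts = summary.by_class.setdefault(cls, {"passed": 0, "failed": 0})
        summary.missing_evaluations += len(verdict.missing_evaluations)
        if verdict.passed:
            summary.passed += 1
            cls_counts["passed"] += 1
        else:
            summary.failed += 1
            cls_counts["failed"] += 1
            for reason in verdict.failed_predicates:
                summary.failed_by_reason[reason] = (
                    summary.failed_by_reason.get(reason, 0) + 1
                )
        yield record, verdict
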