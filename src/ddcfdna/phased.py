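"""Haplotype-aware donor/recipient variant sets and cfDNA comparison.

From phased genotypes of the pair, two disjoint variant sets are
built: an allele at a site is *donor-derived* when it occurs on at
least one donor haplotype and on neither recipient haplotype, and
symmetrically for *recipient-derived*.  cfDNA genotype calls are then
compared against both sets; the per-chromosome matched counts give
percent ddcfDNA as 100 × donor-matched / (donor- + recipient-matched).

At single biallelic SNPs this is equivalent to the unphased
discriminating-allele index — phase carries no extra information for
a one-site comparison — so the two pipelines serve as mutual checks.
Allele matching is on left-normalized SNP alleles; haplotype-path
equivalence for complex variants is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .index import GenotypeCall
from .quantify import AlleleCalls, DonorFractionEstimate, _finalize

__all__ = [
    "DerivedVariantSet",
    "MatchedCounts",
    "build_phased_sets",
    "match_cfdna_to_sets",
    "estimate_fraction_phased",
]


@dataclass(frozen=True)
class DerivedVariantSet:
    """All (chromosome, position, allele) triples attributable to one
    individual of the pair."""

    origin: str  # "donor-derived" or "recipient-derived"
    members: frozenset[tuple[str, int, str]]

    def per_chrom_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for chrom, _, _ in self.members:
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.members)
        return pd.DataFrame(rows, columns=["chrom", "pos", "allele"])


def _require_phased(call: GenotypeCall, label: str) -> None:
    if not call.phased:
        raise ValueError(
            f"{label} genotype at {call.chrom}:{call.pos} is unphased; "
            "the phased method requires '|' genotypes — use the unphased "
            "informative-index method instead"
        )


def build_phased_sets(
    donor_calls: Iterable[GenotypeCall],
    recipient_calls: Iterable[GenotypeCall],
) -> tuple[DerivedVariantSet, DerivedVariantSet]:
    """Assign each allele at jointly-phased sites to donor or recipient.

    Disjoint by construction: an allele present in both individuals
    belongs to neither set.
    """
    donor_by_site: dict[tuple[str, int], GenotypeCall] = {}
    for call in donor_calls:
        _require_phased(call, "donor")
        donor_by_site[(call.chrom, call.pos)] = call
    donor_members: set[tuple[str, int, str]] = set()
    recip_members: set[tuple[str, int, str]] = set()
    for call in recipient_calls:
        _require_phased(call, "recipient")
        site = (call.chrom, call.pos)
        donor_call = donor_by_site.get(site)
        if donor_call is None:
            continue
        donor_alleles = set(donor_call.allele_bases())
        recip_alleles = set(call.allele_bases())
        for allele in donor_alleles - recip_alleles:
            donor_members.add((call.chrom, call.pos, allele))
        for allele in recip_alleles - donor_alleles:
            recip_members.add((call.chrom, call.pos, allele))
    return (
        DerivedVariantSet("donor-derived", frozenset(donor_members)),
        DerivedVariantSet("recipient-derived", frozenset(recip_members)),
    )


@dataclass
class MatchedCounts:
    """Per-chromosome counts of derived-set members whose allele was
    called in the cfDNA sample."""

    per_chrom: pd.DataFrame  # chrom, donor_matched, recipient_matched
    skipped_sites: int = 0
    set_sizes: dict[str, int] = field(default_factory=dict)


def match_cfdna_to_sets(
    donor_set: DerivedVariantSet,
    recipient_set: DerivedVariantSet,
    calls: AlleleCalls,
) -> MatchedCounts:
    """Count, per chromosome and origin, set members present in the
    cfDNA allele calls."""
    counts: dict[str, dict[str, int]] = {}
    chroms = {c for c, _, _ in donor_set.members | recipient_set.members}
    for chrom in chroms:
        counts[chrom] = {"donor_matched": 0, "recipient_matched": 0}
    for origin_key, vset in (
        ("donor_matched", donor_set),
        ("recipient_matched", recipient_set),
    ):
        for chrom, pos, allele in vset.members:
            if allele in calls.get((chrom, pos)):
                counts[chrom][origin_key] += 1
    rows = [
        {"chrom": chrom, **counts[chrom]} for chrom in sorted(counts)
    ]
    return MatchedCounts(
        per_chrom=pd.DataFrame(
            rows, columns=["chrom", "donor_matched", "recipient_matched"]
        ),
        set_sizes={
            "donor-derived": len(donor_set.members),
            "recipient-derived": len(recipient_set.members),
        },
    )


def estimate_fraction_phased(matched: MatchedCounts) -> DonorFractionEstimate:
    """Percent ddcfDNA from haplotype-derived matched counts.

    100 × donor-matched / (donor-matched + recipient-matched) per
    chromosome and pooled; a zero denominator is flagged as "no
    informative coverage", never reported as 0.
    """
    rows = [
        {
            "chrom": row.chrom,
            "numerator": row.donor_matched,
            "denominator": row.donor_matched + row.recipient_matched,
        }
        for row in matched.per_chrom.itertuples(index=False)
    ]
    return _finalize("phased", rows, [])
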