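"""Donor/recipient informative-site index (unphased method).

At every site jointly called in a transplant pair, the two diploid
genotypes are compared as unordered allele pairs.  A site is *shared*
when the genotypes are identical; otherwise each individual's
*discriminating alleles* — alleles it carries that the other lacks —
are recorded, because a cfDNA read showing such an allele can be
attributed to that individual.  The per-site classes are:

=================  ==============================================
shared             identical genotypes, no discriminating alleles
donor-unique       only the donor has discriminating alleles
recipient-unique   only the recipient has discriminating alleles
both-unique        each carries an allele the other lacks
uninformative      genotypes differ but neither side has a novel
                   allele (unreachable for diploid genotypes; kept
                   for defensive exhaustiveness)
=================  ==============================================

Sites called in only one individual are routed to a separate
half-called tally and never classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SiteClass",
    "GenotypeCall",
    "SiteClassification",
    "InformativeSiteIndex",
    "classify_site",
    "build_index",
    "snp_density",
]


class SiteClass(str, Enum):
    SHARED = "shared"
    DONOR_UNIQUE = "donor-unique"
    RECIPIENT_UNIQUE = "recipient-unique"
    BOTH_UNIQUE = "both-unique"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at one site.

    ``alleles`` holds the two allele indices into ``(ref,) + alts``.
    When ``phased`` is True the order of ``alleles`` is the haplotype
    order; the genotype as an unordered pair is available through
    :meth:`genotype`.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    alleles: tuple[int, int]
    phased: bool = False
    annotations: Optional[object] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alts)
        for a in self.alleles:
            if not 0 <= a < n_alleles:
                raise ValueError(
                    f"allele index {a} out of range at {self.chrom}:{self.pos}"
                )

    def genotype(self) -> tuple[int, int]:
        """The genotype as a sorted (unordered) pair of allele indices."""
        a, b = self.alleles
        return (a, b) if a <= b else (b, a)

    def allele_bases(self) -> tuple[str, str]:
        """The two allele strings, in stored (haplotype) order."""
        declared = (self.ref,) + self.alts
        return declared[self.alleles[0]], declared[self.alleles[1]]


@dataclass(frozen=True)
class SiteClassification:
    site_class: SiteClass
    donor_discriminating: frozenset[int]
    recipient_discriminating: frozenset[int]


def classify_site(
    donor_gt: Sequence[int], recipient_gt: Sequence[int]
) -> SiteClassification:
    """Classify one jointly-called site and extract discriminating alleles.

    Both genotypes are unordered pairs of allele indices referring to
    the same ref/alt declaration.  Donor-discriminating alleles are
    those in the donor genotype absent from the recipient genotype,
    and conversely.
    """
    d = tuple(sorted(donor_gt))
    r = tuple(sorted(recipient_gt))
    if len(d) != 2 or len(r) != 2:
        raise ValueError("genotypes must be diploid (two allele indices)")
    if d == r:
        return SiteClassification(SiteClass.SHARED, frozenset(), frozenset())
    donor_disc = frozenset(set(d) - set(r))
    recip_disc = frozenset(set(r) - set(d))
    if donor_disc and recip_disc:
        cls = SiteClass.BOTH_UNIQUE
    elif donor_disc:
        cls = SiteClass.DONOR_UNIQUE
    elif recip_disc:
        cls = SiteClass.RECIPIENT_UNIQUE
    else:
        cls = SiteClass.UNINFORMATIVE
    return SiteClassification(cls, donor_disc, recip_disc)


_INDEX_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alts",
    "site_class",
    "donor_gt",
    "recipient_gt",
    "donor_disc",
    "recip_disc",
]


@dataclass
class InformativeSiteIndex:
    """Per-site classification table plus class tallies.

    ``sites`` has one row per jointly-called site with the class, both
    genotypes (allele indices as "a/b" strings) and the discriminating
    allele *bases* as comma-joined strings (empty when none).
    """

    sites: pd.DataFrame
    half_called: int = 0
    per_chrom_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _INDEX_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"index table missing columns: {missing}")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c.value: 0 for c in SiteClass}
        counts.update(self.sites["site_class"].value_counts().to_dict())
        return counts

    @property
    def n_informative(self) -> int:
        return int((self.sites["site_class"] != SiteClass.SHARED.value).sum())

    def summary(self) -> dict:
        return {
            "n_sites": int(len(self.sites)),
            "n_informative": self.n_informative,
            "half_called": self.half_called,
            "class_counts": self.class_counts,
            "per_chrom_counts": {k: dict(v) for k, v in self.per_chrom_counts.items()},
        }

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InformativeSiteIndex":
        sites = pd.read_csv(
            path,
            sep="\t",
            dtype={c: str for c in _INDEX_COLUMNS if c not in ("pos",)},
            keep_default_na=False,
        )
        sites["pos"] = sites["pos"].astype(int)
        idx = cls(sites=sites)
        idx.per_chrom_counts = _per_chrom_counts(sites)
        return idx


def _per_chrom_counts(sites: pd.DataFrame) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for (chrom, cls), n in sites.groupby(["chrom", "site_class"]).size().items():
        out.setdefault(chrom, {})[cls] = int(n)
    return out


def _check_sorted(calls: Sequence[GenotypeCall], label: str) -> None:
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for call in calls:
        if call.chrom not in last:
            if call.chrom in seen_order:
                raise ValueError(
                    f"{label} stream not sorted: chromosome {call.chrom} "
                    f"reappears at {call.chrom}:{call.pos}"
                )
            seen_order.append(call.chrom)
            last[call.chrom] = call.pos
        elif call.pos <= last[call.chrom]:
            raise ValueError(
                f"{label} stream not sorted at {call.chrom}:{call.pos} "
                f"(previous position {last[call.chrom]})"
            )
        else:
            last[call.chrom] = call.pos


def build_index(
    donor_calls: Iterable[GenotypeCall],
    recipient_calls: Iterable[GenotypeCall],
) -> InformativeSiteIndex:
    """Classify every jointly-called site in a single coordinated pass.

    Both streams must be sorted by chromosome then position; an
    unsorted stream raises an error naming the first offending
    position.  Sites present in only one stream are tallied as
    half-called and excluded from the table.
    """
    donor_list = list(donor_calls)
    recip_list = list(recipient_calls)
    _check_sorted(donor_list, "donor")
    _check_sorted(recip_list, "recipient")

    donor_by_site = {(c.chrom, c.pos): c for c in donor_list}
    recip_by_site = {(c.chrom, c.pos): c for c in recip_list}
    joint = [k for k in donor_by_site if k in recip_by_site]
    half_called = (len(donor_by_site) - len(joint)) + (len(recip_by_site) - len(joint))

    rows = []
    for key in joint:
        d = donor_by_site[key]
        r = recip_by_site[key]
        if d.ref != r.ref or d.alts != r.alts:
            raise ValueError(
                f"ref/alt declarations differ at {key[0]}:{key[1]}: "
                f"{d.ref}/{d.alts} vs {r.ref}/{r.alts}"
            )
        result = classify_site(d.genotype(), r.genotype())
        declared = (d.ref,) + d.alts
        rows.append(
            {
                "chrom": d.chrom,
                "pos": d.pos,
                "ref": d.ref,
                "alts": ",".join(d.alts),
                "site_class": result.site_class.value,
                "donor_gt": "/".join(map(str, d.genotype())),
                "recipient_gt": "/".join(map(str, r.genotype())),
                "donor_disc": ",".join(
                    declared[i] for i in sorted(result.donor_discriminating)
                ),
                "recip_disc": ",".join(
                    declared[i] for i in sorted(result.recipient_discriminating)
                ),
            }
        )
    sites = pd.DataFrame(rows, columns=_INDEX_COLUMNS)
    if len(sites):
        sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
    index = InformativeSiteIndex(sites=sites, half_called=half_called)
    index.per_chrom_counts = _per_chrom_counts(sites)
    return index


def snp_density(
    index: InformativeSiteIndex, chrom_lengths: dict[str, int]
) -> tuple[float, dict[str, float]]:
    """SNP density in sites per kilobase, overall and per chromosome.

    The overall density is length-weighted: total site count over
    total length.  Chromosomes present in ``chrom_lengths`` but absent
    from the index contribute zero sites (and their length) to the
    aggregate.
    """
    site_counts = index.sites.groupby("chrom").size().to_dict()
    for chrom in site_counts:
        if chrom not in chrom_lengths:
            raise ValueError(f"no length declared for chromosome {chrom}")
    per_chrom = {
        chrom: site_counts.get(chrom, 0) / (length / 1000.0)
        for chrom, length in chrom_lengths.items()
    }
    total_sites = sum(site_counts.values())
    total_kb = sum(chrom_lengths.values()) / 1000.0
    return total_sites / total_kb, per_chrom
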