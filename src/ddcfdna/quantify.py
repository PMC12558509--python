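"""Percent donor-derived cfDNA from informative-site allele counts.

cfDNA alleles are first *called* per site with a minimum read-support
rule (an allele is present when at least ``min_support`` reads carry
it; default 5, inclusive).  Two unphased estimators of the donor
fraction are then available, reported side by side because a
"percent ddcfDNA" can be denominated either in matched genotypes or
in reads:

``unphased-sitecount``
    numerator = informative sites whose donor-discriminating allele
    is called in the cfDNA; denominator adds the sites whose
    recipient-discriminating allele is called.  Simple and
    call-threshold dependent, so not an unbiased estimate of the
    mixing fraction.

``unphased-readfraction``
    over sites where the donor carries a discriminating allele and
    the recipient is homozygous for a non-discriminating allele,
    f̂ = Σ(discriminating-allele reads × w) / Σ depth with w = 2 when
    the donor is heterozygous for the discriminating allele and
    w = 1 when homozygous.  Under the read-mixture model this has
    expectation f when sequencing error is negligible; an optional
    background-error correction (see
    :func:`estimate_fraction_readfraction`) removes the O(ε) bias
    using an error rate estimated from shared homozygous sites.

Aggregates are pooled-count computations, never means of
per-chromosome values, so the pooled estimate equals the
depth-weighted combination of per-chromosome estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .index import InformativeSiteIndex

__all__ = [
    "CfdnaCounts",
    "AlleleCalls",
    "DonorFractionEstimate",
    "ContaminationResult",
    "call_cfdna_alleles",
    "estimate_fraction_sitecount",
    "estimate_fraction_readfraction",
    "estimate_background_error",
    "contamination_control",
]


class CfdnaCounts:
    """Per-site, per-allele cfDNA read counts.

    Backed by a table with columns ``chrom, pos, allele, count``
    (counts non-negative integers); site depth is the sum of the
    site's allele counts.
    """

    COLUMNS = ["chrom", "pos", "allele", "count"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"counts table missing columns: {missing}")
        table = table[self.COLUMNS].copy()
        table["pos"] = table["pos"].astype(int)
        table["count"] = table["count"].astype(int)
        if (table["count"] < 0).any():
            bad = table[table["count"] < 0].iloc[0]
            raise ValueError(
                f"negative read count at {bad['chrom']}:{bad['pos']} "
                f"allele {bad['allele']}"
            )
        self.table = table
        self._site_alleles: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.table)

    def site_alleles(self) -> dict[tuple[str, int], dict[str, int]]:
        """Mapping (chrom, pos) -> {allele: count}, cached."""
        if self._site_alleles is None:
            out: dict[tuple[str, int], dict[str, int]] = {}
            for chrom, pos, allele, count in self.table.itertuples(index=False):
                out.setdefault((chrom, pos), {})[allele] = count
            self._site_alleles = out
        return self._site_alleles

    def depths(self) -> dict[tuple[str, int], int]:
        return {
            site: sum(alleles.values()) for site, alleles in self.site_alleles().items()
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CfdnaCounts":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str}))


@dataclass
class AlleleCalls:
    """Present-allele sets per site after the read-support rule.

    Sites where no allele reached support are excluded from ``calls``
    and tallied in ``n_no_call`` (they never enter estimator
    denominators).
    """

    min_support: int
    calls: dict[tuple[str, int], frozenset[str]]
    n_no_call: int = 0

    def get(self, site: tuple[str, int]) -> frozenset[str]:
        return self.calls.get(site, frozenset())


def call_cfdna_alleles(counts: CfdnaCounts, min_support: int = 5) -> AlleleCalls:
    """Call an allele present at a site when its count >= ``min_support``."""
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    calls: dict[tuple[str, int], frozenset[str]] = {}
    n_no_call = 0
    for site, alleles in counts.site_alleles().items():
        present = frozenset(a for a, c in alleles.items() if c >= min_support)
        if present:
            calls[site] = present
        else:
            n_no_call += 1
    return AlleleCalls(min_support=min_support, calls=calls, n_no_call=n_no_call)


@dataclass
class DonorFractionEstimate:
    """Percent ddcfDNA per chromosome and pooled, with the counts used.

    ``per_chrom`` columns: chrom, numerator, denominator, percent
    (NaN where the denominator is zero).  ``percent`` is the pooled
    value; when the pooled denominator is zero it is NaN and the
    estimate is flagged "no informative coverage" rather than
    reported as 0.
    """

    method: str
    per_chrom: pd.DataFrame
    numerator: float
    denominator: float
    flags: list[str] = field(default_factory=list)

    @property
    def percent(self) -> float:
        if self.denominator == 0:
            return math.nan
        return 100.0 * self.numerator / self.denominator

    @property
    def no_coverage_chroms(self) -> list[str]:
        return self.per_chrom.loc[
            self.per_chrom["denominator"] == 0, "chrom"
        ].tolist()

    def per_chrom_percent(self) -> pd.Series:
        return self.per_chrom.set_index("chrom")["percent"]

    def to_tsv(self, path) -> None:
        self.per_chrom.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "percent": None if math.isnan(self.percent) else self.percent,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "flags": list(self.flags),
            "no_coverage_chroms": self.no_coverage_chroms,
        }


def _finalize(method: str, rows: list[dict], flags: list[str]) -> DonorFractionEstimate:
    per_chrom = pd.DataFrame(rows, columns=["chrom", "numerator", "denominator"])
    with np.errstate(invalid="ignore", divide="ignore"):
        per_chrom["percent"] = 100.0 * per_chrom["numerator"] / per_chrom[
            "denominator"
        ].replace(0, np.nan)
    num = float(per_chrom["numerator"].sum())
    den = float(per_chrom["denominator"].sum())
    if den == 0:
        flags = flags + ["no informative coverage"]
    return DonorFractionEstimate(
        method=method,
        per_chrom=per_chrom,
        numerator=num,
        denominator=den,
        flags=flags,
    )


def _disc_sets(row) -> tuple[frozenset[str], frozenset[str]]:
    donor = frozenset(row.donor_disc.split(",")) if row.donor_disc else frozenset()
    recip = frozenset(row.recip_disc.split(",")) if row.recip_disc else frozenset()
    return donor, recip


def estimate_fraction_sitecount(
    index: InformativeSiteIndex, calls: AlleleCalls
) -> DonorFractionEstimate:
    """Genotype-count estimator: fraction of informative sites whose
    discriminating allele is called in the cfDNA that are
    donor-discriminating."""
    rows = []
    for chrom, group in index.sites.groupby("chrom", sort=True):
        donor_pos = 0
        recip_pos = 0
        for row in group.itertuples(index=False):
            donor_disc, recip_disc = _disc_sets(row)
            if not donor_disc and not recip_disc:
                continue
            called = calls.get((row.chrom, row.pos))
            if donor_disc & called:
                donor_pos += 1
            if recip_disc & called:
                recip_pos += 1
        rows.append(
            {"chrom": chrom, "numerator": donor_pos, "denominator": donor_pos + recip_pos}
        )
    return _finalize("unphased-sitecount", rows, [])


def _readfraction_site_terms(
    index: InformativeSiteIndex, counts: CfdnaCounts
) -> pd.DataFrame:
    """Per-eligible-site terms: chrom, weighted discriminating reads
    (w·x), depth, and the bias weight k = w."""
    site_alleles = counts.site_alleles()
    records = []
    for row in index.sites.itertuples(index=False):
        donor_disc, _ = _disc_sets(row)
        if not donor_disc:
            continue
        r1, r2 = row.recipient_gt.split("/")
        if r1 != r2:  # recipient must be homozygous for attribution
            continue
        alleles = site_alleles.get((row.chrom, row.pos))
        if not alleles:
            continue
        d1, d2 = row.donor_gt.split("/")
        declared = (row.ref,) + tuple(row.alts.split(",") if row.alts else ())
        donor_bases = {declared[int(d1)], declared[int(d2)]}
        # w = 2 when the donor is het for the discriminating allele(s)
        w = 2.0 if (d1 != d2 and len(donor_disc & donor_bases) == 1) else 1.0
        x = sum(alleles.get(a, 0) for a in donor_disc)
        depth = sum(alleles.values())
        records.append(
            {"chrom": row.chrom, "wx": w * x, "depth": depth, "k_depth": w * depth}
        )
    return pd.DataFrame(records, columns=["chrom", "wx", "depth", "k_depth"])


def estimate_fraction_readfraction(
    index: InformativeSiteIndex,
    counts: CfdnaCounts,
    error_rate: float = 0.0,
) -> DonorFractionEstimate:
    """Read-denominated estimator of the donor fraction.

    With ``error_rate`` ε > 0 the pooled and per-chromosome raw
    ratios r = Σ(w·x)/Σdepth are corrected for background flips:
    E[r] = f(1−2ε) + ε·k̄ with k̄ the depth-weighted mean of the site
    weights, so f̂ = (r − ε·k̄)/(1−2ε).  ε may come from
    :func:`estimate_background_error`.  Corrected values are clamped
    at 0 (a flag records when clamping occurred).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    terms = _readfraction_site_terms(index, counts)
    flags: list[str] = []
    rows = []
    clamped = False
    for chrom in sorted(index.sites["chrom"].unique()):
        sub = terms[terms["chrom"] == chrom]
        depth = float(sub["depth"].sum())
        wx = float(sub["wx"].sum())
        if depth > 0 and error_rate > 0:
            kbar = float(sub["k_depth"].sum()) / depth
            corrected = (wx / depth - error_rate * kbar) / (1.0 - 2.0 * error_rate)
            if corrected < 0:
                corrected, clamped = 0.0, True
            wx = corrected * depth  # store corrected numerator on read scale
        rows.append({"chrom": chrom, "numerator": wx, "denominator": depth})
    if clamped:
        flags.append("clamped at 0 after error correction")
    if error_rate > 0:
        flags.append(f"background error correction applied (eps={error_rate:g})")
    return _finalize("unphased-readfraction", rows, flags)


def estimate_background_error(
    index: InformativeSiteIndex, counts: CfdnaCounts
) -> float:
    """Estimate the per-read allele-flip rate from shared homozygous sites.

    At a site where donor and recipient are identically homozygous,
    every read should carry that allele; any other allele observed is
    sequencing error.  Returns pooled mismatching reads over pooled
    depth (0.0 when no such sites are covered).
    """
    site_alleles = counts.site_alleles()
    err = 0
    total = 0
    for row in index.sites.itertuples(index=False):
        if row.site_class != "shared":
            continue
        a1, a2 = row.donor_gt.split("/")
        if a1 != a2:
            continue
        alleles = site_alleles.get((row.chrom, row.pos))
        if not alleles:
            continue
        declared = (row.ref,) + tuple(row.alts.split(",") if row.alts else ())
        hom_base = declared[int(a1)]
        depth = sum(alleles.values())
        err += depth - alleles.get(hom_base, 0)
        total += depth
    return err / total if total else 0.0


@dataclass(frozen=True)
class ContaminationResult:
    """Coverage of the absent-control chromosome (the Y-chromosome
    negative control stands in an all-female cohort)."""

    control_chrom: str
    covered_positions: int
    chrom_length: int

    @property
    def fraction(self) -> float:
        return self.covered_positions / self.chrom_length

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def contamination_control(
    counts: CfdnaCounts, control_chrom: str, chrom_lengths: dict[str, int]
) -> ContaminationResult:
    """Fraction of control-chromosome positions with any read."""
    if control_chrom not in chrom_lengths:
        raise ValueError(
            f"control chromosome {control_chrom!r} missing from genome declaration"
        )
    sub = counts.table[
        (counts.table["chrom"] == control_chrom) & (counts.table["count"] > 0)
    ]
    covered = sub["pos"].nunique()
    return ContaminationResult(
        control_chrom=control_chrom,
        covered_positions=int(covered),
        chrom_length=chrom_lengths[control_chrom],
    )
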