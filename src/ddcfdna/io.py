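"""VCF and tabular I/O for the pipeline.

VCF 4.x files are read and written through pysam.  Only the fields
the pipeline consumes are round-tripped: contig declarations, the
per-site genotype of the single sample (with phase), QUAL and the six
INFO hard-filter statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .filters import VariantAnnotations, VariantClass
from .index import GenotypeCall

__all__ = ["read_vcf", "write_vcf", "read_fragment_sizes", "write_fragment_sizes"]

_INFO_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
_INFO_DESCRIPTIONS = {
    "QD": "Variant confidence normalized by depth",
    "SOR": "Symmetric odds ratio of strand bias",
    "FS": "Phred-scaled Fisher strand bias",
    "MQ": "RMS mapping quality",
    "MQRankSum": "Rank-sum z of mapping qualities, alt vs ref reads",
    "ReadPosRankSum": "Rank-sum z of read position, alt vs ref reads",
}
_FILTER_REASONS = _INFO_KEYS + ("QUAL",)


def _variant_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    if len(ref) != len(alt):
        return VariantClass.INDEL
    return VariantClass.OTHER


def _build_header(
    chrom_lengths: dict[str, int], sample_name: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(chrom_lengths):
        header.contigs.add(chrom, length=chrom_lengths[chrom])
    for key in _INFO_KEYS:
        header.info.add(key, 1, "Float", _INFO_DESCRIPTIONS[key])
    for reason in _FILTER_REASONS:
        header.filters.add(reason, None, None, f"Hard-filter predicate {reason} failed")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_name)
    return header


def write_vcf(
    path,
    calls: list[GenotypeCall],
    chrom_lengths: dict[str, int],
    sample_name: str,
    filter_reasons: Optional[dict[tuple[str, int], tuple[str, ...]]] = None,
) -> None:
    """Write one sample's genotype calls as an uncompressed VCF.

    Calls carrying :class:`VariantAnnotations` get their statistics in
    INFO (QUAL in the QUAL column).  ``filter_reasons`` optionally
    sets the FILTER column to the failed predicate names per site
    (PASS otherwise).
    """
    header = _build_header(chrom_lengths, sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            record = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref,) + call.alts,
            )
            ann = call.annotations
            if isinstance(ann, VariantAnnotations):
                if ann.QUAL is not None:
                    record.qual = ann.QUAL
                for key in _INFO_KEYS:
                    value = getattr(ann, key)
                    if value is not None:
                        record.info[key] = value
            reasons = (filter_reasons or {}).get((call.chrom, call.pos))
            if reasons:
                for reason in reasons:
                    record.filter.add(reason)
            else:
                record.filter.add("PASS")
            record.samples[sample_name]["GT"] = call.alleles
            record.samples[sample_name].phased = call.phased
            vcf.write(record)


def read_vcf(path) -> list[GenotypeCall]:
    """Read a single-sample VCF into genotype calls.

    Records without a fully called genotype are skipped.  INFO
    statistics that are absent read back as None (missing-value
    semantics downstream).
    """
    path = Path(path)
    calls: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"{path} has {len(samples)} samples; expected a single-sample VCF"
            )
        sample = samples[0]
        for record in vcf:
            gt = record.samples[sample]["GT"]
            if gt is None or any(a is None for a in gt):
                continue
            alts = tuple(record.alts or ())
            if not alts:
                continue
            vclass = _variant_class(record.ref, alts[0])
            info = {
                key: (float(record.info[key]) if key in record.info else None)
                for key in _INFO_KEYS
            }
            ann = VariantAnnotations(
                variant_class=vclass,
                QUAL=None if record.qual is None else float(record.qual),
                **info,
            )
            calls.append(
                GenotypeCall(
                    chrom=record.chrom,
                    pos=record.pos,
                    ref=record.ref,
                    alts=alts,
                    alleles=(int(gt[0]), int(gt[1])),
                    phased=bool(record.samples[sample].phased),
                    annotations=ann,
                )
            )
    return calls


def read_fragment_sizes(path) -> np.ndarray:
    """One fragment size (bp) per line."""
    return np.loadtxt(path, dtype=float, ndmin=1)


def write_fragment_sizes(path, sizes) -> None:
    np.savetxt(path, np.asarray(sizes, dtype=float), fmt="%.3f")
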