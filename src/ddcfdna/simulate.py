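"""Synthetic transplant-pair genomes and cfDNA mixtures with known truth.

The generator emulates the data a donor/recipient heart-transplant
sequencing study produces, so every downstream stage can be tested
against ground truth:

* SNP sites placed along chromosomes at a configurable density
  (default 3.42 per kilobase, matching deep porcine WGS), counts
  Poisson per chromosome;
* diploid biallelic phased genotypes for two unrelated individuals
  drawn from a shared allele-frequency model;
* cfDNA read counts per site: Poisson depth, each read from the donor
  with probability ``f`` (the true donor fraction) else the
  recipient, carrying one of the source's two haplotype alleles
  uniformly, flipped to the other allele with probability ``ε``
  (sequencing error);
* condition-dependent log-normal fragment sizes (baseline vs
  rejection endpoint — graft apoptosis releases larger fragments in
  this model system);
* a designated control chromosome carried in headers but receiving
  zero sites and zero reads — the stand-in for a Y-chromosome
  negative control in an all-female cohort.

Reads are single-site observations: the donor/recipient comparison
downstream is per-genotype at single SNPs, so linked multi-SNP
fragments are not simulated.  Sequencing error flips to the one
alternative allele, the simplest model that can create false donor
signal at ``f = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .filters import VariantAnnotations, VariantClass, SNP_THRESHOLDS, INDEL_THRESHOLDS
from .index import GenotypeCall
from .quantify import CfdnaCounts

__all__ = [
    "SimulationConfig",
    "SiteBlock",
    "PairGenotypes",
    "TruthRecord",
    "SimulatedDataset",
    "simulate_sites",
    "simulate_pair_genotypes",
    "simulate_annotations",
    "simulate_cfdna_counts",
    "simulate_fragment_sizes",
    "simulate_dataset",
    "emit_dataset",
]

_BASES = np.array(["A", "C", "G", "T"])


def _default_chrom_lengths() -> dict[str, int]:
    # 18 autosomes (porcine karyotype) plus the absent-control chromosome.
    lengths = {f"chr{i}": 200_000 for i in range(1, 19)}
    lengths["chrY"] = 50_000
    return lengths


@dataclass
class SimulationConfig:
    """Parameters of one simulated transplant-pair dataset.

    ``chrom_lengths`` includes the ``control_chrom``, which receives
    no variant sites and no reads.  ``alt_freq_fixed`` pins every
    site's population alternate-allele frequency; otherwise
    frequencies are Beta(``alt_freq_alpha``, ``alt_freq_beta``).
    Fragment sizes are log-normal with condition-specific medians
    (``exp`` of the location parameter); the endpoint median must
    exceed the baseline median, reflecting the larger fragments
    observed at rejection.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    control_chrom: str = "chrY"
    snp_density: float = 3.42  # SNPs per kb
    alt_freq_alpha: float = 1.0
    alt_freq_beta: float = 1.0
    alt_freq_fixed: Optional[float] = None
    donor_fraction: float = 0.05
    mean_depth: float = 1000.0
    error_rate: float = 0.001
    fragment_window: tuple[int, int] = (40, 10_000)
    fragment_baseline_median: float = 2500.0
    fragment_endpoint_median: float = 4200.0
    fragment_log_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ValueError(f"donor_fraction must be in [0,1], got {self.donor_fraction}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if self.snp_density <= 0:
            raise ValueError(f"snp_density must be positive, got {self.snp_density}")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        if self.control_chrom not in self.chrom_lengths:
            raise ValueError(
                f"control chromosome {self.control_chrom!r} missing from chrom_lengths"
            )
        if self.fragment_window[0] >= self.fragment_window[1]:
            raise ValueError("fragment window min must be below max")
        if self.fragment_endpoint_median <= self.fragment_baseline_median:
            raise ValueError("endpoint fragment median must exceed baseline median")
        if self.alt_freq_fixed is not None and not 0.0 <= self.alt_freq_fixed <= 1.0:
            raise ValueError("alt_freq_fixed must be in [0,1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SiteBlock:
    """All simulated sites on one chromosome: positions (1-based),
    ref/alt bases, and the two phased haplotype rows per individual
    (0 = ref allele, 1 = alt allele; shape ``(2, n_sites)``)."""

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    donor: np.ndarray
    recipient: np.ndarray


@dataclass
class PairGenotypes:
    blocks: dict[str, SiteBlock]

    def to_calls(self) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
        """Materialise both individuals as sorted phased genotype streams."""
        donor_calls: list[GenotypeCall] = []
        recip_calls: list[GenotypeCall] = []
        for chrom in sorted(self.blocks):
            block = self.blocks[chrom]
            for i, pos in enumerate(block.positions):
                common = dict(
                    chrom=chrom,
                    pos=int(pos),
                    ref=str(block.ref[i]),
                    alts=(str(block.alt[i]),),
                    phased=True,
                )
                donor_calls.append(
                    GenotypeCall(
                        alleles=(int(block.donor[0, i]), int(block.donor[1, i])),
                        **common,
                    )
                )
                recip_calls.append(
                    GenotypeCall(
                        alleles=(int(block.recipient[0, i]), int(block.recipient[1, i])),
                        **common,
                    )
                )
        return donor_calls, recip_calls

    @property
    def n_sites(self) -> int:
        return sum(len(b.positions) for b in self.blocks.values())


@dataclass
class TruthRecord:
    """Ground truth for one simulated cfDNA sample: the true donor
    fraction and the per-site source of every read."""

    donor_fraction: float
    per_chrom: dict[str, pd.DataFrame]  # pos, donor_reads, recipient_reads

    def total_donor_reads(self) -> int:
        return int(sum(df["donor_reads"].sum() for df in self.per_chrom.values()))

    def total_reads(self) -> int:
        return int(
            sum(
                (df["donor_reads"] + df["recipient_reads"]).sum()
                for df in self.per_chrom.values()
            )
        )


def _rng(config: SimulationConfig, seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def simulate_sites(
    config: SimulationConfig, seed: Optional[int] = None
) -> dict[str, np.ndarray]:
    """Place SNP sites along every non-control chromosome.

    Per chromosome the site count is Poisson with mean
    ``length_kb × snp_density`` and positions are drawn uniformly
    without replacement, returned sorted and 1-based.  The control
    chromosome gets an empty position array.
    """
    rng = _rng(config, seed)
    sites: dict[str, np.ndarray] = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        if chrom == config.control_chrom:
            sites[chrom] = np.array([], dtype=np.int64)
            continue
        n = min(int(rng.poisson(length / 1000.0 * config.snp_density)), length)
        positions = np.sort(rng.choice(length, size=n, replace=False)) + 1
        sites[chrom] = positions.astype(np.int64)
    return sites


def simulate_pair_genotypes(
    sites: dict[str, np.ndarray],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> PairGenotypes:
    """Draw phased diploid biallelic genotypes for donor and recipient.

    Both individuals are independent draws from the same per-site
    allele-frequency model (Hardy-Weinberg within each individual,
    no kinship — study pairs are deliberately mismatched and
    unrelated).  Haplotype order is retained, so the truth phase is
    known.
    """
    rng = _rng(config, seed)
    blocks: dict[str, SiteBlock] = {}
    for chrom in sorted(sites):
        positions = sites[chrom]
        n = len(positions)
        if config.alt_freq_fixed is not None:
            freqs = np.full(n, config.alt_freq_fixed)
        else:
            freqs = rng.beta(config.alt_freq_alpha, config.alt_freq_beta, size=n)
        ref_idx = rng.integers(0, 4, size=n)
        # alt differs from ref: shift by 1..3 in base space
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        donor = (rng.random((2, n)) < freqs).astype(np.int8)
        recipient = (rng.random((2, n)) < freqs).astype(np.int8)
        blocks[chrom] = SiteBlock(
            chrom=chrom,
            positions=positions,
            ref=_BASES[ref_idx],
            alt=_BASES[alt_idx],
            donor=donor,
            recipient=recipient,
        )
    return PairGenotypes(blocks=blocks)


# Nominal (passing) draw ranges and per-predicate violating ranges.
_NOMINAL_RANGES = {
    "QD": (10.0, 30.0),
    "QUAL": (100.0, 1000.0),
    "SOR": (0.5, 2.5),
    "FS": (0.0, 30.0),
    "MQ": (50.0, 60.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_VIOLATION_RANGES = {
    ("QD", 2.0): (0.0, 1.9),
    ("QUAL", 30.0): (0.0, 29.0),
    ("SOR", 3.0): (3.5, 6.0),
    ("FS", 60.0): (61.0, 150.0),
    ("FS", 200.0): (201.0, 300.0),
    ("MQ", 40.0): (0.0, 39.0),
    ("MQRankSum", -12.5): (-20.0, -13.0),
    ("ReadPosRankSum", -8.0): (-15.0, -9.0),
    ("ReadPosRankSum", -20.0): (-30.0, -21.0),
}


@dataclass(frozen=True)
class AnnotatedSite:
    chrom: str
    pos: int
    annotations: VariantAnnotations


def simulate_annotations(
    sites: dict[str, np.ndarray],
    config: SimulationConfig,
    seed: Optional[int] = None,
    violation_fraction: float = 0.0,
    indel_fraction: float = 0.0,
) -> tuple[list[AnnotatedSite], dict]:
    """Attach the seven filter statistics to every site.

    Non-injected sites draw all statistics comfortably inside the
    pass region.  A ``violation_fraction`` of sites is injected with
    a value violating exactly one predicate (chosen uniformly from
    the predicate set of the record's class); the returned truth log
    lists every injected site under its predicate name, so a filter
    run can be checked against it exactly.  ``indel_fraction`` of
    records are labelled INDEL (their injectable predicates are the
    INDEL set).
    """
    if not 0.0 <= violation_fraction <= 1.0:
        raise ValueError("violation_fraction must be in [0,1]")
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction must be in [0,1]")
    rng = _rng(config, seed)

    flat: list[tuple[str, int]] = [
        (chrom, int(pos)) for chrom in sorted(sites) for pos in sites[chrom]
    ]
    n = len(flat)
    is_indel = rng.random(n) < indel_fraction
    n_inject = int(round(violation_fraction * n))
    inject_idx = set(
        rng.choice(n, size=n_inject, replace=False).tolist() if n_inject else []
    )

    records: list[AnnotatedSite] = []
    truth: dict[str, list[dict]] = {}
    for i, (chrom, pos) in enumerate(flat):
        stats = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in _NOMINAL_RANGES.items()
        }
        vclass = VariantClass.INDEL if is_indel[i] else VariantClass.SNP
        thresholds = INDEL_THRESHOLDS if is_indel[i] else SNP_THRESHOLDS
        if i in inject_idx:
            stat, _, cutoff = thresholds[rng.integers(0, len(thresholds))]
            lo, hi = _VIOLATION_RANGES[(stat, cutoff)]
            stats[stat] = float(rng.uniform(lo, hi))
            truth.setdefault(stat, []).append(
                {"chrom": chrom, "pos": pos, "value": stats[stat], "class": vclass.value}
            )
        records.append(
            AnnotatedSite(
                chrom=chrom,
                pos=pos,
                annotations=VariantAnnotations(variant_class=vclass, **stats),
            )
        )
    return records, {"n_injected": n_inject, "by_predicate": truth}


def simulate_cfdna_counts(
    pair: PairGenotypes,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[CfdnaCounts, TruthRecord]:
    """Mix donor and recipient reads into per-site allele counts.

    Per site: depth ~ Poisson(``mean_depth``); each read is donor
    with probability ``donor_fraction``; the read allele is one of
    the source's two haplotype alleles uniformly; with probability
    ``error_rate`` it is flipped to the other allele of the biallelic
    site.  Only alleles with at least one read get a row.
    """
    rng = _rng(config, seed)
    f = config.donor_fraction
    eps = config.error_rate
    rows: list[tuple[str, int, str, int]] = []
    truth_frames: dict[str, pd.DataFrame] = {}
    for chrom in sorted(pair.blocks):
        block = pair.blocks[chrom]
        n = len(block.positions)
        if n == 0:
            continue
        depth = rng.poisson(config.mean_depth, size=n)
        donor_reads = rng.binomial(depth, f)
        recip_reads = depth - donor_reads
        p_alt_donor = block.donor.mean(axis=0)
        p_alt_recip = block.recipient.mean(axis=0)
        alt_from_donor = rng.binomial(donor_reads, p_alt_donor)
        alt_from_recip = rng.binomial(recip_reads, p_alt_recip)
        alt_true = alt_from_donor + alt_from_recip
        ref_true = depth - alt_true
        # symmetric allele flips at rate eps
        alt = alt_true - rng.binomial(alt_true, eps) + rng.binomial(ref_true, eps)
        ref = depth - alt
        for i in range(n):
            pos = int(block.positions[i])
            if ref[i] > 0:
                rows.append((chrom, pos, str(block.ref[i]), int(ref[i])))
            if alt[i] > 0:
                rows.append((chrom, pos, str(block.alt[i]), int(alt[i])))
        truth_frames[chrom] = pd.DataFrame(
            {
                "pos": block.positions,
                "donor_reads": donor_reads,
                "recipient_reads": recip_reads,
            }
        )
    table = pd.DataFrame(rows, columns=["chrom", "pos", "allele", "count"])
    return CfdnaCounts(table), TruthRecord(donor_fraction=f, per_chrom=truth_frames)


def simulate_fragment_sizes(
    condition: str,
    n: int,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw ``n`` cfDNA fragment sizes (bp) for one condition.

    Log-normal with location ``log(median)`` for the condition and
    shared log-scale sigma; the endpoint location exceeds baseline by
    construction (validated in the config).
    """
    medians = {
        "baseline": config.fragment_baseline_median,
        "endpoint": config.fragment_endpoint_median,
    }
    if condition not in medians:
        raise ValueError(
            f"unknown condition {condition!r}; expected 'baseline' or 'endpoint'"
        )
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = _rng(config, seed)
    return rng.lognormal(
        mean=float(np.log(medians[condition])), sigma=config.fragment_log_sigma, size=n
    )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sites: dict[str, np.ndarray]
    pair: PairGenotypes
    annotated: list[AnnotatedSite]
    counts: CfdnaCounts
    truth: TruthRecord
    fragments_baseline: np.ndarray
    fragments_endpoint: np.ndarray


def simulate_dataset(
    config: SimulationConfig,
    n_fragments: int = 5000,
    violation_fraction: float = 0.0,
) -> SimulatedDataset:
    """Run the full generator with child seeds derived from the config seed."""
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(6)]
    sites = simulate_sites(config, seed=seeds[0])
    pair = simulate_pair_genotypes(sites, config, seed=seeds[1])
    annotated, _ = simulate_annotations(
        sites, config, seed=seeds[2], violation_fraction=violation_fraction
    )
    counts, truth = simulate_cfdna_counts(pair, config, seed=seeds[3])
    frag_base = simulate_fragment_sizes("baseline", n_fragments, config, seed=seeds[4])
    frag_end = simulate_fragment_sizes("endpoint", n_fragments, config, seed=seeds[5])
    return SimulatedDataset(
        config=config,
        sites=sites,
        pair=pair,
        annotated=annotated,
        counts=counts,
        truth=truth,
        fragments_baseline=frag_base,
        fragments_endpoint=frag_end,
    )


def emit_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the dataset as pipeline-readable files.

    donor.vcf / recipient.vcf (phased GT, INFO annotations, all
    configured contigs in the header including the control
    chromosome), cfdna_counts.tsv, fragment-size lists (one value per
    line) and truth.json.  Everything round-trips through the
    package's readers.
    """
    import json

    from .io import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    donor_calls, recip_calls = dataset.pair.to_calls()
    ann_by_site = {(a.chrom, a.pos): a.annotations for a in dataset.annotated}
    donor_calls = [
        replace(c, annotations=ann_by_site.get((c.chrom, c.pos))) for c in donor_calls
    ]
    recip_calls = [
        replace(c, annotations=ann_by_site.get((c.chrom, c.pos))) for c in recip_calls
    ]
    paths = {
        "donor_vcf": outdir / "donor.vcf",
        "recipient_vcf": outdir / "recipient.vcf",
        "cfdna_counts": outdir / "cfdna_counts.tsv",
        "fragments_baseline": outdir / "fragments_baseline.txt",
        "fragments_endpoint": outdir / "fragments_endpoint.txt",
        "truth": outdir / "truth.json",
    }
    write_vcf(paths["donor_vcf"], donor_calls, dataset.config.chrom_lengths, "DONOR")
    write_vcf(
        paths["recipient_vcf"], recip_calls, dataset.config.chrom_lengths, "RECIPIENT"
    )
    dataset.counts.to_tsv(paths["cfdna_counts"])
    np.savetxt(paths["fragments_baseline"], dataset.fragments_baseline, fmt="%.3f")
    np.savetxt(paths["fragments_endpoint"], dataset.fragments_endpoint, fmt="%.3f")
    truth_json = {
        "donor_fraction": dataset.truth.donor_fraction,
        "seed": dataset.config.seed,
        "total_donor_reads": dataset.truth.total_donor_reads(),
        "total_reads": dataset.truth.total_reads(),
        "per_chrom": {
            chrom: df.to_dict(orient="list")
            for chrom, df in dataset.truth.per_chrom.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return paths
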