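"""cfDNA allele calling and donor-fraction estimators: support
threshold semantics, analytic expectations, pooling conservation and
the negative-control check."""

import math

import numpy as np
import pandas as pd
import pytest

from ddcfdna.index import build_index
from ddcfdna.quantify import (
    AlleleCalls,
    CfdnaCounts,
    call_cfdna_alleles,
    contamination_control,
    estimate_background_error,
    estimate_fraction_readfraction,
    estimate_fraction_sitecount,
)
from ddcfdna.simulate import (
    SimulationConfig,
    simulate_cfdna_counts,
    simulate_pair_genotypes,
    simulate_sites,
)
from test_index import make_call


def counts_from_rows(rows):
    return CfdnaCounts(pd.DataFrame(rows, columns=["chrom", "pos", "allele", "count"]))


class TestAlleleCalls:
    def test_five_reads_is_inclusive(self):
        counts = counts_from_rows([("chr1", 10, "A", 100), ("chr1", 10, "G", 5)])
        calls = call_cfdna_alleles(counts, min_support=5)
        assert calls.get(("chr1", 10)) == {"A", "G"}

    def test_four_reads_is_below_threshold(self):
        counts = counts_from_rows([("chr1", 10, "A", 100), ("chr1", 10, "G", 4)])
        calls = call_cfdna_alleles(counts, min_support=5)
        assert calls.get(("chr1", 10)) == {"A"}

    def test_no_supported_allele_excluded_and_counted(self):
        counts = counts_from_rows([("chr1", 10, "A", 2), ("chr1", 10, "G", 3)])
        calls = call_cfdna_alleles(counts, min_support=5)
        assert calls.get(("chr1", 10)) == frozenset()
        assert calls.n_no_call == 1
        assert ("chr1", 10) not in calls.calls

    def test_invalid_support_threshold(self):
        with pytest.raises(ValueError):
            call_cfdna_alleles(counts_from_rows([]), min_support=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            counts_from_rows([("chr1", 10, "A", -1)])

    def test_raising_support_never_adds_alleles(self, small_dataset):
        calls5 = call_cfdna_alleles(small_dataset.counts, min_support=5)
        calls10 = call_cfdna_alleles(small_dataset.counts, min_support=10)
        for site, present in calls10.calls.items():
            assert present <= calls5.get(site)


def two_class_index(n_donor_pos, n_recip_pos):
    """Index of donor-unique then recipient-unique sites on one chromosome."""
    donor, recipient = [], []
    pos = 0
    for _ in range(n_donor_pos):
        pos += 1
        donor.append(make_call("chr1", pos, (0, 1)))
        recipient.append(make_call("chr1", pos, (0, 0)))
    for _ in range(n_recip_pos):
        pos += 1
        donor.append(make_call("chr1", pos, (0, 0)))
        recipient.append(make_call("chr1", pos, (0, 1)))
    return build_index(donor, recipient), pos


class TestSitecountEstimator:
    def test_percentage_arithmetic(self):
        index, n = two_class_index(30, 970)
        calls = AlleleCalls(
            min_support=5,
            calls={("chr1", p): frozenset({"A", "G"}) for p in range(1, n + 1)},
        )
        est = estimate_fraction_sitecount(index, calls)
        assert est.percent == pytest.approx(3.0)
        assert est.numerator == 30 and est.denominator == 1000

    def test_recipient_only_cfdna_gives_zero(self):
        index, n = two_class_index(10, 10)
        # only the shared/recipient allele A is ever called
        calls = AlleleCalls(
            min_support=5, calls={("chr1", p): frozenset({"A"}) for p in range(1, n + 1)}
        )
        est = estimate_fraction_sitecount(index, calls)
        # recipient-unique sites have discriminating allele G -> also absent;
        # denominator comes only from donor sites' recipient evidence: here zero
        assert est.numerator == 0

    def test_empty_calls_flagged_no_coverage(self):
        index, _ = two_class_index(5, 5)
        est = estimate_fraction_sitecount(index, AlleleCalls(5, {}))
        assert math.isnan(est.percent)
        assert "no informative coverage" in est.flags

    def test_monotone_in_donor_fraction(self):
        base = dict(chrom_lengths={"chr1": 300_000, "chrY": 1000}, mean_depth=200.0)
        means = []
        for f in (0.01, 0.02, 0.05, 0.10):
            estimates = []
            for seed in range(5):
                config = SimulationConfig(donor_fraction=f, seed=seed, **base)
                sites = simulate_sites(config, seed=seed)
                pair = simulate_pair_genotypes(sites, config, seed=seed + 100)
                counts, _ = simulate_cfdna_counts(pair, config, seed=seed + 200)
                index = build_index(*pair.to_calls())
                calls = call_cfdna_alleles(counts)
                estimates.append(estimate_fraction_sitecount(index, calls).percent)
            means.append(np.mean(estimates))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestReadFractionEstimator:
    def test_analytic_hom_donor_example(self):
        # donor hom for the discriminating allele, 7 of 100 reads carry it
        donor = [make_call("chr1", p, (1, 1)) for p in range(1, 11)]
        recipient = [make_call("chr1", p, (0, 0)) for p in range(1, 11)]
        index = build_index(donor, recipient)
        counts = counts_from_rows(
            [row for p in range(1, 11) for row in
             [("chr1", p, "A", 93), ("chr1", p, "G", 7)]]
        )
        est = estimate_fraction_readfraction(index, counts)
        assert est.percent == pytest.approx(7.0)

    def test_het_donor_weight_doubles_signal(self):
        donor = [make_call("chr1", 1, (0, 1))]
        recipient = [make_call("chr1", 1, (0, 0))]
        index = build_index(donor, recipient)
        counts = counts_from_rows([("chr1", 1, "A", 95), ("chr1", 1, "G", 5)])
        est = estimate_fraction_readfraction(index, counts)
        assert est.percent == pytest.approx(10.0)  # 2 * 5/100

    def test_recipient_het_sites_excluded(self):
        donor = [make_call("chr1", 1, (1, 1), alts=("G", "T"))]
        recipient = [make_call("chr1", 1, (0, 2), alts=("G", "T"))]
        index = build_index(donor, recipient)
        counts = counts_from_rows([("chr1", 1, "A", 50), ("chr1", 1, "G", 50)])
        est = estimate_fraction_readfraction(index, counts)
        assert est.denominator == 0

    def test_zero_fraction_zero_error_is_exactly_zero(self):
        config = SimulationConfig(
            chrom_lengths={"chr1": 100_000, "chrY": 1000},
            donor_fraction=0.0,
            error_rate=0.0,
            mean_depth=100.0,
            seed=31,
        )
        sites = simulate_sites(config, seed=31)
        pair = simulate_pair_genotypes(sites, config, seed=32)
        counts, _ = simulate_cfdna_counts(pair, config, seed=33)
        index = build_index(*pair.to_calls())
        est = estimate_fraction_readfraction(index, counts)
        assert est.percent == 0.0

    def test_pooled_equals_depth_weighted_per_chrom(self, small_dataset):
        index = build_index(*small_dataset.pair.to_calls())
        est = estimate_fraction_readfraction(index, small_dataset.counts)
        weighted = (
            est.per_chrom["percent"].fillna(0.0) * est.per_chrom["denominator"]
        ).sum() / est.per_chrom["denominator"].sum()
        assert est.percent == pytest.approx(weighted)

    def test_background_error_estimate_recovers_epsilon(self, small_dataset):
        index = build_index(*small_dataset.pair.to_calls())
        eps_hat = estimate_background_error(index, small_dataset.counts)
        eps = small_dataset.config.error_rate
        # pooled binomial SE over shared-hom depth
        shared_hom = (index.sites["site_class"] == "shared").sum()
        total_depth = shared_hom * small_dataset.config.mean_depth
        se = math.sqrt(eps / total_depth)
        assert abs(eps_hat - eps) < 4 * se

    def test_invalid_error_rate_rejected(self, small_dataset):
        index = build_index(*small_dataset.pair.to_calls())
        with pytest.raises(ValueError):
            estimate_fraction_readfraction(index, small_dataset.counts, error_rate=0.6)


class TestContaminationControl:
    def test_simulator_output_is_exactly_zero(self, small_dataset):
        result = contamination_control(
            small_dataset.counts,
            small_dataset.config.control_chrom,
            small_dataset.config.chrom_lengths,
        )
        assert result.fraction == 0.0

    def test_single_read_on_control(self):
        counts = counts_from_rows([("chrY", 500, "A", 1)])
        result = contamination_control(counts, "chrY", {"chrY": 10_000})
        assert result.percent == pytest.approx(0.01)

    def test_undeclared_control_is_error(self):
        with pytest.raises(ValueError, match="control"):
            contamination_control(counts_from_rows([]), "chrY", {"chr1": 100})
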