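"""Generator statistical properties: site placement, genotype
frequencies, read mixing, fragment sizes, determinism and emission."""

import math

import numpy as np
import pytest

from ddcfdna.io import read_vcf
from ddcfdna.simulate import (
    SimulationConfig,
    emit_dataset,
    simulate_cfdna_counts,
    simulate_dataset,
    simulate_fragment_sizes,
    simulate_pair_genotypes,
    simulate_sites,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"donor_fraction": 1.5},
            {"donor_fraction": -0.1},
            {"error_rate": 0.5},
            {"snp_density": 0.0},
            {"chrom_lengths": {"chr1": 0, "chrY": 100}},
            {"chrom_lengths": {"chr1": 100}},  # control chromosome missing
            {"fragment_window": (10_000, 40)},
            {"fragment_baseline_median": 5000.0, "fragment_endpoint_median": 4000.0},
            {"alt_freq_fixed": 1.2},
            {"mean_depth": 0.0},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateSites:
    def test_positions_one_based_strictly_increasing(self, small_config):
        sites = simulate_sites(small_config, seed=1)
        for chrom, positions in sites.items():
            if len(positions):
                assert positions[0] >= 1
                assert (np.diff(positions) > 0).all()

    def test_control_chromosome_has_no_sites(self, small_config):
        sites = simulate_sites(small_config, seed=1)
        assert len(sites[small_config.control_chrom]) == 0

    def test_site_count_scales_with_length(self):
        # 3x the length -> ~3x the sites, within Poisson tolerance
        config = SimulationConfig(
            chrom_lengths={"chr1": 100_000, "chr2": 300_000, "chrY": 1000}, seed=2
        )
        counts1, counts2 = [], []
        for seed in range(30):
            sites = simulate_sites(config, seed=seed)
            counts1.append(len(sites["chr1"]))
            counts2.append(len(sites["chr2"]))
        ratio = np.mean(counts2) / np.mean(counts1)
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_fixed_seed_reproduces_exact_site_list(self, small_config):
        a = simulate_sites(small_config, seed=42)
        b = simulate_sites(small_config, seed=42)
        for chrom in a:
            np.testing.assert_array_equal(a[chrom], b[chrom])


class TestPairGenotypes:
    def test_hardy_weinberg_at_half_frequency(self):
        # closed form at p=0.5: hom-ref/het/hom-alt = 0.25/0.5/0.25
        config = SimulationConfig(
            chrom_lengths={"chr1": 3_000_000, "chrY": 1000},
            alt_freq_fixed=0.5,
            seed=3,
        )
        sites = simulate_sites(config, seed=3)
        pair = simulate_pair_genotypes(sites, config, seed=4)
        block = pair.blocks["chr1"]
        n = len(block.positions)
        assert n > 9000
        dosage = block.donor.sum(axis=0)
        for target, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            observed = (dosage == target).mean()
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se

    def test_zero_frequency_means_all_hom_ref(self, small_config):
        config = SimulationConfig(
            chrom_lengths=small_config.chrom_lengths, alt_freq_fixed=0.0, seed=5
        )
        sites = simulate_sites(config, seed=5)
        pair = simulate_pair_genotypes(sites, config, seed=6)
        for block in pair.blocks.values():
            assert not block.donor.any()
            assert not block.recipient.any()

    def test_same_seed_identical_output(self, small_config):
        sites = simulate_sites(small_config, seed=7)
        a = simulate_pair_genotypes(sites, small_config, seed=8)
        b = simulate_pair_genotypes(sites, small_config, seed=8)
        for chrom in a.blocks:
            np.testing.assert_array_equal(a.blocks[chrom].donor, b.blocks[chrom].donor)
            np.testing.assert_array_equal(a.blocks[chrom].ref, b.blocks[chrom].ref)


class TestCfdnaMixing:
    @pytest.mark.parametrize("f,source_is_donor", [(0.0, False), (1.0, True)])
    def test_pure_mixtures_error_free(self, f, source_is_donor):
        config = SimulationConfig(
            chrom_lengths={"chr1": 50_000, "chrY": 1000},
            donor_fraction=f,
            error_rate=0.0,
            mean_depth=50.0,
            seed=9,
        )
        sites = simulate_sites(config, seed=9)
        pair = simulate_pair_genotypes(sites, config, seed=10)
        _, truth = simulate_cfdna_counts(pair, config, seed=11)
        donor_reads = truth.total_donor_reads()
        total = truth.total_reads()
        assert donor_reads == (total if source_is_donor else 0)

    def test_donor_read_share_converges_to_f(self):
        config = SimulationConfig(
            chrom_lengths={"chr1": 1_000_000, "chrY": 1000},
            donor_fraction=0.05,
            mean_depth=300.0,
            seed=12,
        )
        sites = simulate_sites(config, seed=12)
        pair = simulate_pair_genotypes(sites, config, seed=13)
        _, truth = simulate_cfdna_counts(pair, config, seed=14)
        total = truth.total_reads()
        share = truth.total_donor_reads() / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(share - 0.05) < 3 * se

    def test_counts_sum_to_truth_depth(self, small_dataset):
        depths = small_dataset.counts.depths()
        for chrom, frame in small_dataset.truth.per_chrom.items():
            for pos, d_reads, r_reads in frame.itertuples(index=False):
                assert depths.get((chrom, int(pos)), 0) == d_reads + r_reads


class TestFragmentSizes:
    def test_zero_draws_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate_fragment_sizes("baseline", 0, small_config)

    def test_unknown_condition_rejected(self, small_config):
        with pytest.raises(ValueError, match="condition"):
            simulate_fragment_sizes("relapse", 10, small_config)

    def test_baseline_median_matches_lognormal_closed_form(self, small_config):
        sizes = simulate_fragment_sizes("baseline", 10_000, small_config, seed=15)
        assert np.median(sizes) == pytest.approx(
            small_config.fragment_baseline_median, rel=0.05
        )

    def test_endpoint_larger_than_baseline(self, small_config):
        base = simulate_fragment_sizes("baseline", 10_000, small_config, seed=16)
        end = simulate_fragment_sizes("endpoint", 10_000, small_config, seed=17)
        assert end.mean() > base.mean()


class TestEmitDataset:
    def test_round_trip_and_truth(self, tmp_path, small_dataset):
        paths = emit_dataset(small_dataset, tmp_path)
        donor = read_vcf(paths["donor_vcf"])
        expected_donor, _ = small_dataset.pair.to_calls()
        assert [(c.chrom, c.pos, c.alleles, c.phased) for c in donor] == [
            (c.chrom, c.pos, c.alleles, c.phased) for c in expected_donor
        ]
        import json

        truth = json.loads(paths["truth"].read_text())
        assert truth["donor_fraction"] == small_dataset.config.donor_fraction

    def test_control_chrom_in_header_but_no_counts(self, tmp_path, small_dataset):
        import pysam

        paths = emit_dataset(small_dataset, tmp_path)
        with pysam.VariantFile(str(paths["donor_vcf"])) as vcf:
            assert small_dataset.config.control_chrom in vcf.header.contigs
        counts = small_dataset.counts.table
        assert (counts["chrom"] == small_dataset.config.control_chrom).sum() == 0

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(
            chrom_lengths={"chr1": 30_000, "chrY": 1000}, seed=77
        )
        paths_a = emit_dataset(simulate_dataset(config, n_fragments=100), tmp_path / "a")
        paths_b = emit_dataset(simulate_dataset(config, n_fragments=100), tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes()
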