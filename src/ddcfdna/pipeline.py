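"""End-to-end orchestration: simulate → filter → index → quantify → stats.

``run_all`` executes every stage in order against a simulated
transplant-pair dataset, writes all intermediate files into the
output directory, and records a manifest (seed, configuration echo,
SHA-256 digest of every output, per-stage summaries).  All
randomness derives from the configuration seed, so a rerun with an
identical configuration is byte-identical, manifest included.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import __version__
from .filters import FilterSummary, filter_stream
from .fragments import DEFAULT_WINDOW, mean_fragment_size
from .index import build_index, snp_density
from .io import read_fragment_sizes, read_vcf
from .phased import build_phased_sets, estimate_fraction_phased, match_cfdna_to_sets
from .quantify import (
    CfdnaCounts,
    call_cfdna_alleles,
    contamination_control,
    estimate_background_error,
    estimate_fraction_readfraction,
    estimate_fraction_sitecount,
)
from .rejection import concordance_report, fig4_report
from .simulate import SimulationConfig, emit_dataset, simulate_dataset

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    outdir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_support: int = 5
    fragment_window: tuple[float, float] = DEFAULT_WINDOW
    n_fragments: int = 5000
    violation_fraction: float = 0.0
    seed: Optional[int] = None  # overrides sim.seed when given

    def resolved_sim(self) -> SimulationConfig:
        if self.seed is None:
            return self.sim
        return replace(self.sim, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_sim()
    manifest: dict = {
        "package_version": __version__,
        "seed": sim.seed,
        "config": {
            **asdict(sim),
            "min_support": config.min_support,
            "fragment_window": list(config.fragment_window),
        },
        "stages": {},
    }

    # simulate
    dataset = simulate_dataset(
        sim,
        n_fragments=config.n_fragments,
        violation_fraction=config.violation_fraction,
    )
    paths = emit_dataset(dataset, outdir)
    manifest["stages"]["simulate"] = {
        "n_sites": dataset.pair.n_sites,
        "true_donor_fraction": dataset.truth.donor_fraction,
    }

    # filter
    donor_calls = read_vcf(paths["donor_vcf"])
    recip_calls = read_vcf(paths["recipient_vcf"])
    donor_summary, recip_summary = FilterSummary(), FilterSummary()
    donor_pass = [r for r, v in filter_stream(donor_calls, donor_summary) if v.passed]
    recip_pass = [r for r, v in filter_stream(recip_calls, recip_summary) if v.passed]
    manifest["stages"]["filter"] = {
        "donor": donor_summary.as_dict(),
        "recipient": recip_summary.as_dict(),
    }

    # index (unphased)
    index = build_index(donor_pass, recip_pass)
    index_path = outdir / "index.tsv"
    index.to_tsv(index_path)
    paths["index"] = index_path
    overall_density, _ = snp_density(
        index,
        {c: l for c, l in sim.chrom_lengths.items() if c != sim.control_chrom},
    )
    manifest["stages"]["index"] = {
        **index.summary(),
        "snp_density_per_kb": overall_density,
    }

    # quantify (both unphased estimators + phased)
    counts = CfdnaCounts.from_tsv(paths["cfdna_counts"])
    calls = call_cfdna_alleles(counts, min_support=config.min_support)
    est_site = estimate_fraction_sitecount(index, calls)
    eps_hat = estimate_background_error(index, counts)
    est_read = estimate_fraction_readfraction(index, counts, error_rate=eps_hat)
    donor_set, recip_set = build_phased_sets(donor_pass, recip_pass)
    matched = match_cfdna_to_sets(donor_set, recip_set, calls)
    est_phased = estimate_fraction_phased(matched)
    for est, name in (
        (est_site, "estimate_sitecount.tsv"),
        (est_read, "estimate_readfraction.tsv"),
        (est_phased, "estimate_phased.tsv"),
    ):
        est.to_tsv(outdir / name)
        paths[name.removesuffix(".tsv")] = outdir / name
    try:
        donor_r, recip_r = concordance_report(est_phased, est_site)
        concordance = {"donor": donor_r.r, "recipient": recip_r.r}
    except ValueError:  # too few chromosomes or zero variance (e.g. f = 0)
        concordance = {"donor": None, "recipient": None}
    control = contamination_control(counts, sim.control_chrom, sim.chrom_lengths)
    manifest["stages"]["quantify"] = {
        "min_support": config.min_support,
        "n_no_call_sites": calls.n_no_call,
        "background_error_estimate": eps_hat,
        "sitecount": est_site.summary(),
        "readfraction": est_read.summary(),
        "phased": est_phased.summary(),
        "concordance_r_donor": concordance["donor"],
        "concordance_r_recipient": concordance["recipient"],
        "control_chrom_covered_percent": control.percent,
    }

    # fragment statistics
    base = read_fragment_sizes(paths["fragments_baseline"])
    end = read_fragment_sizes(paths["fragments_endpoint"])
    base_mean = mean_fragment_size(base, config.fragment_window)
    end_mean = mean_fragment_size(end, config.fragment_window)
    manifest["stages"]["fragments"] = {
        "baseline_mean_bp": base_mean.mean,
        "endpoint_mean_bp": end_mean.mean,
        "baseline_n_used": base_mean.n_used,
        "endpoint_n_used": end_mean.n_used,
    }

    # cohort rejection statistics (packaged fixture)
    fig4 = fig4_report()
    manifest["stages"]["rejection_stats"] = {
        key: {
            "inputs": entry["inputs"],
            **(
                {"r": entry["result"].r, "p": entry["result"].p}
                if hasattr(entry["result"], "r")
                else {"p_one_tailed": entry["result"].p_one_tailed}
            ),
        }
        for key, entry in fig4.items()
    }

    manifest["outputs"] = {
        name: {"path": str(path), "sha256": _sha256(Path(path))}
        for name, path in sorted(paths.items())
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
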