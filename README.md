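# ddcfdna

Quantification of **donor-derived cell-free DNA (ddcfDNA)** from
whole-genome donor/recipient genotypes and plasma cfDNA allele counts,
for transplant-rejection monitoring — built around a porcine (Yucatan
pig) heterotopic heart-transplant model, where the percentage of
circulating cfDNA attributable to the allograft rises with acute
rejection.

The package is aimed at researchers building cfDNA-based chimerism
assays: it implements the full analysis downstream of variant calling
(the upstream read processing — alignment, GATK calling, read-backed
phasing — is consumed, not re-implemented), together with a synthetic
transplant-pair generator so every stage is testable at a known donor
fraction.

## What it computes

Given diploid genotypes of a donor–recipient pair at shared SNP sites
and per-site cfDNA read counts:

1. **Hard filtering.** Variant records are excluded by the standard
   fixed-threshold predicates — SNPs fail on
   QD < 2.0, QUAL < 30.0, SOR > 3.0, FS > 60.0, MQ < 40.0,
   MQRankSum < −12.5 or ReadPosRankSum < −8.0; INDELs on QD < 2.0,
   QUAL < 30.0, FS > 200.0 or ReadPosRankSum < −20.0. All
   inequalities are strict; missing statistics pass with a logged
   count.
2. **Informative-site index (unphased).** Each jointly-called site is
   classified as shared, donor-unique, recipient-unique or
   both-unique, recording each side's *discriminating alleles* (the
   alleles the other individual lacks).
3. **Phased variant sets.** From phased genotypes, an allele is
   donor-derived iff it lies on a donor haplotype and on neither
   recipient haplotype (symmetrically for the recipient); the two
   sets are disjoint by construction.
4. **cfDNA allele calls.** An allele is present at a site when at
   least 5 reads support it (inclusive, configurable).
5. **Donor-fraction estimation.** Per chromosome and pooled:
   - *site-count*: `% = 100 · (# sites with donor-discriminating
     allele called) / (that + # sites with recipient-discriminating
     allele called)` — and the phased analogue over set members;
   - *read-fraction*: over sites where the recipient is homozygous
     and the donor carries a discriminating allele,
     `f̂ = Σ(wᵢ·xᵢ) / Σ dᵢ`, with `xᵢ` the discriminating-allele
     reads, `dᵢ` the depth and `wᵢ = 2` (donor heterozygous) or `1`
     (homozygous), so that `E[f̂] = f` under the read-mixture model;
     an optional background-error correction
     `f̂ = (r − ε·k̄)/(1 − 2ε)` removes the sequencing-error bias with
     ε estimated from shared homozygous sites.
6. **Controls and markers.** Coverage of an absent control chromosome
   (the Y-chromosome negative control in an all-female cohort);
   windowed mean cfDNA fragment size in [40, 10000] bp; and the
   six-animal cohort statistics: Pearson correlations of %ddcfDNA
   with ln(troponin), time to rejection and endpoint fragment size,
   plus a paired one-tailed t-test of endpoint vs baseline fragment
   sizes.

## Worked example

```python
from ddcfdna import *
from ddcfdna.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(
    chrom_lengths={**{f"chr{i}": 200_000 for i in range(1, 19)}, "chrY": 10_000},
    donor_fraction=0.05, mean_depth=1000.0, error_rate=0.001, seed=1,
)
ds = simulate_dataset(config)
donor, recipient = ds.pair.to_calls()
index = build_index(donor, recipient)
print(f"jointly called sites: {len(index.sites)}  informative: {index.n_informative}")

calls = call_cfdna_alleles(ds.counts, min_support=5)
eps = estimate_background_error(index, ds.counts)
est = estimate_fraction_readfraction(index, ds.counts, error_rate=eps)
print(f"background error estimate: {eps:.2e}")
print(f"read-fraction %ddcfDNA: {est.percent:.3f} (truth 5.0)")

for key, entry in fig4_report().items():
    res = entry["result"]
    if hasattr(res, "r"):
        print(f"{key}: r={res.r:.2f} p={res.p:.3f}")
    else:
        print(f"{key}: one-tailed p={res.p_one_tailed:.3f}")
```

prints

```
jointly called sites: 12304  informative: 5704
background error estimate: 1.01e-03
read-fraction %ddcfDNA: 4.995 (truth 5.0)
troponin: r=0.80 p=0.057
time_to_rejection: r=-0.66 p=0.157
time_to_rejection_uncensored_only: r=-0.67 p=0.214
endpoint_fragment: r=0.95 p=0.004
fragment_growth: one-tailed p=0.003
```

The simulated mixture at a true donor fraction of 5% is recovered as
4.995% by the read-fraction estimator after subtracting the estimated
sequencing-error background (≈10⁻³ per read). The cohort report
reproduces the rejection-marker statistics from the packaged
six-animal table: %ddcfDNA correlates with log troponin (r = 0.80),
negatively with time to rejection (r = −0.66, the non-rejecting
animal entered at its sacrifice day with a sensitivity recomputation
without it), strongly with endpoint fragment size (r = 0.95), and
fragments are significantly larger at the rejection endpoint
(p = 0.003).

A command-line interface mirrors the stages
(`ddcfdna simulate | filter | index | quantify | quantify-phased |
fragstats | rejection-stats | run-all`); `run-all` writes every
intermediate file plus a manifest with content digests, and reruns
with the same seed are byte-identical.

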