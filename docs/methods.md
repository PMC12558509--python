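# Methods

## Problem and model

A transplanted organ under immune attack releases DNA fragments into
the recipient's plasma. With donor and recipient genomes sequenced,
any site where their genotypes differ is *informative*: a cfDNA read
(or a genotype call) carrying an allele only one individual possesses
can be attributed to that individual. The quantity of interest is
the donor fraction f — the proportion of cfDNA reads originating
from the graft — reported as percent ddcfDNA.

The read-level model used throughout (simulator and estimator
derivations): at an informative site with depth d, each read is drawn
from the donor with probability f, otherwise from the recipient; the
read's allele is one of the source's two haplotype alleles with equal
probability; with probability ε it is flipped to the other allele of
the biallelic site. Reads are independent across and within sites
(single-site observations; fragment linkage is not modelled because
the comparison is per-SNP).

## Filtering

Hard-filter predicates operate on the seven per-site statistics
(QD, QUAL, SOR, FS, MQ, MQRankSum, ReadPosRankSum), with separate
threshold sets for SNPs and INDELs. Two semantic decisions are fixed
here: every inequality is strict, so a value exactly at a threshold
passes; and a missing statistic cannot fail its predicate — it
passes, with the number of such non-evaluations counted in the filter
summary so partially-annotated inputs are auditable. Same-length
multi-nucleotide substitutions belong to neither predicate set and
are routed out as unclassifiable rather than silently dropped.

## The informative index and discriminating alleles

"Unique vs shared" is operationalised at two levels. The site class
(shared / donor-unique / recipient-unique / both-unique) compares the
diploid genotypes as unordered pairs. The *discriminating-allele
sets* (donor alleles absent from the recipient, and conversely) are
stored per site because cfDNA evidence is per-allele: a donor 0/1 vs
recipient 1/1 site differs in genotype yet offers the donor no
unique allele — it contributes the donor-discriminating allele 0 and
nothing on the recipient side. Sites called in only one individual
are counted as half-called and excluded from quantification, so
missingness is never conflated with uniqueness. Coordinates are
1-based (VCF convention) throughout.

At single biallelic SNPs the phased assignment (allele on ≥1 donor
haplotype and neither recipient haplotype) coincides exactly with the
unphased discriminating-allele sets — phase adds information only for
multi-site haplotype comparisons, which are out of scope — and the
test suite asserts this equivalence; the two pipelines therefore act
as mutual cross-checks, mirroring the near-perfect concordance the
two methods show in practice.

## Estimators

Two unphased estimators are reported side by side, because "percent
ddcfDNA" can be denominated in matched genotypes or in reads.

**Site-count** (and its phased analogue): the fraction of
informative sites (set members) whose discriminating allele is called
in the cfDNA under the ≥5-read support rule. It is simple and
matches the genotype-comparison description of the assay, but its
value depends on depth and the support threshold, so it is *not* an
unbiased estimate of f; the report tags it distinctly. Sites where
no allele reaches support are excluded from denominators and counted.

**Read-fraction** (the parameter-recovery surface): over sites where
the recipient is homozygous for a non-discriminating allele and the
donor carries a discriminating allele,

    f̂_raw = Σᵢ wᵢ xᵢ / Σᵢ dᵢ,   wᵢ = 2 (donor het), 1 (donor hom)

with xᵢ the discriminating-allele read count. The weight makes the
estimator unbiased under the error-free mixture model: a het donor
transmits its discriminating allele on only half its reads.
Recipient-heterozygous sites are excluded since reads cannot be
attributed there.

With sequencing error the raw ratio has expectation
f(1−2ε) + ε·k̄, where k̄ = Σwᵢdᵢ/Σdᵢ (for a het donor both the loss
of true signal and the gain of false signal scale with w). The
corrected estimator

    f̂ = (f̂_raw − ε·k̄) / (1 − 2ε)

removes this bias; at the default ε = 0 it is the identity. ε can be
supplied or estimated from the data: at sites where donor and
recipient are identically homozygous, every non-matching read is an
error, and the pooled mismatch rate estimates ε with negligible
variance at typical depths. This background subtraction is standard
practice in ddcfDNA assays, where raw error rates (~10⁻³) are
commensurate with low clinical donor fractions. Corrected values are
clamped at 0 with a flag.

Aggregation is always pooled-count, never a mean of per-chromosome
values, so the pooled estimate equals the depth-weighted combination
of per-chromosome estimates exactly (also after correction, which is
affine in the pooled ratio). A zero denominator yields a flagged
"no informative coverage" result, never a silent 0.

## Fragment sizes and cohort statistics

Mean fragment size is computed inside a closed window [40, 10000] bp
(the sizing range of the instrument; closedness is a documented
choice — the bounds themselves occur with probability ~0 under a
continuous size model). The baseline/endpoint comparison is a paired
one-tailed Student's t-test (alternative: endpoint larger), which
errors on zero-variance differences rather than returning a
degenerate p.

The packaged six-animal cohort table drives the marker correlations.
Decisions made where the analysis was open, each verified against the
statistics the table reproduces: the unphased %ddcfDNA column feeds
the correlations (the phased column does not reproduce the troponin
and time-to-rejection values); troponin is log-transformed with the
natural log (Pearson's r is log-base invariant, so this is cosmetic);
the censored animal enters the time-to-rejection correlation at its
sacrifice day (106), with a sensitivity recomputation excluding it
always emitted. All p-values are two-tailed except the paired
fragment test. The significance formatter uses the conventional
strict bands ns / * / ** / *** / **** at 0.05, 0.01, 0.001, 0.0001.

Method concordance is summarised as the Pearson r between
per-chromosome donor percentages of the phased and unphased runs.
With a common within-method denominator the recipient-percent
correlation (also reported) equals the donor one by affine
invariance; the two differ only in workflows that normalise each
origin set separately.

## The synthetic-data generator

The generator emulates the study conditions: SNP density 3.42 per
kilobase (Poisson site counts per chromosome, uniform positions);
biallelic sites with population alternate-allele frequencies drawn
Beta(1, 1) by default (or pinned for analytic tests); two unrelated
individuals drawn independently under Hardy–Weinberg (study pairs
are deliberately fully mismatched, so no kinship knob); Poisson
depth (default mean 1000 at informative sites, the regime where the
5-read rule is comfortably satisfiable); donor fraction default 0.05,
mid-range of the observed 1.8–7.4%; symmetric allele-flip error
ε = 0.001, a typical post-filter substitution-error scale;
condition-specific log-normal fragment sizes with default medians
2500 bp (baseline) and 4200 bp (endpoint) and log-sigma 0.25,
matching the cohort's Bioanalyzer means (~2.6 kb and ~4.3 kb — these
instrument means sit far above the canonical ~167 bp cfDNA mode, so
the generator exposes location parameters rather than asserting a
biological size model). A designated control chromosome appears in
headers but receives no sites or reads — the stand-in for the
Y-chromosome negative control in an all-female cohort.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: alignment and mapping artefacts,
GC/coverage bias, context-dependent and strand-asymmetric errors,
linked multi-SNP fragments, multiallelic sites, indels in the
genotype stream, relatedness, and genotype-calling errors in the
donor/recipient truth. Annotation statistics are drawn from nominal
pass ranges with optional per-predicate violation injection; they
exercise the filter's logic, not the joint distribution of real GATK
annotations.

## Numerical and testing choices

Fixed seeds make every output byte-identical across reruns (child
seeds are derived from the master seed via a seed sequence, kept
below 2³¹). Statistical unit tests assert at 3 standard errors of
closed-form (binomial/Poisson/quadrature) oracles; the Pearson
machinery is checked to 1e-12 against an explicit covariance-and-t
implementation. Problem sizes in the suite are desk-scale — e.g.
18 × 200 kb chromosomes for method concordance, one ~5 Mb chromosome
(~10⁴ informative sites at depth 1000) for parameter recovery, 10³
chromosomes for the density check — large enough for the asserted
tolerances, small enough to run in seconds; the study-scale numbers
(10⁷ pair-unique SNPs genome-wide) are not reproduced at desk scale.

## Known limitations

The site-count estimator's mapping from f to percent is
depth- and threshold-dependent by design; use the read-fraction
estimator for chimerism quantification. The error correction assumes
a single symmetric flip rate shared across sites. Half-called and
multiallelic handling exists downstream but multiallelic sites are
not simulated. No clinical decision threshold for rejection is
implemented or implied.
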