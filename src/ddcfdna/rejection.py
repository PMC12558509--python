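"""Rejection-marker statistics for the six-animal cohort.

The packaged cohort table (one row per transplanted animal) carries
endpoint troponin (ng/L), time to fulminant rejection (days; the one
non-rejecting animal is censored at its sacrifice day, 106),
Bioanalyzer mean cfDNA fragment sizes at baseline and endpoint (bp),
and percent ddcfDNA by the phased and unphased methods.

The report regenerates the study's correlation surface:

A. unphased %ddcfDNA vs log-transformed troponin (Pearson);
B. unphased %ddcfDNA vs time to rejection, censored animal included
   at its sacrifice day, with a sensitivity recomputation without it;
C. unphased %ddcfDNA vs endpoint fragment size (Pearson);
D. paired one-tailed t-test of endpoint vs baseline fragment size.

Troponin is log-transformed with the natural log; Pearson's r is
invariant to the log base, so the choice is cosmetic.  All p-values
are two-tailed except the paired test in D.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import PairedTResult, compare_conditions
from .quantify import DonorFractionEstimate

__all__ = [
    "AnimalRecord",
    "CorrelationResult",
    "load_cohort_table",
    "pearson_test",
    "significance_label",
    "fig4_report",
    "concordance_report",
]


@dataclass(frozen=True)
class AnimalRecord:
    animal: str
    troponin_ng_per_l: float
    time_to_rejection_days: float
    censored: bool
    baseline_fragment_bp: float
    endpoint_fragment_bp: float
    pct_ddcfdna_phased: float
    pct_ddcfdna_unphased: float

    def __post_init__(self) -> None:
        for name in (
            "troponin_ng_per_l",
            "time_to_rejection_days",
            "baseline_fragment_bp",
            "endpoint_fragment_bp",
            "pct_ddcfdna_phased",
            "pct_ddcfdna_unphased",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive for animal {self.animal}")


def load_cohort_table(path=None) -> pd.DataFrame:
    """Load the cohort table (packaged fixture by default)."""
    if path is None:
        ref = importlib.resources.files("ddcfdna") / "data" / "table1.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = [
        AnimalRecord(
            animal=str(r.animal),
            troponin_ng_per_l=float(r.troponin_ng_per_l),
            time_to_rejection_days=float(r.time_to_rejection_days),
            censored=bool(r.censored),
            baseline_fragment_bp=float(r.baseline_fragment_bp),
            endpoint_fragment_bp=float(r.endpoint_fragment_bp),
            pct_ddcfdna_phased=float(r.pct_ddcfdna_phased),
            pct_ddcfdna_unphased=float(r.pct_ddcfdna_unphased),
        )
        for r in df.itertuples(index=False)
    ]
    df.attrs["records"] = records
    return df


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float  # two-tailed

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with the t-distributed two-tailed p-value
    on n−2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson test requires n >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero variance input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r=r, n=n, t=t, p=float(res.pvalue))


def significance_label(p: float) -> str:
    """Map a p-value to the conventional significance bands:
    ns (p ≥ 0.05), * (p < 0.05), ** (p < 0.01), *** (p < 0.001),
    **** (p < 0.0001)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fig4_report(cohort: pd.DataFrame | None = None) -> dict:
    """Recompute the four rejection-marker statistics from the cohort
    table (the packaged fixture when none is given).

    Returns a dict with entries ``troponin`` (A), ``time_to_rejection``
    (B, censored animal at its sacrifice day, plus a
    ``time_to_rejection_uncensored_only`` sensitivity recomputation),
    ``endpoint_fragment`` (C) — all correlations against the unphased
    %ddcfDNA column — and ``fragment_growth`` (D), each labeled with
    the inputs used.
    """
    if cohort is None:
        cohort = load_cohort_table()
    required = {
        "troponin_ng_per_l",
        "time_to_rejection_days",
        "censored",
        "baseline_fragment_bp",
        "endpoint_fragment_bp",
        "pct_ddcfdna_unphased",
    }
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table incomplete; missing columns {sorted(missing)}")
    dd = cohort["pct_ddcfdna_unphased"].to_numpy(float)
    report: dict = {}
    report["troponin"] = {
        "inputs": "unphased %ddcfDNA vs ln(troponin ng/L)",
        "result": pearson_test(dd, np.log(cohort["troponin_ng_per_l"].to_numpy(float))),
    }
    report["time_to_rejection"] = {
        "inputs": "unphased %ddcfDNA vs time to rejection (censored at sacrifice day)",
        "result": pearson_test(dd, cohort["time_to_rejection_days"].to_numpy(float)),
    }
    uncens = cohort[~cohort["censored"].astype(bool)]
    report["time_to_rejection_uncensored_only"] = {
        "inputs": "sensitivity: rejecting animals only",
        "result": pearson_test(
            uncens["pct_ddcfdna_unphased"].to_numpy(float),
            uncens["time_to_rejection_days"].to_numpy(float),
        ),
    }
    report["endpoint_fragment"] = {
        "inputs": "unphased %ddcfDNA vs endpoint mean fragment size (bp)",
        "result": pearson_test(dd, cohort["endpoint_fragment_bp"].to_numpy(float)),
    }
    report["fragment_growth"] = {
        "inputs": "paired one-tailed t, endpoint vs baseline fragment size",
        "result": compare_conditions(
            cohort["baseline_fragment_bp"].to_numpy(float),
            cohort["endpoint_fragment_bp"].to_numpy(float),
        ),
    }
    return report


def concordance_report(
    phased: DonorFractionEstimate, unphased: DonorFractionEstimate
) -> tuple[CorrelationResult, CorrelationResult]:
    """Phased-vs-unphased method concordance over chromosomes.

    Pearson r between the per-chromosome donor percentages of the two
    methods, and between the recipient percentages (100 − donor).
    Note that with a common denominator per method the recipient
    correlation equals the donor correlation by affine invariance;
    both are reported for symmetry with origin-resolved workflows.
    Chromosomes with no informative coverage in either method are
    excluded; mismatched chromosome sets are an error.
    """
    p = phased.per_chrom_percent()
    u = unphased.per_chrom_percent()
    if set(p.index) != set(u.index):
        raise ValueError(
            f"chromosome sets differ between methods: "
            f"{sorted(set(p.index) ^ set(u.index))}"
        )
    joined = pd.DataFrame({"phased": p, "unphased": u}).dropna()
    donor = pearson_test(joined["phased"], joined["unphased"])
    recipient = pearson_test(100.0 - joined["phased"], 100.0 - joined["unphased"])
    return donor, recipient
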