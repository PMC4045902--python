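"""Continental allele-frequency differentiation scan.

For each biallelic SNP present in both the study cohort and a continental
frequency panel, the scan computes, per comparison population:

* a single-SNP Fst (two-population Weir–Cockerham variance-components
  estimator, sample-frequency version, as popularized for genome scans by
  Akey and colleagues);
* an exact binomial test of the study alternate-allele count against a
  Binomial(n, p0) null with p0 the continental frequency, run as two
  one-sided tests (both tails) and combined by doubling the smaller tail;
* an FDR q-value (Benjamini–Hochberg step-up by default, with Storey's
  π0-estimated variant behind a switch), computed within each population's
  test family.

A marker is significantly differentiated versus a population when
Fst ≥ 0.25 and q ≤ 0.05 (both thresholds configurable); the "venn class"
of a marker is the set of populations against which it is significant, and
the headline set contains the markers significant against all of them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "fst_single_snp",
    "binomial_two_sided_scan",
    "fdr_qvalues",
    "differentiation_scan",
    "venn_partition",
]


def fst_single_snp(
    p1: float, n1: int, p2: float, n2: int, clamp_negative: bool = False
) -> float:
    """Two-population variance-components Fst from allele frequencies.

    ``p1, p2`` are alternate-allele frequencies; ``n1, n2`` the allele-count
    denominators (2 × diploid individuals with data).  With the
    sample-size-weighted mean frequency p̄, the among-population mean square
    MSP, the within-population mean square MSG, and the sample-size
    correction n_c,

        Fst = (MSP − MSG) / (MSP + (n_c − 1)·MSG).

    Negative estimates are reported raw by default (``clamp_negative=True``
    truncates at 0).  A SNP monomorphic for the same allele in both
    populations has no variance to partition: Fst = 0.
    """
    out = fst_single_snp_arrays(
        np.asarray([p1], float),
        np.asarray([n1], float),
        np.asarray([p2], float),
        np.asarray([n2], float),
        clamp_negative=clamp_negative,
    )
    return float(out[0])


def fst_single_snp_arrays(
    p1: np.ndarray,
    n1: np.ndarray,
    p2: np.ndarray,
    n2: np.ndarray,
    clamp_negative: bool = False,
) -> np.ndarray:
    """Vectorized :func:`fst_single_snp` over aligned arrays."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("allele-count denominators must be >= 2")
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    # r = 2 populations
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # /(r-1) = /1
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (n - 2.0)
    nc = n - (n1**2 + n2**2) / n
    denom = msp + (nc - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (msp - msg) / denom
    fst = np.where(denom == 0.0, 0.0, fst)  # monomorphic in both: no variance
    if clamp_negative:
        fst = np.maximum(fst, 0.0)
    return fst


def binomial_two_sided_scan(
    k, n, p0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two one-sided exact binomial tails and their doubled combination.

    Under X ~ Binomial(n, p0): ``p_upper = P(X ≥ k)``, ``p_lower = P(X ≤ k)``
    and ``p_combined = min(1, 2·min(p_lower, p_upper))``.  Both tails include
    P(X = k), so p_lower + p_upper ≥ 1 always.  Degenerate nulls p0 ∈ {0, 1}
    are handled exactly.  Accepts scalars or aligned arrays.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("require 0 <= p0 <= 1")
    p_lower = stats.binom.cdf(k, n, p0)
    p_upper = stats.binom.sf(k - 1, n, p0)
    # exact handling of degenerate nulls
    p_lower = np.where(p0 == 0.0, 1.0, p_lower)
    p_upper = np.where(p0 == 0.0, np.where(k == 0, 1.0, 0.0), p_upper)
    p_upper = np.where(p0 == 1.0, 1.0, p_upper)
    p_lower = np.where(p0 == 1.0, np.where(k == n, 1.0, 0.0), p_lower)
    p_combined = np.minimum(1.0, 2.0 * np.minimum(p_lower, p_upper))
    return p_lower, p_upper, p_combined


def fdr_qvalues(
    pvalues, method: str = "bh", lambdas: Optional[np.ndarray] = None
) -> np.ndarray:
    """FDR q-values for a family of p-values.

    ``method="bh"`` (default) is Benjamini–Hochberg step-up with
    monotonicity enforcement — equivalent to Storey's q-values with π0 = 1.
    ``method="storey"`` estimates π0 by the λ-smoother (median of the
    tail-proportion estimates over a λ grid, capped at 1) and rescales the
    BH q-values.  Order-preserving with the p-values in both cases.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q
    if method != "storey":
        raise ValueError(f"unknown FDR method: {method}")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_grid = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    pi0 = min(1.0, float(np.median(pi0_grid)))
    if pi0 <= 0:
        pi0 = 1.0
        warnings.warn("Storey pi0 estimate <= 0; falling back to pi0 = 1")
    return np.minimum(q * pi0, 1.0)


@dataclass
class ScanResult:
    """Per-SNP scan table plus bookkeeping."""

    table: pd.DataFrame
    populations: list[str]
    n_dropped_allele_mismatch: int
    fst_threshold: float
    q_threshold: float

    @property
    def headline(self) -> pd.DataFrame:
        """Markers significant versus ALL comparison populations."""
        return self.table[self.table["n_significant"] == len(self.populations)]


def differentiation_scan(
    study_counts: pd.DataFrame,
    panel: pd.DataFrame,
    fst_threshold: float = 0.25,
    q_threshold: float = 0.05,
    fdr_method: str = "bh",
    clamp_negative_fst: bool = False,
) -> ScanResult:
    """Run the full scan.

    ``study_counts``: one row per biallelic study SNP with columns
    chrom, pos, ref, alt, k (alt-allele count over non-missing genotypes)
    and n (non-missing allele total).  ``panel``: rows (chrom, pos, alt,
    population, p, n_alleles).  Panel frequencies are harmonized to the
    study's alternate allele: complemented when the panel's reported allele
    is the study's reference; markers whose panel allele matches neither
    study allele are dropped and logged.  q-values form one family per
    population, over the markers tested against that population.
    """
    study = study_counts.copy()
    study["chrom"] = study["chrom"].astype(str)
    panel = panel.copy()
    panel["chrom"] = panel["chrom"].astype(str)

    merged = study.merge(
        panel, on=["chrom", "pos"], suffixes=("", "_panel"), how="inner"
    )
    match_alt = merged["alt_panel"] == merged["alt"]
    match_ref = merged["alt_panel"] == merged["ref"]
    mismatch = ~(match_alt | match_ref)
    n_dropped = int(merged.loc[mismatch, ["chrom", "pos"]].drop_duplicates().shape[0])
    if n_dropped:
        logger.warning(
            "dropped %d markers with panel alleles matching neither study allele",
            n_dropped,
        )
    merged = merged[~mismatch].copy()
    merged["p0"] = np.where(match_alt[~mismatch], merged["p"], 1.0 - merged["p"])

    populations = sorted(merged["population"].unique())
    # test only markers with panel coverage in every comparison population
    n_pops_per_site = merged.groupby(["chrom", "pos"])["population"].nunique()
    covered = n_pops_per_site[n_pops_per_site == len(populations)].index
    merged = merged[merged.set_index(["chrom", "pos"]).index.isin(covered)]
    key_cols = ["chrom", "pos", "ref", "alt", "k", "n"]
    out = study[study.set_index(["chrom", "pos"]).index.isin(
        merged.set_index(["chrom", "pos"]).index
    )][key_cols].reset_index(drop=True)
    out_index = out.set_index(["chrom", "pos"]).index

    sig_flags = np.zeros((len(out), len(populations)), dtype=bool)
    for pi, pop in enumerate(populations):
        sub = merged[merged["population"] == pop].set_index(["chrom", "pos"])
        sub = sub.loc[out_index]
        k = sub["k"].to_numpy(np.int64)
        n = sub["n"].to_numpy(np.int64)
        p_study = np.divide(k, n, out=np.zeros(len(sub)), where=n > 0)
        fst = fst_single_snp_arrays(
            p_study,
            n.astype(float),
            sub["p0"].to_numpy(float),
            sub["n_alleles"].to_numpy(float),
            clamp_negative=clamp_negative_fst,
        )
        p_lo, p_up, p_comb = binomial_two_sided_scan(k, n, sub["p0"].to_numpy(float))
        q = fdr_qvalues(p_comb, method=fdr_method)
        sig = (fst >= fst_threshold) & (q <= q_threshold)
        sig_flags[:, pi] = sig
        out[f"fst_{pop}"] = fst
        out[f"p_lower_{pop}"] = p_lo
        out[f"p_upper_{pop}"] = p_up
        out[f"p_combined_{pop}"] = p_comb
        out[f"q_{pop}"] = q
        out[f"significant_{pop}"] = sig

    out["n_significant"] = sig_flags.sum(axis=1)
    out["venn_class"] = [
        ",".join(p for p, s in zip(populations, row) if s) for row in sig_flags
    ]
    return ScanResult(
        table=out,
        populations=populations,
        n_dropped_allele_mismatch=n_dropped,
        fst_threshold=fst_threshold,
        q_threshold=q_threshold,
    )


def venn_partition(result: ScanResult) -> pd.DataFrame:
    """Counts of markers per nonempty subset of comparison populations.

    The subsets partition the markers significant versus at least one
    population; their sizes sum to that count.
    """
    tab = result.table
    sig = tab[tab["n_significant"] > 0]
    counts = sig.groupby("venn_class").size().rename("n_markers").reset_index()
    return counts.sort_values("venn_class").reset_index(drop=True)
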