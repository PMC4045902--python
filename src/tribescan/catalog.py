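"""Variant cataloguing: known/novel status, annotation classes, Ti:Tv,
MAF spectra, indel sizes, substitution-matrix comparison, genotype
concordance and cross-cohort frequency correlation.

Known/novel follows the reference-catalog rule: a variant is *novel* if its
site is absent from the catalog, or if any observed alternate allele is not
among the catalogued alleles; otherwise *known*.  Annotation classes
partition variants into the 13 gene-context labels (Coding, Splicing, UTRs,
up/downstream windows, intronic, non-coding exonic, intergenic and their
combinations) using a fixed precedence over the transcripts a variant
touches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import Interval, SiteKey, Variant

__all__ = [
    "CatalogEntry",
    "build_catalog",
    "classify_known_novel",
    "titv_ratio",
    "GeneModel",
    "annotate_class",
    "ANNOTATION_CLASSES",
    "maf_spectrum",
    "indel_size_distribution",
    "mantel_substitution_correlation",
    "genotype_concordance",
    "frequency_correlation",
]


# ---------------------------------------------------------------------------
# Known / novel


@dataclass(frozen=True)
class CatalogEntry:
    site: SiteKey
    known_alleles: frozenset

    def __post_init__(self) -> None:
        if not self.known_alleles:
            raise ValueError("catalog entry needs a non-empty allele set")


def build_catalog(df: pd.DataFrame) -> dict[SiteKey, CatalogEntry]:
    """Index a catalog table (chrom, pos, alleles comma-joined) by site."""
    out: dict[SiteKey, CatalogEntry] = {}
    for row in df.itertuples(index=False):
        site = SiteKey(str(row.chrom), int(row.pos))
        alleles = frozenset(str(row.alleles).upper().split(","))
        out[site] = CatalogEntry(site, alleles)
    return out


def classify_known_novel(
    variants: Iterable[Variant], catalog: Mapping[SiteKey, CatalogEntry]
) -> list[str]:
    """Label each variant ``known`` or ``novel`` against the catalog.

    Novel iff the site is absent from the catalog OR the observed alternate
    alleles are not a subset of the catalogued alleles.  Monotone in the
    catalog: enlarging it never converts known → novel.
    """
    labels = []
    for v in variants:
        entry = catalog.get(v.site)
        if entry is None or not set(v.alts) <= entry.known_alleles:
            labels.append("novel")
        else:
            labels.append("known")
    return labels


# ---------------------------------------------------------------------------
# Ti:Tv

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def titv_ratio(variants: Iterable[Variant]) -> float:
    """Transition/transversion ratio over biallelic SNPs.

    Transitions are A↔G and C↔T.  Returns NaN with a warning when there are
    no transversions (including the empty set).
    """
    n_ti = n_tv = 0
    for v in variants:
        if not (v.is_biallelic and v.is_snp):
            continue
        if (v.ref, v.alts[0]) in _TRANSITIONS:
            n_ti += 1
        else:
            n_tv += 1
    if n_tv == 0:
        warnings.warn("no transversions; Ti:Tv undefined")
        return math.nan
    return n_ti / n_tv


# ---------------------------------------------------------------------------
# Annotation classes

ANNOTATION_CLASSES = (
    "Coding",
    "Coding,Splicing",
    "Downstream",
    "Downstream,Upstream",
    "Intergenic",
    "Intronic",
    "NCExonic",
    "NCSplicing",
    "Splicing",
    "3'UTR",
    "3'UTR,5'UTR",
    "5'UTR",
    "Upstream",
)


@dataclass
class GeneModel:
    """One transcript: strand, exons, CDS span and coding status.

    Exons are 0-based half-open and non-overlapping; ``cds_start/cds_end``
    (0-based half-open span) are ignored for non-coding transcripts.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    coding: bool = True
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.coding and (self.cds_start is None or self.cds_end is None):
            raise ValueError("coding transcript needs a CDS span")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]


_FLANK_BP = 1000  # up/downstream window from transcript start/stop
_SPLICE_BP = 2  # canonical splice window beyond each internal exon boundary


def _transcript_effect(pos0: int, gm: GeneModel) -> Optional[str]:
    """Effect of a variant (0-based position) on one transcript, or None."""
    in_exon = any(s <= pos0 < e for s, e in gm.exons)
    if gm.tx_start <= pos0 < gm.tx_end:
        if in_exon:
            if gm.coding:
                if gm.cds_start <= pos0 < gm.cds_end:
                    return "Coding"
                before_cds = pos0 < gm.cds_start
                if gm.strand == "+":
                    return "5'UTR" if before_cds else "3'UTR"
                return "3'UTR" if before_cds else "5'UTR"
            return "NCExonic"
        # intronic; splice window = within _SPLICE_BP of an internal boundary
        for (s1, e1), (s2, _e2) in zip(gm.exons, gm.exons[1:]):
            if e1 <= pos0 < e1 + _SPLICE_BP or s2 - _SPLICE_BP <= pos0 < s2:
                return "Splicing" if gm.coding else "NCSplicing"
        return "Intronic"
    # flanks, strand-aware: upstream of transcription start / downstream of stop
    if gm.strand == "+":
        if gm.tx_start - _FLANK_BP <= pos0 < gm.tx_start:
            return "Upstream"
        if gm.tx_end <= pos0 < gm.tx_end + _FLANK_BP:
            return "Downstream"
    else:
        if gm.tx_end <= pos0 < gm.tx_end + _FLANK_BP:
            return "Upstream"
        if gm.tx_start - _FLANK_BP <= pos0 < gm.tx_start:
            return "Downstream"
    return None


def annotate_class(variant: Variant, gene_models: Sequence[GeneModel]) -> str:
    """Assign exactly one of the 13 annotation classes to a variant.

    Effects are collected per transcript and reduced by precedence:
    splice+coding combinations first, then coding, splicing, UTRs (with the
    two-sided combination), non-coding exonic/splice, intronic, the
    1000-bp up/downstream windows (with the two-transcript combination),
    and intergenic as the fallback — including variants on contigs absent
    from the gene models.
    """
    pos0 = variant.site.pos - 1
    effects = set()
    for gm in gene_models:
        if gm.chrom != variant.site.chrom:
            continue
        eff = _transcript_effect(pos0, gm)
        if eff:
            effects.add(eff)
    if {"Coding", "Splicing"} <= effects:
        return "Coding,Splicing"
    if "Coding" in effects:
        return "Coding"
    if "Splicing" in effects:
        return "Splicing"
    if {"3'UTR", "5'UTR"} <= effects:
        return "3'UTR,5'UTR"
    if "5'UTR" in effects:
        return "5'UTR"
    if "3'UTR" in effects:
        return "3'UTR"
    if "NCSplicing" in effects:
        return "NCSplicing"
    if "NCExonic" in effects:
        return "NCExonic"
    if "Intronic" in effects:
        return "Intronic"
    if {"Upstream", "Downstream"} <= effects:
        return "Downstream,Upstream"
    if "Upstream" in effects:
        return "Upstream"
    if "Downstream" in effects:
        return "Downstream"
    return "Intergenic"


# ---------------------------------------------------------------------------
# MAF spectrum


@dataclass
class MafSpectrum:
    """Binned minor-allele-frequency counts per stratum (known / novel)."""

    bin_edges: tuple[float, ...]
    bin_labels: tuple[str, ...]
    counts: pd.DataFrame  # rows = strata, columns = bin labels
    n_excluded_all_missing: int
    mean_maf: dict[str, float]
    welch_t: Optional[float]
    welch_p: Optional[float]

    def fractions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


_DEFAULT_EDGES = (0.05, 0.10)


def maf_spectrum(
    variants: Sequence[Variant],
    stratum_labels: Sequence[str],
    bin_edges: tuple[float, ...] = _DEFAULT_EDGES,
) -> MafSpectrum:
    """MAF spectrum of biallelic SNPs, stratified (typically known/novel).

    MAF = min(p, 1−p) from non-missing allele counts.  Bins are closed on
    the left: with the default edges, "<5%" is [0, 0.05), "5-10%" is
    [0.05, 0.10) and ">10%" is [0.10, 0.5].  Sites with all genotypes
    missing are excluded and tallied.  Mean MAF per stratum is compared by
    Welch's unequal-variance t-test when both strata are non-trivial.
    """
    if len(stratum_labels) != len(variants):
        raise ValueError("one stratum label per variant required")
    edges = tuple(sorted(bin_edges))
    labels = (
        [f"<{edges[0]:g}"]
        + [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
        + [f">{edges[-1]:g}"]
    )
    strata = sorted(set(stratum_labels))
    counts = pd.DataFrame(0, index=strata, columns=labels, dtype=int)
    mafs: dict[str, list[float]] = {s: [] for s in strata}
    n_excluded = 0
    for v, stratum in zip(variants, stratum_labels):
        if not v.is_biallelic:
            continue
        k, n = v.alt_allele_count()
        if n == 0:
            n_excluded += 1
            continue
        p = k / n
        maf = min(p, 1.0 - p)
        mafs[stratum].append(maf)
        b = int(np.searchsorted(edges, maf, side="right"))
        counts.loc[stratum, labels[b]] += 1
    mean_maf = {s: (float(np.mean(v)) if v else math.nan) for s, v in mafs.items()}
    welch_t = welch_p = None
    filled = [s for s in strata if len(mafs[s]) >= 2]
    if len(filled) == 2:
        welch_t, welch_p = stats.ttest_ind(
            mafs[filled[0]], mafs[filled[1]], equal_var=False
        )
        welch_t, welch_p = float(welch_t), float(welch_p)
    return MafSpectrum(
        bin_edges=edges,
        bin_labels=tuple(labels),
        counts=counts,
        n_excluded_all_missing=n_excluded,
        mean_maf=mean_maf,
        welch_t=welch_t,
        welch_p=welch_p,
    )


# ---------------------------------------------------------------------------
# Indel sizes


def indel_size_distribution(
    indels: Sequence[Variant],
    stratum_labels: Sequence[str],
    max_abs_size: int = 50,
) -> pd.DataFrame:
    """Histogram of net length change (len(alt) − len(ref)) per stratum.

    Symmetric range [−max_abs_size, +max_abs_size]; sizes outside are
    clipped into the extreme bins.  Rows indexed by size, one column per
    stratum.
    """
    sizes = range(-max_abs_size, max_abs_size + 1)
    strata = sorted(set(stratum_labels))
    hist = pd.DataFrame(0, index=list(sizes), columns=strata, dtype=int)
    for v, stratum in zip(indels, stratum_labels):
        if not v.is_biallelic:
            continue
        delta = len(v.alts[0]) - len(v.ref)
        if delta == 0:
            continue
        delta = max(-max_abs_size, min(max_abs_size, delta))
        hist.loc[delta, stratum] += 1
    return hist


# ---------------------------------------------------------------------------
# Mantel test on substitution matrices


def mantel_substitution_correlation(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two labeled square count matrices.

    r is the Pearson correlation of the off-diagonal entries; the one-sided
    p-value is (1 + #{permuted r ≥ observed}) / (1 + n_perm) under
    simultaneous row/column label permutation of the second matrix.
    """
    if list(counts_a.index) != list(counts_a.columns) or list(
        counts_b.index
    ) != list(counts_b.columns):
        raise ValueError("matrices must be square with matching row/column labels")
    if list(counts_a.index) != list(counts_b.index):
        raise ValueError("the two matrices must share labels")
    a = counts_a.to_numpy(float)
    b = counts_b.to_numpy(float)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    va = a[off]
    if np.std(va) == 0 or np.std(b[off]) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(stats.pearsonr(va, b[off])[0])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        r = float(stats.pearsonr(va, bp[off])[0])
        if r >= r_obs:
            n_ge += 1
    return r_obs, (1 + n_ge) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Concordance and frequency correlation


def genotype_concordance(
    seq_calls: Mapping[tuple[SiteKey, str], tuple],
    array_calls: Mapping[tuple[SiteKey, str], tuple],
) -> tuple[float, list, pd.DataFrame]:
    """Concordance between two genotype call sets joined on (site, sample).

    Genotypes are compared as unordered allele pairs.  Returns the overall
    rate, the discordant keys, and a per-zygosity breakdown (zygosity of the
    first call set).
    """
    joined = set(seq_calls) & set(array_calls)
    if not joined:
        raise ValueError("no sites shared between the call sets")
    rows = {"het": [0, 0], "hom": [0, 0]}  # [matches, total]
    discordant = []
    for key in sorted(joined):
        g1 = tuple(sorted(seq_calls[key]))
        g2 = tuple(sorted(array_calls[key]))
        zyg = "het" if g1[0] != g1[1] else "hom"
        rows[zyg][1] += 1
        if g1 == g2:
            rows[zyg][0] += 1
        else:
            discordant.append(key)
    breakdown = pd.DataFrame(
        {
            "zygosity": list(rows),
            "matches": [rows[z][0] for z in rows],
            "total": [rows[z][1] for z in rows],
        }
    )
    rate = breakdown["matches"].sum() / breakdown["total"].sum()
    return float(rate), discordant, breakdown


def frequency_correlation(
    freqs_a: pd.DataFrame,
    freqs_b: pd.DataFrame,
    deleterious_only: bool = False,
) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation of allele frequencies between two cohorts.

    Input frames have columns chrom, pos, alt, freq and optionally
    ``deleterious`` (bool; the damaging-prediction OR-rule flag consumed as
    input).  Markers are joined on (chrom, pos, alt).  Returns (r, 95%
    Fisher-z CI, p).  Requires ≥3 joined markers.
    """
    keys = ["chrom", "pos", "alt"]
    a = freqs_a.copy()
    b = freqs_b.copy()
    if deleterious_only:
        a = a[a["deleterious"].astype(bool)]
        b = b[b["deleterious"].astype(bool)]
    joined = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if len(joined) < 3:
        raise ValueError("need at least 3 joined markers")
    x = joined["freq_a"].to_numpy(float)
    y = joined["freq_b"].to_numpy(float)
    if np.any((x < 0) | (x > 1)) or np.any((y < 0) | (y > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    r, p = stats.pearsonr(x, y)
    n = len(joined)
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    ci = (math.tanh(z - 1.959963984540054 * se), math.tanh(z + 1.959963984540054 * se))
    return float(r), ci, float(p)
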