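"""Synthetic inputs with the statistical structure the analyses assume.

The study whose computations this package re-implements characterized an
Arabian-peninsula cohort against continental reference panels; its raw data
are not deposited, so every pipeline stage here is exercised on generated
data instead.  The generator emulates:

* a continental allele-frequency panel for four populations, drawn
  Balding–Nichols style around a shared ancestral frequency, with a
  dispersion (drift) parameter ``drift_f``;
* a diploid study cohort genotyped under Hardy–Weinberg equilibrium, with a
  configurable fraction of SNPs whose study frequency is shifted by a fixed
  additive effect (the "planted" differentiated markers, recorded in a
  truth table);
* a dbSNP-like reference catalog covering a configurable fraction of sites,
  optionally omitting one observed alternate allele at some sites to
  exercise the allele-subset novelty rule;
* multi-caller structural-variant call sets with breakpoint jitter; and
* sequences evolved along a known tree under a Kimura two-parameter
  substitution process (matching the K2P distance used downstream).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import MISSING, SiteKey, Variant
from .phylo import Tree, parse_newick

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated study conditions: 15 diploid study
    samples scanned against four continental panels of 100 diploids each,
    with an ancestral-frequency distribution skewed toward rare alleles and
    small within-continent drift so that, absent planted shifts, the panel
    frequency is a faithful null frequency for the study cohort.
    """

    n_snps: int = 5000
    n_samples_study: int = 15
    populations: Sequence[tuple[str, int]] = (
        ("AFR", 100),
        ("AMR", 100),
        ("ASN", 100),
        ("EUR", 100),
    )
    base_freq_dist: tuple[float, float] = (1.0, 3.0)  # Beta(a, b) for ancestral p
    drift_f: float = 0.005  # Balding–Nichols dispersion of panel frequencies
    planted_fraction: float = 0.0
    planted_shift: float = 0.4  # additive, clamped to [0.01, 0.99]
    missing_rate: float = 0.01
    catalog_coverage: float = 0.92
    catalog_coverage_exomic: Optional[float] = None  # falls back to catalog_coverage
    catalog_allele_omission: float = 0.0
    sv_n: int = 300
    sv_jitter_bp: int = 30
    sv_callers: Sequence[str] = ("breakdancer", "pindel", "cnvnator", "breakseq")
    sv_caller_report_prob: float = 0.9
    tree_newick: str = "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,(E:0.05,F:0.05):0.05);"
    seq_len: int = 1000
    kappa: float = 2.0  # transition/transversion rate ratio
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "planted_fraction",
            "missing_rate",
            "catalog_coverage",
            "catalog_allele_omission",
            "sv_caller_report_prob",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 1 or self.n_samples_study < 1:
            raise ValueError("sizes must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.sv_jitter_bp < 0:
            raise ValueError("sv_jitter_bp must be >= 0")


@dataclass
class CohortSim:
    """In-memory result of the panel + cohort simulation."""

    sites: pd.DataFrame  # chrom,pos,ref,alt,p_ancestral,p_study,planted
    panel: pd.DataFrame  # chrom,pos,alt,population,p,n_alleles
    genotypes: np.ndarray  # (n_snps, n_samples) alt-allele dosage, -1 = missing
    sample_names: list[str]

    @property
    def truth(self) -> pd.DataFrame:
        return self.sites[["chrom", "pos", "planted", "p_ancestral", "p_study"]]

    def variants(self) -> list[Variant]:
        out = []
        for row, gts in zip(self.sites.itertuples(index=False), self.genotypes):
            genos = []
            for g in gts:
                if g < 0:
                    genos.append(MISSING)
                elif g == 0:
                    genos.append((0, 0))
                elif g == 1:
                    genos.append((0, 1))
                else:
                    genos.append((1, 1))
            out.append(
                Variant(
                    site=SiteKey(str(row.chrom), int(row.pos)),
                    ref=row.ref,
                    alts=[row.alt],
                    genotypes=genos,
                )
            )
        return out

    def study_counts(self) -> pd.DataFrame:
        """Per-SNP alt-allele count k and non-missing allele total n."""
        obs = self.genotypes >= 0
        k = np.where(obs, self.genotypes, 0).sum(axis=1)
        n = 2 * obs.sum(axis=1)
        return self.sites[["chrom", "pos", "ref", "alt"]].assign(k=k, n=n)


def _random_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = np.array([str(c) for c in range(1, 23)])[
        np.arange(cfg.n_snps) % 22
    ]
    pos = 1000 * (np.arange(cfg.n_snps) // 22 + 1)
    ref_idx = rng.integers(0, 4, size=cfg.n_snps)
    alt_shift = rng.integers(1, 4, size=cfg.n_snps)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": BASES[ref_idx],
            "alt": BASES[(ref_idx + alt_shift) % 4],
        }
    )


def simulate_panel_and_cohort(cfg: SimConfig) -> CohortSim:
    """Draw the continental panel and the study cohort for one seed.

    Panel frequencies for each population are Beta-perturbations of the
    shared ancestral frequency with variance ``drift_f · p(1−p)``.  Study
    genotypes are i.i.d. Hardy–Weinberg draws at the study frequency, which
    equals the ancestral frequency except at planted SNPs, where it is
    shifted by ``planted_shift`` (clamped to [0.01, 0.99]).
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _random_sites(cfg, rng)
    a, b = cfg.base_freq_dist
    p_anc = rng.beta(a, b, size=cfg.n_snps)
    p_anc = np.clip(p_anc, 0.01, 0.99)

    planted = np.zeros(cfg.n_snps, dtype=bool)
    n_planted = int(round(cfg.planted_fraction * cfg.n_snps))
    if n_planted:
        planted[rng.choice(cfg.n_snps, size=n_planted, replace=False)] = True
    sign = np.where(p_anc <= 0.5, 1.0, -1.0)  # shift away from the nearer boundary
    p_study = np.where(
        planted, np.clip(p_anc + sign * cfg.planted_shift, 0.01, 0.99), p_anc
    )

    panel_rows = []
    F = cfg.drift_f
    for pop, n_dip in cfg.populations:
        if F > 0:
            alpha = p_anc * (1.0 - F) / F
            beta = (1.0 - p_anc) * (1.0 - F) / F
            p_pop = rng.beta(alpha, beta)
        else:
            p_pop = p_anc.copy()
        panel_rows.append(
            pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "alt": sites["alt"],
                    "population": pop,
                    "p": p_pop,
                    "n_alleles": 2 * n_dip,
                }
            )
        )
    panel = pd.concat(panel_rows, ignore_index=True)

    genotypes = rng.binomial(2, p_study[:, None], size=(cfg.n_snps, cfg.n_samples_study))
    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes = np.where(miss, -1, genotypes)

    sites = sites.assign(p_ancestral=p_anc, p_study=p_study, planted=planted)
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples_study)]
    return CohortSim(sites=sites, panel=panel, genotypes=genotypes, sample_names=samples)


def simulate_catalog(cfg: SimConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """A dbSNP-like reference catalog over the simulated sites.

    Each site is included with probability ``catalog_coverage``
    (``catalog_coverage_exomic`` for sites flagged exomic, when the sites
    table carries an ``exomic`` column).  At a further
    ``catalog_allele_omission`` fraction of included sites the recorded
    allele set omits the observed alternate allele, so the variant is
    catalogued at the site but with a non-matching allele.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    cov = np.full(len(sites), cfg.catalog_coverage)
    if "exomic" in sites.columns and cfg.catalog_coverage_exomic is not None:
        cov = np.where(sites["exomic"].to_numpy(), cfg.catalog_coverage_exomic, cov)
    included = rng.random(len(sites)) < cov
    omit = rng.random(len(sites)) < cfg.catalog_allele_omission
    rows = []
    for (row, inc, om) in zip(sites.itertuples(index=False), included, omit):
        if not inc:
            continue
        alleles = {row.ref} if om else {row.ref, row.alt}
        rows.append(
            {
                "chrom": str(row.chrom),
                "pos": int(row.pos),
                "alleles": ",".join(sorted(alleles)),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "alleles"])


# ---------------------------------------------------------------------------
# Structural variants

SV_TYPES = ("DEL", "DUP", "INV")
# length regimes loosely following common repeat-driven deletion modes:
# short (SINE-like, 300–400 bp), long (LINE-like, 6–7 kb), and a broad range
_SV_LEN_RANGES = ((300, 400), (6000, 7000), (500, 5000))


def simulate_sv_callsets(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-caller SV call sets with jittered breakpoints, plus truth.

    Returns ``(calls, truth)``: truth has one row per true event; calls carry
    ``caller`` and ``event_id`` columns mapping each call to its event.
    Callers report each event independently with probability
    ``sv_caller_report_prob``; reported endpoints are jittered uniformly in
    ±``sv_jitter_bp``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    truth_rows = []
    spacing = 50_000
    for i in range(cfg.sv_n):
        lo, hi = _SV_LEN_RANGES[int(rng.integers(0, len(_SV_LEN_RANGES)))]
        length = int(rng.integers(lo, hi + 1))
        start = spacing * (i + 1)
        truth_rows.append(
            {
                "event_id": i,
                "chrom": str(1 + i % 5),
                "start": start,
                "end": start + length,
                "type": SV_TYPES[int(rng.integers(0, len(SV_TYPES)))],
            }
        )
    truth = pd.DataFrame(truth_rows)
    call_rows = []
    for caller in cfg.sv_callers:
        for row in truth.itertuples(index=False):
            if rng.random() >= cfg.sv_caller_report_prob:
                continue
            j = cfg.sv_jitter_bp
            ds = int(rng.integers(-j, j + 1)) if j else 0
            de = int(rng.integers(-j, j + 1)) if j else 0
            start, end = row.start + ds, row.end + de
            if end <= start:
                end = start + 1
            call_rows.append(
                {
                    "chrom": row.chrom,
                    "start": start,
                    "end": end,
                    "type": row.type,
                    "caller": caller,
                    "event_id": row.event_id,
                }
            )
    calls = pd.DataFrame(
        call_rows, columns=["chrom", "start", "end", "type", "caller", "event_id"]
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Sequence evolution (K2P along a tree)


def _k2p_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(P same, P transition, P each transversion) after branch length d
    expected substitutions/site under K2P with ts/tv rate ratio kappa."""
    if d <= 0:
        return 1.0, 0.0, 0.0
    # alpha*t = kappa*d/(kappa+2), beta*t = d/(kappa+2) so alpha*t + 2*beta*t = d
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_same, p_ti, p_tv_each


def _evolve(seq: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    p_same, p_ti, p_tv = _k2p_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ti_mask = (u >= p_same) & (u < p_same + p_ti)
    tv1_mask = (u >= p_same + p_ti) & (u < p_same + p_ti + p_tv)
    tv2_mask = u >= p_same + p_ti + p_tv
    # base encoding: A=0, G=1 purines; C=2, T=3 pyrimidines
    out[ti_mask] = seq[ti_mask] ^ 1  # A<->G, C<->T
    out[tv1_mask] = seq[tv1_mask] ^ 2  # A<->C, G<->T
    out[tv2_mask] = seq[tv2_mask] ^ 3  # A<->T, G<->C
    return out


_CODE_TO_BASE = np.array(list("AGCT"))


def simulate_sequences(cfg: SimConfig) -> tuple[dict[str, str], Tree]:
    """Evolve tip sequences along ``cfg.tree_newick`` under K2P.

    Branch lengths are in expected substitutions per site.  Returns the
    alignment (tip name → sequence) and the true tree.
    """
    if cfg.seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    tree = parse_newick(cfg.tree_newick)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    root_seq = rng.integers(0, 4, size=cfg.seq_len)
    out: dict[str, str] = {}

    def walk(node, seq):
        for child in node.children:
            child_seq = _evolve(seq, child.length or 0.0, cfg.kappa, rng)
            if child.is_leaf:
                out[child.name] = "".join(_CODE_TO_BASE[child_seq])
            else:
                walk(child, child_seq)

    walk(tree.root, root_seq)
    return out, tree


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of the config with a different seed."""
    return replace(cfg, seed=seed)
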