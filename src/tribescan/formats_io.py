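"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are strict throughout the package: VCF positions are
1-based, BED intervals 0-based half-open, and all internal interval math is
0-based half-open with converters at the boundary.  A variant at 1-based
position ``p`` overlaps an :class:`Interval` iff ``start < p <= end``.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import pandas as pd


class FormatError(ValueError):
    """A file did not conform to the expected format."""


class SiteKey(NamedTuple):
    """A genomic variant location: chromosome label and 1-based position."""

    chrom: str
    pos: int


Genotype = tuple[Optional[int], Optional[int]]
MISSING: Genotype = (None, None)


@dataclass
class Variant:
    """One variant record: location, alleles and per-sample genotypes.

    ``alts`` keeps multi-allelic records intact (1 alt = biallelic,
    2 = triallelic); downstream modules decide their own biallelic-only
    behavior.  Genotypes are pairs of allele indices, ``(None, None)`` when
    missing; missing genotypes are excluded from allele counts downstream.
    """

    site: SiteKey
    ref: str
    alts: list[str]
    genotypes: list[Genotype] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def alt_allele_count(self, alt_index: int = 1) -> tuple[int, int]:
        """(count of allele ``alt_index``, total non-missing alleles)."""
        k = n = 0
        for g in self.genotypes:
            for a in g:
                if a is not None:
                    n += 1
                    if a == alt_index:
                        k += 1
        return k, n


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


def xopen(path, mode: str = "rt"):
    """Open a path, transparently decompressing ``.gz``."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF


def vcf_samples(path) -> list[str]:
    from cyvcf2 import VCF

    v = VCF(os.fspath(path))
    try:
        return list(v.samples)
    finally:
        v.close()


def read_vcf(path, sample_subset: Optional[Sequence[str]] = None) -> Iterator[Variant]:
    """Yield :class:`Variant` records from a VCF 4.x file, in file order.

    Multi-allelic records are not split.  Alleles are upper-cased but not
    otherwise normalized.  Missing genotypes are preserved as ``(None, None)``.
    """
    from cyvcf2 import VCF

    try:
        v = VCF(os.fspath(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    if sample_subset is not None:
        v.set_samples(list(sample_subset))
    try:
        for i, rec in enumerate(v, start=1):
            try:
                gts = [
                    (None if g[0] < 0 else int(g[0]), None if g[1] < 0 else int(g[1]))
                    if len(g) >= 3
                    else (None if g[0] < 0 else int(g[0]), None)
                    for g in rec.genotypes
                ]
                yield Variant(
                    site=SiteKey(rec.CHROM, rec.POS),
                    ref=rec.REF.upper(),
                    alts=[a.upper() for a in rec.ALT],
                    genotypes=gts,
                )
            except Exception as exc:
                raise FormatError(
                    f"malformed genotype column at record {i} of {path}"
                ) from exc
    finally:
        v.close()


def contig_order(path) -> list[str]:
    """Contig order from the VCF header's ##contig lines, if present."""
    order = []
    with xopen(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("##contig=") and "ID=" in line:
                ident = line.split("ID=")[1].split(",")[0].split(">")[0].strip()
                order.append(ident)
    return order


def write_vcf(
    variants: Iterable[Variant],
    samples: Sequence[str],
    path,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Write a minimal VCF 4.2 file with GT-only genotype columns."""
    with xopen(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs or []:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for v in variants:
            gt_strs = [
                "./."
                if g[0] is None
                else f"{g[0]}/{'.' if g[1] is None else g[1]}"
                for g in v.genotypes
            ]
            row = [
                v.site.chrom,
                str(v.site.pos),
                ".",
                v.ref,
                ",".join(v.alts),
                ".",
                ".",
                ".",
                "GT",
            ] + gt_strs
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Interval]:
    """Read BED3+ (0-based half-open); unsorted input is sorted internally."""
    out: list[Interval] = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                iv = Interval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else "",
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with xopen(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, require_aligned: bool = False) -> dict[str, str]:
    """Read FASTA into an ordered name → sequence mapping (upper-cased).

    With ``require_aligned`` an unequal-length (ragged) set of sequences is a
    :class:`FormatError`.
    """
    from Bio import SeqIO

    with xopen(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    if require_aligned:
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with xopen(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Frequency panel and generic TSV

PANEL_COLUMNS = ["chrom", "pos", "alt", "population", "p", "n_alleles"]


def read_tsv_panel(path) -> pd.DataFrame:
    """Read a continental allele-frequency panel.

    One row per (SNP, population): alternate allele, alternate-allele
    frequency ``p`` in [0, 1] and allele-count denominator ``n_alleles``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"panel {path} missing columns: {sorted(missing)}")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise FormatError(f"panel {path}: frequency outside [0,1]")
    if (df["n_alleles"] < 2).any():
        raise FormatError(f"panel {path}: n_alleles < 2")
    return df


def write_tsv_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PANEL_COLUMNS)


# ---------------------------------------------------------------------------
# Newick (delegates to the tree structures in phylo)


def read_newick(path):
    from .phylo import parse_newick

    with xopen(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree, path) -> None:
    with xopen(path, "wt") as fh:
        fh.write(tree.to_newick() + "\n")
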