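"""Multi-caller structural-variant merging and annotation.

Calls of the same type on the same chromosome are merged when their
reciprocal overlap reaches a threshold (default 0.5: the intersection covers
at least half of each interval).  Merging is single-linkage — connected
components of the reciprocal-overlap graph, BEDTools-style chained merging —
with a strict-clique mode available.  Point-like insertions are matched by
breakpoint distance, translocations by both breakpoints.  Merged deletions
are classified known/novel against a DGV-like catalog by one-directional
covered fraction, and their repeat composition is summarized per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import Interval

SV_TYPES = ("DEL", "DUP", "INS", "INV", "TANDEM-DUP", "ITX", "CTX")

__all__ = [
    "SVCall",
    "SVCluster",
    "reciprocal_overlap",
    "merge_callsets",
    "classify_sv_known",
    "covered_fraction",
    "repeat_composition",
]


@dataclass(frozen=True)
class SVCall:
    """A caller-attributed structural-variant interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    type: str
    caller: str = ""
    partner: Optional[tuple[str, int]] = None  # CTX partner locus

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.type not in ("INS", "ITX", "CTX") and self.end <= self.start:
            raise ValueError("interval SV must have end > start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SVCluster:
    """A merged cluster: union span plus member calls with provenance."""

    chrom: str
    start: int
    end: int
    type: str
    members: list[SVCall] = field(default_factory=list)

    @property
    def callers(self) -> set[str]:
        return {m.caller for m in self.members}


def reciprocal_overlap(
    a: SVCall, b: SVCall, t: float = 0.5
) -> tuple[float, float, bool]:
    """Overlap fractions of each call and whether both reach threshold t."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("reciprocal overlap undefined for zero-length intervals")
    if a.chrom != b.chrom or a.type != b.type:
        return 0.0, 0.0, False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    fa, fb = ov / len(a), ov / len(b)
    return fa, fb, (fa >= t and fb >= t)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pairs_link(a: SVCall, b: SVCall, t: float, breakpoint_window: int) -> bool:
    if a.type in ("ITX", "CTX"):
        if abs(a.start - b.start) > breakpoint_window:
            return False
        pa = a.partner or (a.chrom, a.end)
        pb = b.partner or (b.chrom, b.end)
        return pa[0] == pb[0] and abs(pa[1] - pb[1]) <= breakpoint_window
    if a.type == "INS":
        return abs(a.start - b.start) <= breakpoint_window
    return reciprocal_overlap(a, b, t)[2]


def merge_callsets(
    callsets: Iterable[Sequence[SVCall]],
    t: float = 0.5,
    breakpoint_window: int = 100,
    mode: str = "single",
) -> list[SVCluster]:
    """Merge calls across callers into clusters.

    ``mode="single"`` (default): connected components under the pairwise
    merge relation.  ``mode="clique"``: additionally splits components so
    that every pair inside a cluster satisfies the relation directly.
    Interval types use reciprocal overlap at threshold ``t``; insertions and
    translocations use ``breakpoint_window``.  Output is deterministic,
    ordered by (chrom, start), independent of input order.
    """
    calls: list[SVCall] = [c for cs in callsets for c in cs]
    calls.sort(key=lambda c: (c.chrom, c.type, c.start, c.end, c.caller))
    clusters: list[SVCluster] = []
    # group by (chrom, type); sweep within group
    i = 0
    while i < len(calls):
        j = i
        while (
            j < len(calls)
            and calls[j].chrom == calls[i].chrom
            and calls[j].type == calls[i].type
        ):
            j += 1
        group = calls[i:j]
        clusters.extend(_merge_group(group, t, breakpoint_window, mode))
        i = j
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.type))
    return clusters


def _merge_group(
    group: list[SVCall], t: float, window: int, mode: str
) -> list[SVCluster]:
    n = len(group)
    uf = _UnionFind(n)
    # sorted by start: b cannot link to a once b.start is past a.end + window
    for ai in range(n):
        a = group[ai]
        horizon = a.end + (window if a.type in ("INS", "ITX", "CTX") else 0)
        for bi in range(ai + 1, n):
            if group[bi].start > horizon:
                break
            if _pairs_link(a, group[bi], t, window):
                uf.union(ai, bi)
    comps: dict[int, list[int]] = {}
    for k in range(n):
        comps.setdefault(uf.find(k), []).append(k)
    out = []
    for members in comps.values():
        if mode == "single":
            out.append(_make_cluster([group[k] for k in members]))
        elif mode == "clique":
            out.extend(
                _make_cluster([group[k] for k in sub])
                for sub in _greedy_cliques(group, members, t, window)
            )
        else:
            raise ValueError(f"unknown merge mode {mode!r}")
    return out


def _greedy_cliques(group, members, t, window):
    remaining = list(members)
    while remaining:
        clique = [remaining[0]]
        for k in remaining[1:]:
            if all(_pairs_link(group[c], group[k], t, window) for c in clique):
                clique.append(k)
        yield clique
        remaining = [k for k in remaining if k not in clique]


def _make_cluster(members: list[SVCall]) -> SVCluster:
    return SVCluster(
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        type=members[0].type,
        members=members,
    )


# ---------------------------------------------------------------------------
# Known / novel against a DGV-like deletion catalog


def covered_fraction(start: int, end: int, intervals: Iterable[Interval]) -> float:
    """Fraction of [start, end) covered by the union of the intervals."""
    length = end - start
    if length <= 0:
        raise ValueError("empty interval")
    segs = sorted(
        (max(start, iv.start), min(end, iv.end))
        for iv in intervals
        if iv.start < end and iv.end > start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / length


def classify_sv_known(
    clusters: Sequence[SVCluster],
    dgv_catalog: Sequence[Interval],
    threshold: float = 0.5,
) -> list[str]:
    """Known/novel per deletion cluster against a catalog of deletions.

    Known iff the union of catalog intervals covers ≥ ``threshold`` of the
    detected deletion (one-directional, not reciprocal).  Monotone in
    catalog size.  Non-deletion clusters are labelled with an empty string.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in dgv_catalog:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    labels = []
    for cl in clusters:
        if cl.type != "DEL":
            labels.append("")
            continue
        frac = covered_fraction(cl.start, cl.end, by_chrom.get(cl.chrom, []))
        labels.append("known" if frac >= threshold else "novel")
    return labels


# ---------------------------------------------------------------------------
# Repeat composition

REPEAT_FAMILIES = ("SINE", "LINE", "LTR", "other")


def repeat_composition(
    deletions: Sequence[SVCluster],
    repeat_intervals: Sequence[Interval],
    rich_threshold: float = 0.5,
    length_bins: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-deletion repeat-family covered fractions and a length summary.

    ``repeat_intervals`` carry the family in their label and must be
    pre-flattened (non-overlapping) within each family.  A deletion is
    repeat-rich when any family's covered fraction reaches
    ``rich_threshold``.  The summary histogram bins deletion lengths
    stratified by dominant family, exposing family-specific length modes
    (e.g. the 300–400 bp short-interspersed-element peak).
    """
    fam_intervals: dict[str, dict[str, list[Interval]]] = {}
    for iv in repeat_intervals:
        fam = iv.label if iv.label in REPEAT_FAMILIES else "other"
        fam_intervals.setdefault(fam, {}).setdefault(iv.chrom, []).append(iv)
    rows = []
    for k, cl in enumerate(deletions):
        fracs = {
            fam: covered_fraction(
                cl.start, cl.end, fam_intervals.get(fam, {}).get(cl.chrom, [])
            )
            for fam in REPEAT_FAMILIES
        }
        best = max(fracs, key=lambda f: (fracs[f], f))
        rows.append(
            {
                "cluster": k,
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "length": cl.end - cl.start,
                **{f"frac_{f}": fracs[f] for f in REPEAT_FAMILIES},
                "dominant_family": best if fracs[best] > 0 else "none",
                "repeat_rich": max(fracs.values()) >= rich_threshold,
            }
        )
    per_del = pd.DataFrame(rows)
    if length_bins is None:
        length_bins = [0, 100, 200, 300, 400, 500, 1000, 2000, 5000, 6000, 7000, 10_000]
    if len(per_del):
        per_del["length_bin"] = pd.cut(per_del["length"], bins=length_bins)
        summary = (
            per_del.groupby(["dominant_family", "length_bin"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["dominant_family", "length_bin", "n"])
    return per_del, summary
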