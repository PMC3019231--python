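"""Tolerance-aware interval arithmetic over peak sets.

Everything downstream — replicate reproducibility, cross-sample peak
sharing, histone co-occupancy — reduces to the overlap predicate defined
here:

    gap(a, b) = max(0, max(a.start, b.start) - min(a.end, b.end))
    overlaps(a, b, tol)  iff  same chromosome and gap(a, b) <= tol

Touching or intersecting spans have gap 0, so adjacent half-open
intervals ([100,200) and [200,300)) overlap already at tolerance 0; add
±1 bp yourself if you need strict interiors. A tolerance of 200 bp is
the conventional nucleosome-positioning allowance used when comparing
transcription-factor peaks with histone-mark peaks.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .io_formats import GeneRecord, PeakRecord

__all__ = [
    "gap",
    "overlaps",
    "OverlapResult",
    "set_overlap",
    "merge_peak_sets",
    "nearest_tss",
    "NO_GENE",
]

#: Sentinel distance when a peak's chromosome carries no gene at all.
NO_GENE: tuple[None, None] = (None, None)


def gap(a: PeakRecord, b: PeakRecord) -> int | None:
    """Base-pair gap between two spans; 0 when they touch or intersect,
    ``None`` when they sit on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def overlaps(a: PeakRecord, b: PeakRecord, tolerance: int = 0) -> bool:
    """True iff a and b are on the same chromosome within ``tolerance`` bp.

    Symmetric, and monotone in tolerance: a hit at tolerance t is a hit at
    every t' >= t.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    g = gap(a, b)
    return g is not None and g <= tolerance


@dataclass
class OverlapResult:
    """Set-level overlap accounting, anchored on set A.

    ``n_a_hit`` counts A-peaks with at least one B-match (each A-peak at
    most once, however many B-peaks it touches); ``pct_a_hit`` is the
    A-anchored percentage rounded to the nearest integer — the convention
    behind statements like "1,243 (80%) of the 1,547 replicate-1 peaks
    were also present in replicate 2".
    """

    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def pct_a_hit(self) -> int:
        if self.n_a == 0:
            return 0
        return round(100 * self.n_a_hit / self.n_a)

    @property
    def frac_a_hit(self) -> float:
        return 0.0 if self.n_a == 0 else self.n_a_hit / self.n_a


def set_overlap(
    a: list[PeakRecord], b: list[PeakRecord], tolerance: int = 0
) -> OverlapResult:
    """Count which peaks of A have a match in B (and vice versa).

    Matching uses :func:`overlaps` at the given tolerance. ``pairs`` holds
    every matched (a_index, b_index) in input order. Runs in
    O((n+m) log m + |pairs|) via sorted per-chromosome sweeps.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, pb in enumerate(b):
        by_chrom.setdefault(pb.chrom, []).append((pb.start, pb.end, j))
    for entries in by_chrom.values():
        entries.sort()
    pairs: list[tuple[int, int]] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    for i, pa in enumerate(a):
        entries = by_chrom.get(pa.chrom)
        if not entries:
            continue
        starts = [e[0] for e in entries]
        # candidate B-peaks: start <= pa.end + tol and end >= pa.start - tol
        hi = bisect_right(starts, pa.end + tolerance)
        for s, e, j in entries[:hi]:
            if e >= pa.start - tolerance:
                pairs.append((i, j))
                a_hit.add(i)
                b_hit.add(j)
    pairs.sort()
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_a_hit=len(a_hit), n_b_hit=len(b_hit), pairs=pairs
    )


def merge_peak_sets(sets: list[list[PeakRecord]]) -> list[PeakRecord]:
    """Union several peak sets into disjoint, sorted intervals.

    Overlapping or touching intervals are fused; a merged peak's height is
    the maximum of its constituents' heights. Coverage (the set of covered
    bases) is exactly the union of the inputs' coverage.
    """
    all_peaks = [p for s in sets for p in s]
    all_peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    merged: list[PeakRecord] = []
    for p in all_peaks:
        if merged and merged[-1].chrom == p.chrom and p.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = PeakRecord(
                last.chrom,
                last.start,
                max(last.end, p.end),
                height=max(last.height, p.height),
                name=last.name,
            )
        else:
            merged.append(p)
    return merged


def _tss_distance(center: int, gene: GeneRecord) -> int:
    """Signed distance from a peak center to a gene's strand-aware TSS.

    Negative when the center lies upstream of the TSS in the gene's
    reading direction, positive downstream. For a '+' gene this is
    center - TSS; for a '-' gene, TSS - center.
    """
    if gene.strand == "+":
        return center - gene.tss
    return gene.tss - center


def nearest_tss(
    peak: PeakRecord, genes: list[GeneRecord]
) -> tuple[str | None, int | None]:
    """Nearest gene by absolute signed TSS distance from the peak center.

    Returns (gene_id, signed_distance); ties on |distance| break to the
    lexicographically smallest gene_id. If no gene lies on the peak's
    chromosome the sentinel ``(None, None)`` is returned (annotation
    treats it as gene desert).
    """
    best: tuple[int, str, int] | None = None
    center = peak.center
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = _tss_distance(center, g)
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, d)
    if best is None:
        return NO_GENE
    return best[1], best[2]


class TssIndex:
    """Sorted per-chromosome TSS index for fast nearest-TSS queries.

    Produces identical answers to :func:`nearest_tss` (including the
    lexicographic tie-break) in O(log n) per query.
    """

    def __init__(self, genes: list[GeneRecord]) -> None:
        self._by_chrom: dict[str, list[tuple[int, str, GeneRecord]]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g))
        for entries in self._by_chrom.values():
            entries.sort(key=lambda t: (t[0], t[1]))

    def nearest(self, chrom: str, center: int) -> tuple[GeneRecord | None, int | None]:
        entries = self._by_chrom.get(chrom)
        if not entries:
            return None, None
        positions = [e[0] for e in entries]
        i = bisect_left(positions, center)
        best: tuple[int, str, GeneRecord, int] | None = None

        def consider(j: int) -> None:
            nonlocal best
            tss, gid, g = entries[j]
            d = _tss_distance(center, g)
            key = (abs(d), gid)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), gid, g, d)

        # seed the bound with the two immediate neighbours
        if i - 1 >= 0:
            consider(i - 1)
        if i < len(entries):
            consider(i)
        assert best is not None
        # widen outward while a position could still tie on |distance|
        # (|d| equals |center - tss| regardless of strand)
        j = i - 2
        while j >= 0 and abs(center - positions[j]) <= best[0]:
            consider(j)
            j -= 1
        j = i + 1
        while j < len(entries) and abs(positions[j] - center) <= best[0]:
            consider(j)
            j += 1
        return best[2], best[3]
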