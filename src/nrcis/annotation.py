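"""Genomic-location classification and TSS-centric summaries of peak sets.

Peaks are classified into eight location categories relative to the
nearest RefSeq-style gene model, using the peak center (integer
midpoint):

* ``FIVE_D`` — 10-100 kb upstream of the TSS
* ``DISTAL_PROMOTER`` — 2-10 kb upstream of the TSS
* ``PROXIMAL_PROMOTER`` — <2 kb upstream of the TSS
* ``GENE`` — center inside the gene body (sub-category: first exon,
  first intron, other exon, other intron, in transcription order)
* ``THREE_PROXIMAL`` — <2 kb downstream of the last exon
* ``THREE_DISTAL`` — 2-10 kb downstream of the last exon
* ``THREE_D`` — 10-100 kb downstream of the last exon
* ``GENE_DESERT`` — >100 kb from every gene

A peak whose center falls inside a gene body is always ``GENE``
(peak-center membership wins over any promoter reading); when both an
upstream and a downstream band are in range for different genes at equal
distance, the upstream (promoter-centric) reading is preferred.

Target genes: a peak targets its nearest gene when the absolute signed
TSS distance is within a window (default ±1 kb, inclusive at both ends).
Several peaks may share one target gene, so the distinct target-gene
count can be smaller than the assignment count.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .interval_core import TssIndex, _tss_distance
from .io_formats import GeneRecord, PeakRecord

__all__ = [
    "LocationCategory",
    "GeneSubCategory",
    "PeakAnnotation",
    "TargetAssignment",
    "classify_location",
    "annotate_peaks",
    "location_summary",
    "tss_histogram",
    "assign_target_genes",
    "multiway_target_overlap",
    "median_height_split",
    "tag_density_profile",
]

GENE_DESERT_DISTANCE = 100_000
PROXIMAL_BP = 2_000
DISTAL_BP = 10_000


class LocationCategory(enum.Enum):
    FIVE_D = "5d"
    DISTAL_PROMOTER = "distal_promoter"
    PROXIMAL_PROMOTER = "proximal_promoter"
    GENE = "gene"
    THREE_PROXIMAL = "3_proximal"
    THREE_DISTAL = "3_distal"
    THREE_D = "3d"
    GENE_DESERT = "gene_desert"


class GeneSubCategory(enum.Enum):
    EXON1 = "exon1"
    INTRON1 = "intron1"
    OTHER_EXON = "other_exon"
    OTHER_INTRON = "other_intron"


@dataclass(frozen=True)
class PeakAnnotation:
    """Full annotation of one peak: category, anchor gene, TSS distance."""

    peak: PeakRecord
    category: LocationCategory
    sub_category: GeneSubCategory | None
    gene_id: str | None
    tss_distance: int | None

    def __post_init__(self) -> None:
        if (self.sub_category is not None) != (self.category is LocationCategory.GENE):
            raise ValueError("sub_category present iff category is GENE")


@dataclass(frozen=True)
class TargetAssignment:
    """A peak assigned to its nearest gene within the TSS window."""

    peak_name: str
    gene_id: str
    tss_distance: int


def _upstream_band(dist: int) -> LocationCategory | None:
    """Band for a center ``dist`` bp upstream of a TSS (dist > 0)."""
    if dist < PROXIMAL_BP:
        return LocationCategory.PROXIMAL_PROMOTER
    if dist < DISTAL_BP:
        return LocationCategory.DISTAL_PROMOTER
    if dist <= GENE_DESERT_DISTANCE:
        return LocationCategory.FIVE_D
    return None


def _downstream_band(dist: int) -> LocationCategory | None:
    """Band for a center ``dist`` bp downstream of a transcript 3' end."""
    if dist < PROXIMAL_BP:
        return LocationCategory.THREE_PROXIMAL
    if dist < DISTAL_BP:
        return LocationCategory.THREE_DISTAL
    if dist <= GENE_DESERT_DISTANCE:
        return LocationCategory.THREE_D
    return None


def _gene_sub_category(center: int, gene: GeneRecord) -> GeneSubCategory:
    """Exon/intron sub-category, first/other in transcription order.

    For a '-' strand gene the first exon is the highest-coordinate exon.
    A center inside the gene body but outside the exon span (possible
    when exons do not flush the transcript edges) is attributed to the
    nearest flanking exon's side as an intron-like gap clamped to the
    terminal intron index.
    """
    starts, ends = gene.exon_starts, gene.exon_ends
    n = len(starts)
    if n == 0:
        # no exon structure: treat the whole body as its single exon
        return GeneSubCategory.EXON1
    i = bisect_right(starts, center) - 1  # rightmost exon starting at/left of center
    if i >= 0 and center < ends[i]:
        genomic_exon = i
        tx_exon = genomic_exon if gene.strand == "+" else n - 1 - genomic_exon
        return GeneSubCategory.EXON1 if tx_exon == 0 else GeneSubCategory.OTHER_EXON
    # intronic (or a gap before the first / after the last exon): the
    # intron between genomic exons i and i+1, clamped into range
    genomic_intron = min(max(i, 0), n - 2) if n >= 2 else 0
    n_introns = max(n - 1, 1)
    tx_intron = genomic_intron if gene.strand == "+" else n_introns - 1 - genomic_intron
    return GeneSubCategory.INTRON1 if tx_intron == 0 else GeneSubCategory.OTHER_INTRON


def _classify_against_gene(
    center: int, gene: GeneRecord
) -> tuple[tuple[int, int, str], LocationCategory, GeneSubCategory | None] | None:
    """Distance key and category of one peak center against one gene.

    The key orders candidate anchor genes: absolute anchor distance first
    (0 inside the gene body), then upstream before downstream on ties,
    then gene_id. Returns None when the gene is irrelevant (>100 kb away
    on both anchors).
    """
    if gene.tx_start <= center < gene.tx_end:
        return (0, 0, gene.gene_id), LocationCategory.GENE, _gene_sub_category(
            center, gene
        )
    d_tss = _tss_distance(center, gene)
    # downstream distance from the strand-aware 3' end, positive past it
    if gene.strand == "+":
        d_three = center - gene.three_prime_end
    else:
        d_three = gene.three_prime_end - center
    # d_tss == 0 outside the body happens for a '-' gene whose TSS
    # coordinate tx_end is excluded from the half-open body
    if d_tss <= 0:  # at/upstream of the TSS in reading direction
        cat = _upstream_band(-d_tss)
        if cat is None:
            return None
        return (-d_tss, 0, gene.gene_id), cat, None
    if d_three >= 0:  # at/past the 3' end
        cat = _downstream_band(d_three)
        if cat is None:
            return None
        return (d_three, 1, gene.gene_id), cat, None
    # between TSS and 3' end but outside [tx_start, tx_end) cannot happen:
    # the anchors are the transcript edges themselves
    return None


def classify_location(
    peak: PeakRecord, genes: list[GeneRecord]
) -> tuple[LocationCategory, GeneSubCategory | None]:
    """Classify one peak into its location category (and GENE sub-category).

    The anchor is the gene minimising the distance key described in
    :func:`_classify_against_gene`; with no gene within 100 kb (or none
    on the chromosome) the peak is a gene-desert peak.
    """
    center = peak.center
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        res = _classify_against_gene(center, g)
        if res is not None and (best is None or res[0] < best[0]):
            best = res
    if best is None:
        return LocationCategory.GENE_DESERT, None
    return best[1], best[2]


def annotate_peaks(
    peaks: list[PeakRecord], genes: list[GeneRecord]
) -> list[PeakAnnotation]:
    """Classify every peak and attach its nearest-TSS gene and distance."""
    index = TssIndex(genes)
    out: list[PeakAnnotation] = []
    for p in peaks:
        cat, sub = classify_location(p, genes)
        g, d = index.nearest(p.chrom, p.center)
        out.append(
            PeakAnnotation(
                peak=p,
                category=cat,
                sub_category=sub,
                gene_id=None if g is None else g.gene_id,
                tss_distance=d,
            )
        )
    return out


def location_summary(
    peaks: list[PeakRecord], genes: list[GeneRecord]
) -> dict[str, dict[str, int]]:
    """Counts and integer percentages per location category.

    Returns ``{"counts": {...}, "percent": {...}, "gene_counts": {...},
    "gene_percent": {...}}``; category counts always sum to ``len(peaks)``
    and percentages are computed on the full peak set, rounded to the
    nearest integer. GENE sub-category percentages are relative to the
    peaks inside genes.
    """
    counts = {c.value: 0 for c in LocationCategory}
    sub_counts = {s.value: 0 for s in GeneSubCategory}
    for p in peaks:
        cat, sub = classify_location(p, genes)
        counts[cat.value] += 1
        if sub is not None:
            sub_counts[sub.value] += 1
    n = len(peaks)
    n_gene = counts[LocationCategory.GENE.value]
    percent = {k: (round(100 * v / n) if n else 0) for k, v in counts.items()}
    gene_percent = {
        k: (round(100 * v / n_gene) if n_gene else 0) for k, v in sub_counts.items()
    }
    return {
        "counts": counts,
        "percent": percent,
        "gene_counts": sub_counts,
        "gene_percent": gene_percent,
    }


def _signed_bins(span_bp: int, bin_bp: int) -> np.ndarray:
    """Bin edges covering [-span, span) in steps of bin_bp."""
    if span_bp % bin_bp:
        raise ValueError("span_bp must be a multiple of bin_bp")
    return np.arange(-span_bp, span_bp + bin_bp, bin_bp)


def _bin_signed_distances(
    distances: list[int], bin_bp: int, span_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram signed distances into [i*bin, (i+1)*bin) bins over ±span.

    Distances outside [-span, span) are excluded. Returns (edges, counts)
    with len(edges) == len(counts) + 1.
    """
    edges = _signed_bins(span_bp, bin_bp)
    d = np.asarray(distances, dtype=np.int64)
    d = d[(d >= -span_bp) & (d < span_bp)]
    idx = (d + span_bp) // bin_bp
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return edges, counts


def tss_histogram(
    peaks: list[PeakRecord],
    genes: list[GeneRecord],
    bin_bp: int = 100,
    span_bp: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of peak-center distances to the nearest TSS.

    Bin i covers signed distances [i*bin_bp, (i+1)*bin_bp); a distance of
    -1 falls in the [-bin_bp, 0) bin. Peaks outside ±span (or with no
    gene on their chromosome) are excluded, so the counts sum to the
    number of in-span peaks. Returns (bin_edges, counts).
    """
    index = TssIndex(genes)
    distances = []
    for p in peaks:
        _, d = index.nearest(p.chrom, p.center)
        if d is not None:
            distances.append(d)
    return _bin_signed_distances(distances, bin_bp, span_bp)


def assign_target_genes(
    peaks: list[PeakRecord],
    genes: list[GeneRecord],
    window: int = 1_000,
) -> list[TargetAssignment]:
    """Assign each peak to its nearest gene when |TSS distance| <= window.

    The window is inclusive at both ends (±1 kb means [-1000, +1000]).
    Peaks with no gene on their chromosome, or beyond the window, yield no
    assignment. Multiple peaks may target the same gene.
    """
    index = TssIndex(genes)
    out: list[TargetAssignment] = []
    for i, p in enumerate(peaks):
        g, d = index.nearest(p.chrom, p.center)
        if g is None or d is None or abs(d) > window:
            continue
        name = p.name if p.name is not None else f"peak_{i + 1}"
        out.append(TargetAssignment(peak_name=name, gene_id=g.gene_id, tss_distance=d))
    return out


def target_gene_set(assignments: list[TargetAssignment]) -> set[str]:
    """Distinct target genes behind a list of assignments."""
    return {a.gene_id for a in assignments}


def multiway_target_overlap(
    named_sets: dict[str, set[str]],
) -> dict[frozenset[str], int]:
    """Exact region counts of the k-set Venn diagram over target genes.

    Returns a mapping from each non-empty combination of set names (as a
    frozenset) to the number of genes belonging to exactly those sets.
    Region counts sum to the size of the union.
    """
    names = sorted(named_sets)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    universe = set().union(*named_sets.values()) if named_sets else set()
    for gene in universe:
        membership = frozenset(n for n in names if gene in named_sets[n])
        regions[membership] += 1
    return regions


def common_target_count(named_sets: dict[str, set[str]]) -> int:
    """Number of genes shared by every set (the full intersection)."""
    if not named_sets:
        return 0
    it = iter(named_sets.values())
    common = set(next(it))
    for s in it:
        common &= s
    return len(common)


def median_height_split(
    peaks: list[PeakRecord],
    genes: list[GeneRecord],
    window: int = 1_000,
) -> tuple[float | None, float | None]:
    """Median summit heights of peaks within vs outside ±window of a TSS.

    TSS-proximal binding shows up as an elevated within-window median.
    The median of an even-sized group is the mean of the two central
    values; an empty partition yields ``None``.
    """
    index = TssIndex(genes)
    inside: list[float] = []
    outside: list[float] = []
    for p in peaks:
        _, d = index.nearest(p.chrom, p.center)
        if d is not None and abs(d) <= window:
            inside.append(p.height)
        else:
            outside.append(p.height)
    med_in = float(np.median(inside)) if inside else None
    med_out = float(np.median(outside)) if outside else None
    return med_in, med_out


def tag_density_profile(
    tag_positions: list[tuple[str, int]],
    genes: list[GeneRecord],
    bin_bp: int = 100,
    span_bp: int = 2_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin counts of single-bp tag positions around the TSSs of a
    gene list (e.g. the genes bound by the factor).

    Like :func:`tss_histogram` but over read 5'-end positions instead of
    peak centers; the signed-distance convention is the strand-aware one
    of :func:`nrcis.interval_core.nearest_tss`. Returns (edges, counts).
    """
    index = TssIndex(genes)
    distances = []
    for chrom, pos in tag_positions:
        _, d = index.nearest(chrom, pos)
        if d is not None:
            distances.append(d)
    return _bin_signed_distances(distances, bin_bp, span_bp)
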