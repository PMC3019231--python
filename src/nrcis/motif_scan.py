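"""Nuclear-receptor repeat-element and ETS-motif scanning.

Nuclear receptors bind two copies of the hexamer half-site AGGTCA in one
of three relative orientations, separated by a 0-8 bp spacer:

* ``DR`` (direct repeat):    ``H  N{s}  H``
* ``IR`` (inverted repeat):  ``H  N{s}  rc(H)``  — half-sites pointing
  toward each other
* ``ER`` (everted repeat):   ``rc(H)  N{s}  H``  — pointing away

where ``H`` is the half-site and ``rc`` the reverse complement. DR1 —
a direct repeat with a single spacer base — is the canonical element of
the TR2/TR4 subfamily. The orientation naming above follows the
NHR-scan convention; the literature is inconsistent, so check the
pattern definitions rather than the labels when comparing tools.

ETS-family factors (ELK1, ELK4, GABPA, ...) recognise the core GGAA,
extended CCGGAA.

Scanning reports every matching window on both strands (overlaps
allowed); the minus strand is scanned by applying the same plus-strand
patterns to the reverse complement of the sequence and mapping
coordinates back. A per-half mismatch budget is enforced independently
on each half-site; ``N`` bases never match. Because the IR and ER
arrangements are reverse-complement palindromic, each of their genomic
windows is reported once per strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .annotation import _bin_signed_distances

__all__ = [
    "RepeatElementSpec",
    "MotifHit",
    "ETS_PATTERNS",
    "MOTIF_CLASSES",
    "scan_repeat_elements",
    "scan_ets",
    "classify_peak_motifs",
    "motif_offset_histogram",
    "spacer_composition",
    "expected_background_hits",
    "reverse_complement",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
ETS_PATTERNS = {"core": "GGAA", "extended": "CCGGAA"}
MOTIF_CLASSES = ("repeat_only", "ets_only", "both", "neither")


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class RepeatElementSpec:
    """A two-half-site repeat element to scan for.

    ``max_mismatch_per_half`` is the main sensitivity knob: it bounds the
    mismatches allowed in EACH half-site independently (the spacer bases
    are unconstrained).
    """

    arrangement: str = "DR"
    spacer: int = 1
    half_site: str = "AGGTCA"
    max_mismatch_per_half: int = 1

    def __post_init__(self) -> None:
        if self.arrangement not in ("DR", "ER", "IR"):
            raise ValueError(f"arrangement must be DR/ER/IR, got {self.arrangement!r}")
        if not 0 <= self.spacer <= 8:
            raise ValueError(f"spacer must be in [0, 8], got {self.spacer}")
        if len(self.half_site) != 6 or set(self.half_site) - set("ACGT"):
            raise ValueError("half_site must be a 6-mer over A/C/G/T")
        if self.max_mismatch_per_half < 0:
            raise ValueError("max_mismatch_per_half must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.arrangement}{self.spacer}"

    @property
    def length(self) -> int:
        """Total motif window length: two half-sites plus spacer (12-20)."""
        return 12 + self.spacer

    def half_patterns(self) -> tuple[str, str]:
        """Plus-strand (left, right) half-site patterns."""
        h = self.half_site
        rc = reverse_complement(h)
        if self.arrangement == "DR":
            return h, h
        if self.arrangement == "IR":
            return h, rc
        return rc, h  # ER


@dataclass(frozen=True)
class MotifHit:
    """One matched motif window in one sequence.

    ``start`` is the 0-based offset of the window on the forward
    sequence, whatever the strand. ``spacer_base`` is the spacer sequence
    as read in the matched orientation (a single base for spacer-1
    elements, ``None`` for spacer 0 and for ETS hits). ``center_offset``
    is the signed distance from the sequence (peak) center to the hit
    center, hit_center - seq_center.
    """

    motif_class: str
    start: int
    length: int
    strand: str
    spacer_base: str | None
    mismatches: int
    center_offset: int
    seq_name: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal base {exc.args[0]!r} in sequence") from exc


def _half_mismatches(codes: np.ndarray, pattern: str, offset: int, n_pos: int) -> np.ndarray:
    """Mismatch count of ``pattern`` at window positions 0..n_pos-1, where
    the half-site sits ``offset`` bases into the window."""
    mm = np.zeros(n_pos, dtype=np.int16)
    for k, base in enumerate(pattern):
        mm += codes[offset + k : offset + k + n_pos] != _CODE[base]
    return mm


def _scan_one_strand(seq: str, spec: RepeatElementSpec) -> list[tuple[int, int]]:
    """(start, total_mismatches) of every plus-strand window match."""
    window = spec.length
    n_pos = len(seq) - window + 1
    if n_pos <= 0:
        return []
    codes = _encode(seq)
    left, right = spec.half_patterns()
    mm_left = _half_mismatches(codes, left, 0, n_pos)
    mm_right = _half_mismatches(codes, right, 6 + spec.spacer, n_pos)
    budget = spec.max_mismatch_per_half
    ok = np.flatnonzero((mm_left <= budget) & (mm_right <= budget))
    return [(int(i), int(mm_left[i] + mm_right[i])) for i in ok]


def scan_repeat_elements(
    seq: str, spec: RepeatElementSpec, seq_name: str | None = None
) -> list[MotifHit]:
    """All repeat-element windows matching ``spec`` on both strands.

    Hits are sorted by (start, strand); overlapping hits are all
    reported.
    """
    seq = seq.upper()
    seq_center = len(seq) // 2
    window = spec.length
    hits: list[MotifHit] = []
    for start, mism in _scan_one_strand(seq, spec):
        spacer_seq = seq[start + 6 : start + 6 + spec.spacer] or None
        hits.append(
            MotifHit(
                motif_class=spec.name,
                start=start,
                length=window,
                strand="+",
                spacer_base=spacer_seq,
                mismatches=mism,
                center_offset=start + window // 2 - seq_center,
                seq_name=seq_name,
            )
        )
    rc = reverse_complement(seq)
    for p, mism in _scan_one_strand(rc, spec):
        start = len(seq) - p - window
        spacer_seq = rc[p + 6 : p + 6 + spec.spacer] or None
        hits.append(
            MotifHit(
                motif_class=spec.name,
                start=start,
                length=window,
                strand="-",
                spacer_base=spacer_seq,
                mismatches=mism,
                center_offset=start + window // 2 - seq_center,
                seq_name=seq_name,
            )
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_ets(seq: str, mode: str = "extended", seq_name: str | None = None) -> list[MotifHit]:
    """Exact-match ETS motif scan on both strands.

    ``mode`` is ``"core"`` (GGAA / reverse-strand TTCC) or ``"extended"``
    (CCGGAA / TTCCGG).
    """
    if mode not in ETS_PATTERNS:
        raise ValueError(f"mode must be one of {tuple(ETS_PATTERNS)}, got {mode!r}")
    seq = seq.upper()
    pattern = ETS_PATTERNS[mode]
    rc_pattern = reverse_complement(pattern)
    seq_center = len(seq) // 2
    window = len(pattern)
    hits: list[MotifHit] = []
    for strand, pat in (("+", pattern), ("-", rc_pattern)):
        start = seq.find(pat)
        while start != -1:
            hits.append(
                MotifHit(
                    motif_class=f"ETS_{mode}",
                    start=start,
                    length=window,
                    strand=strand,
                    spacer_base=None,
                    mismatches=0,
                    center_offset=start + window // 2 - seq_center,
                    seq_name=seq_name,
                )
            )
            start = seq.find(pat, start + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def classify_peak_motifs(
    peak_sequences: dict[str, str],
    repeat_spec: RepeatElementSpec | None = None,
    ets_mode: str = "extended",
) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Classify each peak sequence by motif content.

    A peak is ``both`` when it carries at least one repeat-element hit
    and at least one ETS hit, ``repeat_only`` / ``ets_only`` when only
    one kind is present, else ``neither`` (presence only: a zero-or-one
    occurrence reading of multiple hits). Returns (per-peak class,
    {"counts": ..., "percent": ...}); the four counts sum to the number
    of peaks and percentages are rounded to integers.
    """
    if repeat_spec is None:
        repeat_spec = RepeatElementSpec()
    per_peak: dict[str, str] = {}
    counts = {c: 0 for c in MOTIF_CLASSES}
    for name, seq in peak_sequences.items():
        has_repeat = bool(scan_repeat_elements(seq, repeat_spec))
        has_ets = bool(scan_ets(seq, ets_mode))
        if has_repeat and has_ets:
            cls = "both"
        elif has_repeat:
            cls = "repeat_only"
        elif has_ets:
            cls = "ets_only"
        else:
            cls = "neither"
        per_peak[name] = cls
        counts[cls] += 1
    n = len(peak_sequences)
    percent = {k: (round(100 * v / n) if n else 0) for k, v in counts.items()}
    return per_peak, {"counts": counts, "percent": percent}


def motif_offset_histogram(
    hits: list[MotifHit], bin_bp: int = 10, span_bp: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hit center offsets from the peak center.

    Bin i covers [i*bin_bp, (i+1)*bin_bp); offsets outside ±span are
    excluded, so the counts sum to the number of in-span hits. A motif
    concentrated under the peak center shows up as a central mode.
    """
    return _bin_signed_distances([h.center_offset for h in hits], bin_bp, span_bp)


def spacer_composition(hits: list[MotifHit]) -> dict[str, float]:
    """Base frequencies of single-base spacers over DR1-style hits.

    Only hits whose spacer is exactly one base contribute; frequencies
    over {A, C, G, T} sum to 1. No such hits -> empty mapping.
    """
    counts = {b: 0 for b in "ACGT"}
    total = 0
    for h in hits:
        if h.spacer_base is not None and len(h.spacer_base) == 1 and h.spacer_base in counts:
            counts[h.spacer_base] += 1
            total += 1
    if total == 0:
        return {}
    return {b: c / total for b, c in counts.items()}


def expected_background_hits(
    seq_len: int, n_seqs: int, spec: RepeatElementSpec
) -> float:
    """Expected repeat-element hit count on i.i.d. uniform ACGT sequences.

    Per half-site, a window position matches with probability
    ``sum_{j<=m} C(6,j) (3/4)^j (1/4)^(6-j)`` for mismatch budget m; the
    two halves are independent and the spacer is free. The expectation
    covers both strands:
    ``2 * (seq_len - window + 1) * n_seqs * p_half^2``.
    """
    n_pos = max(0, seq_len - spec.length + 1)
    m = spec.max_mismatch_per_half
    p_half = sum(comb(6, j) * (3 ** j) / (4 ** 6) for j in range(min(m, 6) + 1))
    return 2.0 * n_pos * n_seqs * p_half * p_half
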