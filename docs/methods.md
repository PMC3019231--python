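# Methods

This note records the model choices, conventions and numerical
decisions behind `nrcis`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention); 1-based sources
must be converted at the reader boundary. The peak "position" used for
every distance computation is the integer midpoint
`floor((start + end) / 2)`; peak callers differ on whether summit or
midpoint is the better anchor, and the midpoint is chosen because it
needs no extra summit column and matches the peak-center convention of
the motif offset analysis.

Overlap uses `gap(a, b) = max(0, max(s_a, s_b) − min(e_a, e_b))`, so
touching half-open intervals (`[100,200)` and `[200,300)`) have gap 0
and overlap already at tolerance 0. This definition is simple and
monotone in the tolerance; users who need strict interiors can subtract
1 bp from the tolerance themselves. The default tolerance is 0 for
replicate and cross-sample comparisons (the tool whose accounting this
reproduces does not document its allowance) and 200 bp against
histone-mark peaks, the standard nucleosome-positioning slack.
Set-level overlap is A-anchored — each A-peak counts at most once — and
the reported percentage is rounded to the nearest integer, matching how
such figures are printed in practice. Ties anywhere (equidistant genes,
equal p-values) break lexicographically on the identifier so results
are platform-independent.

## TSS distances and location categories

The TSS is `tx_start` for `+` genes and `tx_end` for `−` genes; signed
distance is positive downstream of the TSS in the gene's reading
direction, negative upstream. Histogram bin *i* covers
`[i·bin, (i+1)·bin)`, so distance −1 falls in the `[−bin, 0)` bin.

Each peak is classified against the gene minimising
`min(|d_TSS|, |d_3′|)` with distance 0 inside a gene body. A center
inside the body is always GENE (the exon/intron sub-category is indexed
in transcription order, so a minus-strand gene's first exon is its
highest-coordinate exon); a TSS-spanning peak therefore never splits
between "promoter" and "gene". When an upstream band of one gene and a
downstream band of another tie on distance, the upstream
(promoter-centric) reading wins. Band edges: proximal `< 2 kb`, distal
`[2, 10) kb`, far `[10, 100] kb`, desert `> 100 kb`. The ±1 kb
target-gene window is inclusive at both ends ("within ±1 kb" read as a
closed interval). Medians of even-sized groups are the mean of the two
central values; quartiles interpolate linearly between order
statistics. One TSS per gene record: transcript isoforms are out of
scope.

## Repeat-element and ETS scanning

Patterns are built from the half-site H = AGGTCA: DR = H·N{s}·H,
IR = H·N{s}·rc(H) (half-sites pointing toward each other),
ER = rc(H)·N{s}·H (pointing away), spacer s ∈ [0, 8] — window lengths
12–20 nt. **Orientation naming differs between tools in this
literature**; check the pattern definitions above when comparing. The
minus strand is scanned by applying the same patterns to the reverse
complement and mapping coordinates back; because IR and ER are
reverse-complement palindromic arrangements, each of their windows is
reported once per strand. All overlapping windows are reported; the
per-peak motif classification uses presence only (a zero-or-one
occurrence reading).

Matching is consensus-based with an independent mismatch budget per
half-site (default 1; the main sensitivity knob). `N` never matches a
fixed pattern position; spacer positions are unconstrained. ETS motifs
(GGAA core, CCGGAA extended) are matched exactly. De novo motif
discovery is deliberately out of scope: the verifiable content is the
motif model, not the discovery heuristic. `MotifHit.spacer_base` holds
the spacer sequence as read in the matched orientation (a single base
for spacer-1 elements).

The analytic background expectation for i.i.d. uniform sequences is
`2 · (L − w + 1) · n_seqs · p_half²` with
`p_half = Σ_{j≤m} C(6,j)·3^j/4^6`; it treats window positions as
independent, which is exact for the expectation (linearity) though not
for the variance, so simulation checks use a 3σ Poisson band.

## Enrichment and expression

Over-representation is the standard one-sided hypergeometric upper
tail; the "modified" variant some concept-enrichment servers advertise
is unspecified, so the standard tail is used and labelled as such.
No multiple-testing correction is applied by default (significance at
raw p < 0.05, matching the practice being reproduced);
Benjamini–Hochberg is available behind a flag. Mean-equalisation
scales population b by `mean(a)/mean(b)`, leaving dimensionless shape
statistics of b unchanged. qPCR fold enrichment is
`2^(cT_input − cT_ChIP)`, optionally times an input-dilution factor.

## Synthetic data: what it emulates, and what passing tests show

Defaults encode the study conditions the generators emulate: 63% of
peaks within ±1 kb of a TSS; summit-height medians 114 (inside) vs 50
(outside) on a log-normal with σ_ln = 0.5; 80% replicate overlap with
±50 bp jitter; DR1 planted in 23% and extended ETS in 63% of peak
sequences at N(0, 50 bp) offsets from the center, spacer base A or G
with equal probability; expression medians 535 (targets) vs 219
(background) on a log-normal with σ_ln = 1. Uniform base composition;
500 bp peak sequences; 2 chromosomes × 5 Mb with ~300 non-overlapping
genes are the default desk-scale genome (larger tests raise
`n_chroms`/`chrom_length` so the requested gene count fits).

A single root seed spawns one independent stream per generator, so
adding a generator never perturbs another's output; everything is
byte-reproducible per seed. The exact-count fixtures are *constructed*,
not sampled: overlap membership is assigned deterministically and
positions are laid out with guaranteed spacing, because worked-example
targets must be exact. In the replicate generator the realised overlap
equals the configured fraction exactly when base peaks are spaced
farther apart than peak width + jitter (`generate_spaced_peaks`
guarantees this); on clustered base peaks jittered partners can graze
neighbouring peaks and push the measured fraction slightly above the
configured one.

What the generators do **not** emulate: genomic sequence composition
(GC/CpG structure, repeats), overlapping or nested genes, isoform
diversity, read-level noise, summit asymmetry, and correlated motif
co-occurrence (plants are independent). Passing recovery tests
therefore demonstrate the correctness of the measurement machinery
under known truth, not the biological fidelity of any particular
dataset.

Statistical recovery tests compare a seeded estimate against the
configured truth at the stated tolerance; where a single run's sampling
error approaches that tolerance (class proportions at n = 2000,
expression medians at n = 1000), the test pools a few independent
seeded runs so the estimator's noise sits well inside the band rather
than widening the band.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script fast:
oracle comparisons use ≥1000 random instances with set sizes ≤ 200,
exhaustive scanner checks use 60-mers over all 27 arrangement × spacer
combinations, background-rate checks use 10,000 random 500-mers, the
hypergeometric oracle enumerates all draws for backgrounds up to
N = 12, and recovery runs use the printed-scale sizes (1,547 replicate
peaks, 2,000 peaks, 1,000 sequences).
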