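import numpy as np
import pytest

from nrcis.annotation import (
    GeneSubCategory,
    LocationCategory,
    assign_target_genes,
    classify_location,
    location_summary,
    median_height_split,
    multiway_target_overlap,
    tag_density_profile,
    tss_histogram,
)
from nrcis.io_formats import GeneRecord, PeakRecord
from nrcis.synthetic_data import SimulationConfig, generate_gene_annotation, generate_peak_set


def peak_at(center, chrom="chr1", width=20):
    return PeakRecord(chrom, center - width // 2, center + width - width // 2)


class TestClassifyLocation:
    def test_proximal_promoter_upstream_of_plus_gene(self, plus_gene):
        cat, sub = classify_location(peak_at(9_500), [plus_gene])
        assert cat is LocationCategory.PROXIMAL_PROMOTER and sub is None

    def test_upstream_bands_plus_gene(self, plus_gene):
        cases = {
            9_500: LocationCategory.PROXIMAL_PROMOTER,  # 500 bp upstream
            5_000: LocationCategory.DISTAL_PROMOTER,  # 5 kb upstream
        }
        for center, expected in cases.items():
            cat, _ = classify_location(peak_at(center), [plus_gene])
            assert cat is expected, center
        far_gene = GeneRecord("G", "G", "chr1", "+", 110_000, 116_000)
        cat, _ = classify_location(peak_at(60_000), [far_gene])  # 50 kb upstream
        assert cat is LocationCategory.FIVE_D

    def test_downstream_bands_plus_gene(self, plus_gene):
        # 3' end at 16000
        cases = {
            16_500: LocationCategory.THREE_PROXIMAL,
            19_000: LocationCategory.THREE_DISTAL,
            66_000: LocationCategory.THREE_D,
        }
        for center, expected in cases.items():
            cat, _ = classify_location(peak_at(center), [plus_gene])
            assert cat is expected, center

    def test_gene_desert_beyond_100kb(self):
        gene = GeneRecord("G", "G", "chr1", "+", 1_000_000, 1_010_000)
        cat, _ = classify_location(peak_at(850_000), [gene])  # 150 kb upstream
        assert cat is LocationCategory.GENE_DESERT

    def test_no_gene_on_chromosome_is_desert(self, plus_gene):
        cat, _ = classify_location(peak_at(10_500, chrom="chr9"), [plus_gene])
        assert cat is LocationCategory.GENE_DESERT

    def test_minus_gene_every_region_enumerated(self, minus_gene):
        # genomic exons [10000,11000) [12000,13000) [15000,16000); tx order reversed
        expectations = {
            15_500: (LocationCategory.GENE, GeneSubCategory.EXON1),
            14_000: (LocationCategory.GENE, GeneSubCategory.INTRON1),
            12_500: (LocationCategory.GENE, GeneSubCategory.OTHER_EXON),
            11_500: (LocationCategory.GENE, GeneSubCategory.OTHER_INTRON),
            10_500: (LocationCategory.GENE, GeneSubCategory.OTHER_EXON),
            16_500: (LocationCategory.PROXIMAL_PROMOTER, None),  # upstream for '-'
            9_500: (LocationCategory.THREE_PROXIMAL, None),  # downstream of 3' end
        }
        for center, expected in expectations.items():
            assert classify_location(peak_at(center), [minus_gene]) == expected, center

    def test_plus_gene_first_regions(self, plus_gene):
        assert classify_location(peak_at(10_500), [plus_gene]) == (
            LocationCategory.GENE,
            GeneSubCategory.EXON1,
        )
        assert classify_location(peak_at(11_500), [plus_gene]) == (
            LocationCategory.GENE,
            GeneSubCategory.INTRON1,
        )

    def test_center_in_gene_body_wins_over_promoter_of_neighbour(self, plus_gene):
        neighbour = GeneRecord("NB", "NB", "chr1", "+", 10_600, 20_000)
        cat, sub = classify_location(peak_at(10_500), [neighbour, plus_gene])
        assert cat is LocationCategory.GENE  # inside plus_gene's first exon


class TestSummaries:
    def test_all_proximal_promoter_is_100pct(self, plus_gene):
        peaks = [peak_at(9_000 + 100 * i) for i in range(10)]
        s = location_summary(peaks, [plus_gene])
        assert s["percent"][LocationCategory.PROXIMAL_PROMOTER.value] == 100
        assert sum(s["counts"].values()) == 10

    def test_empty_peak_set_all_zero(self, plus_gene):
        s = location_summary([], [plus_gene])
        assert all(v == 0 for v in s["counts"].values())
        assert all(v == 0 for v in s["percent"].values())

    def test_counts_partition_every_peak(self, rng):
        cfg = SimulationConfig(seed=5, n_peaks=300, n_genes=60)
        genes = generate_gene_annotation(cfg)
        peaks, _ = generate_peak_set(cfg, genes)
        s = location_summary(peaks, genes)
        assert sum(s["counts"].values()) == len(peaks)

    def test_strand_mirror_invariance_of_summary(self):
        cfg = SimulationConfig(seed=11, n_peaks=200, n_genes=40, n_chroms=1)
        genes = generate_gene_annotation(cfg)
        peaks, _ = generate_peak_set(cfg, genes)
        # even widths keep the integer midpoint exact under mirroring
        peaks = [PeakRecord(p.chrom, p.center - 100, p.center + 100, p.height, p.name) for p in peaks]
        L = 2 * cfg.chrom_length
        boundary = {x for g in genes for x in (g.tx_start, g.tx_end, *g.exon_starts, *g.exon_ends)}
        peaks = [p for p in peaks if p.center not in boundary]
        flip = {"+": "-", "-": "+"}
        mgenes = [
            GeneRecord(
                g.gene_id, g.symbol, g.chrom, flip[g.strand], L - g.tx_end, L - g.tx_start,
                tuple(L - e for e in reversed(g.exon_ends)),
                tuple(L - s for s in reversed(g.exon_starts)),
            )
            for g in genes
        ]
        mpeaks = [PeakRecord(p.chrom, L - p.end, L - p.start, p.height, p.name) for p in peaks]
        assert location_summary(peaks, genes) == location_summary(mpeaks, mgenes)


class TestTssHistogram:
    def test_edge_conventions(self, plus_gene):
        # distance 0 -> bin [0,100); distance -1 -> bin [-100,0)
        edges, counts = tss_histogram([peak_at(10_000), peak_at(9_999)], [plus_gene], 100, 1_000)
        zero_bin = int(np.searchsorted(edges, 0))
        assert counts[zero_bin] == 1
        assert counts[zero_bin - 1] == 1
        assert counts.sum() == 2

    def test_out_of_span_excluded(self, plus_gene):
        _, counts = tss_histogram([peak_at(50_000)], [plus_gene], 100, 1_000)
        assert counts.sum() == 0

    def test_uniform_placement_roughly_flat(self):
        cfg = SimulationConfig(seed=3, n_peaks=2_000, tss_fraction=1.0)
        genes = generate_gene_annotation(cfg)
        peaks, _ = generate_peak_set(cfg, genes)
        _, counts = tss_histogram(peaks, genes, 100, 1_000)
        # distances are uniform on [-1000, 1000]; chi-square sanity check
        expected = counts.sum() / len(counts)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # 20 bins -> 19 dof; 99.9th percentile ~ 43.8
        assert chi2 < 43.8


class TestTargets:
    def test_two_peaks_one_target_gene(self, plus_gene):
        asg = assign_target_genes([peak_at(9_900), peak_at(10_200)], [plus_gene])
        assert len(asg) == 2
        assert {a.gene_id for a in asg} == {"GPLUS"}

    def test_window_inclusive_at_boundary(self, plus_gene):
        inside = assign_target_genes([peak_at(11_000)], [plus_gene], window=1_000)
        outside = assign_target_genes([peak_at(11_001)], [plus_gene], window=1_000)
        assert len(inside) == 1 and inside[0].tss_distance == 1_000
        assert outside == []

    def test_infinite_window_covers_chromosome(self):
        cfg = SimulationConfig(seed=9, n_peaks=200)
        genes = generate_gene_annotation(cfg)
        peaks, _ = generate_peak_set(cfg, genes)
        asg = assign_target_genes(peaks, genes, window=10**12)
        assert len(asg) == len(peaks)

    def test_median_height_split(self, plus_gene):
        inside = [PeakRecord("chr1", 9_990, 10_010, h) for h in (10, 20, 30)]
        outside = [PeakRecord("chr1", 90_000, 90_020, h) for h in (40, 60)]
        med_in, med_out = median_height_split(inside + outside, [plus_gene])
        assert med_in == 20
        assert med_out == 50  # even count: mean of central pair

    def test_median_empty_partition_sentinel(self, plus_gene):
        med_in, med_out = median_height_split([peak_at(10_000)], [plus_gene])
        assert med_out is None


class TestMultiwayOverlap:
    def test_identical_sets_all_mass_in_intersection(self):
        r = multiway_target_overlap({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert r[frozenset({"A", "B"})] == 2
        assert r[frozenset({"A"})] == 0

    def test_disjoint_sets_zero_intersection(self):
        r = multiway_target_overlap({"A": {"g1"}, "B": {"g2"}})
        assert r[frozenset({"A", "B"})] == 0
        assert r[frozenset({"A"})] == 1

    def test_matches_bitmask_oracle_and_sums_to_union(self, rng):
        for _ in range(10):
            universe = [f"g{i}" for i in range(100)]
            sets = {
                name: {g for g in universe if rng.random() < p}
                for name, p in (("A", 0.3), ("B", 0.5), ("C", 0.2), ("D", 0.4))
            }
            regions = multiway_target_overlap(sets)
            union = set().union(*sets.values())
            assert sum(regions.values()) == len(union)
            for combo, count in regions.items():
                exact = [
                    g for g in union
                    if all((g in sets[n]) == (n in combo) for n in sets)
                ]
                assert count == len(exact)


class TestTagDensity:
    def test_one_tag_per_tss(self):
        genes = [
            GeneRecord(f"G{i}", f"G{i}", "chr1", "+", 10_000 * (i + 1), 10_000 * (i + 1) + 500)
            for i in range(10)
        ]
        tags = [("chr1", g.tss) for g in genes]
        edges, counts = tag_density_profile(tags, genes, 100, 1_000)
        zero_bin = int(np.searchsorted(edges, 0))
        assert counts[zero_bin] == 10

    def test_minus_strand_sign_convention(self):
        g = GeneRecord("G", "G", "chr1", "-", 1_000, 5_000)  # TSS at 5000
        # tag 50 bp before the TSS in reading direction sits at 5050 genomically
        edges, counts = tag_density_profile([("chr1", 5_050)], [g], 100, 1_000)
        bin_minus = int(np.searchsorted(edges, -100))
        assert counts[bin_minus] == 1  # distance -50 -> bin [-100, 0)

    def test_empty_tags_zero_vector(self, plus_gene):
        _, counts = tag_density_profile([], [plus_gene], 100, 1_000)
        assert counts.sum() == 0
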