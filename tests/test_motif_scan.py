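import numpy as np
import pytest

from nrcis.motif_scan import (
    RepeatElementSpec,
    classify_peak_motifs,
    expected_background_hits,
    motif_offset_histogram,
    reverse_complement,
    scan_ets,
    scan_repeat_elements,
    spacer_composition,
)
from nrcis.synthetic_data import SimulationConfig, generate_sequences_with_planted_motifs


def mismatches(window: str, pattern: str) -> int:
    # N never matches a fixed pattern position
    return sum(1 for a, b in zip(window, pattern) if a != b)


def brute_force_repeat_scan(seq: str, spec: RepeatElementSpec):
    """Exhaustive oracle: every start x strand, pure string comparison."""
    left, right = spec.half_patterns()
    w = spec.length
    hits = []
    for scanned, strand in ((seq, "+"), (reverse_complement(seq), "-")):
        for p in range(len(scanned) - w + 1):
            window = scanned[p : p + w]
            m1 = mismatches(window[:6], left)
            m2 = mismatches(window[6 + spec.spacer :], right)
            if m1 <= spec.max_mismatch_per_half and m2 <= spec.max_mismatch_per_half:
                start = p if strand == "+" else len(seq) - p - w
                hits.append((start, strand, m1 + m2))
    return sorted(hits)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


class TestRepeatScan:
    def test_exact_dr1_consensus_plant(self):
        hits = scan_repeat_elements(
            "AGGTCAAAGGTCA", RepeatElementSpec(max_mismatch_per_half=0)
        )
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand, h.spacer_base, h.mismatches) == (0, "+", "A", 0)

    def test_poly_c_has_no_hits(self):
        for arr in ("DR", "ER", "IR"):
            spec = RepeatElementSpec(arrangement=arr, spacer=2, max_mismatch_per_half=0)
            assert scan_repeat_elements("C" * 100, spec) == []

    def test_n_never_matches(self):
        seq = "AGGTCANAGGTCA".replace("N", "N")  # spacer N is free
        hits = scan_repeat_elements(seq, RepeatElementSpec(max_mismatch_per_half=0))
        assert len(hits) == 1 and hits[0].spacer_base == "N"
        # N inside a half-site burns a mismatch
        seq2 = "NGGTCAAAGGTCA"
        assert scan_repeat_elements(seq2, RepeatElementSpec(max_mismatch_per_half=0)) == []
        assert len(scan_repeat_elements(seq2, RepeatElementSpec(max_mismatch_per_half=1))) >= 1

    def test_spacer_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RepeatElementSpec(spacer=9)

    @pytest.mark.parametrize("arrangement", ["DR", "ER", "IR"])
    @pytest.mark.parametrize("spacer", range(9))
    def test_matches_exhaustive_oracle_on_random_60mers(self, rng, arrangement, spacer):
        for budget in (0, 1, 2):
            spec = RepeatElementSpec(
                arrangement=arrangement, spacer=spacer, max_mismatch_per_half=budget
            )
            for _ in range(3):
                seq = random_seq(rng, 60)
                got = [(h.start, h.strand, h.mismatches) for h in scan_repeat_elements(seq, spec)]
                assert sorted(got) == brute_force_repeat_scan(seq, spec)

    def test_reverse_complement_covariance(self, rng):
        for _ in range(50):
            seq = random_seq(rng, 60)
            for arr in ("DR", "ER", "IR"):
                spec = RepeatElementSpec(arrangement=arr, spacer=int(rng.integers(0, 9)))
                fwd = scan_repeat_elements(seq, spec)
                rev = scan_repeat_elements(reverse_complement(seq), spec)
                flip = {"+": "-", "-": "+"}
                mapped = sorted(
                    (len(seq) - h.start - h.length, flip[h.strand], h.mismatches) for h in rev
                )
                assert mapped == sorted((h.start, h.strand, h.mismatches) for h in fwd)


class TestEtsScan:
    def test_extended_forward(self):
        hits = scan_ets("CCGGAA", "extended")
        assert [(h.start, h.strand) for h in hits] == [(0, "+")]

    def test_extended_reverse(self):
        hits = scan_ets("TTCCGG", "extended")
        assert [(h.start, h.strand) for h in hits] == [(0, "-")]

    def test_core_not_matched_in_extended_mode(self):
        assert scan_ets("GGAA", "extended") == []
        assert [(h.start, h.strand) for h in scan_ets("GGAA", "core")] == [(0, "+")]

    def test_core_reverse_is_ttcc(self):
        assert [(h.start, h.strand) for h in scan_ets("TTCC", "core")] == [(0, "-")]


class TestClassification:
    def test_planted_both_classifies_both(self):
        seq = "T" * 40 + "AGGTCAGAGGTCA" + "T" * 10 + "CCGGAA" + "T" * 40
        per_peak, summary = classify_peak_motifs({"s": seq})
        assert per_peak["s"] == "both"
        assert summary["counts"]["both"] == 1

    def test_empty_input_all_zero(self):
        _, summary = classify_peak_motifs({})
        assert all(v == 0 for v in summary["counts"].values())
        assert all(v == 0 for v in summary["percent"].values())

    def test_counts_always_sum_to_n_peaks(self, rng):
        seqs = {f"s{i}": random_seq(rng, 120) for i in range(200)}
        _, summary = classify_peak_motifs(seqs)
        assert sum(summary["counts"].values()) == 200

    def test_recovers_independent_plant_probabilities(self):
        """Four-way class proportions match the independence arithmetic of
        the plant probabilities combined with the analytic background
        hit rates (Poisson presence approximation)."""
        n = 2_000
        spec = RepeatElementSpec()  # 1 mismatch per half
        counts = {c: 0 for c in ("both", "repeat_only", "ets_only", "neither")}
        # pool three independent runs so the sampling error of each class
        # fraction (sigma ~0.5 points) sits well inside the 2-point band
        cfg = SimulationConfig(seed=1)
        for seed in (1, 2, 3):
            seqs, _ = generate_sequences_with_planted_motifs(
                SimulationConfig(seed=seed), n
            )
            _, summary = classify_peak_motifs(seqs, spec, "extended")
            for c in counts:
                counts[c] += summary["counts"][c]
        lam_dr = expected_background_hits(cfg.seq_length, 1, spec)
        p_bg_dr = 1.0 - np.exp(-lam_dr)
        lam_ets = 2 * (cfg.seq_length - 6 + 1) * (1 / 4) ** 6
        p_bg_ets = 1.0 - np.exp(-lam_ets)
        p_dr = 1.0 - (1.0 - cfg.repeat_plant_probability) * (1.0 - p_bg_dr)
        p_ets = 1.0 - (1.0 - cfg.ets_plant_probability) * (1.0 - p_bg_ets)
        expected = {
            "both": p_dr * p_ets,
            "repeat_only": p_dr * (1 - p_ets),
            "ets_only": (1 - p_dr) * p_ets,
            "neither": (1 - p_dr) * (1 - p_ets),
        }
        for cls, p in expected.items():
            assert counts[cls] / (3 * n) == pytest.approx(p, abs=0.02), cls


class TestOffsetsAndSpacers:
    def test_all_plants_at_center_fill_central_bin(self):
        seq = "T" * 43 + "AGGTCAAAGGTCA" + "T" * 43  # window center == seq center
        hits = scan_repeat_elements(seq, RepeatElementSpec(max_mismatch_per_half=0))
        edges, counts = motif_offset_histogram(hits, bin_bp=10, span_bp=50)
        central = int(np.searchsorted(edges, 0))
        assert counts[central] == len(hits) == 1

    def test_empty_hit_list_zeros(self):
        _, counts = motif_offset_histogram([], bin_bp=10, span_bp=50)
        assert counts.sum() == 0

    def test_gaussian_plants_give_centered_histogram(self):
        cfg = SimulationConfig(seed=17, repeat_plant_probability=1.0, ets_plant_probability=0.0)
        seqs, truth = generate_sequences_with_planted_motifs(cfg, 1_000)
        spec = RepeatElementSpec(max_mismatch_per_half=0)
        hits = [h for s in seqs.values() for h in scan_repeat_elements(s, spec)]
        offsets = [h.center_offset for h in hits]
        assert abs(np.mean(offsets)) < 10  # mean offset ~0 at n = 1000

    def test_spacer_composition_pure_a(self):
        hits = scan_repeat_elements("AGGTCAAAGGTCA", RepeatElementSpec(max_mismatch_per_half=0))
        assert spacer_composition(hits)["A"] == 1.0

    def test_spacer_composition_empty(self):
        assert spacer_composition([]) == {}

    def test_spacer_half_a_half_g_recovered(self):
        cfg = SimulationConfig(seed=23, repeat_plant_probability=1.0, ets_plant_probability=0.0)
        seqs, _ = generate_sequences_with_planted_motifs(cfg, 1_000)
        spec = RepeatElementSpec(max_mismatch_per_half=0)
        hits = [h for s in seqs.values() for h in scan_repeat_elements(s, spec)]
        comp = spacer_composition(hits)
        assert comp["A"] == pytest.approx(0.5, abs=0.05)
        assert comp["G"] == pytest.approx(0.5, abs=0.05)


class TestBackgroundExpectation:
    def test_closed_form_single_window(self):
        spec = RepeatElementSpec(max_mismatch_per_half=0)
        assert expected_background_hits(13, 1, spec) == pytest.approx(2 * (1 / 4) ** 12)

    def test_too_short_sequence_zero(self):
        assert expected_background_hits(10, 5, RepeatElementSpec()) == 0

    @pytest.mark.parametrize("budget", [0, 1])
    def test_observed_matches_expectation_within_3_sigma(self, budget):
        cfg = SimulationConfig(
            seed=29, repeat_plant_probability=0.0, ets_plant_probability=0.0
        )
        n_seqs = 10_000
        seqs, _ = generate_sequences_with_planted_motifs(cfg, n_seqs)
        spec = RepeatElementSpec(max_mismatch_per_half=budget)
        observed = sum(len(scan_repeat_elements(s, spec)) for s in seqs.values())
        expected = expected_background_hits(cfg.seq_length, n_seqs, spec)
        assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_planted_recall_is_total(self):
        cfg = SimulationConfig(seed=31, repeat_plant_probability=1.0, ets_plant_probability=1.0)
        seqs, truth = generate_sequences_with_planted_motifs(cfg, 300)
        spec = RepeatElementSpec(max_mismatch_per_half=0)
        for entry in truth:
            seq = seqs[entry["name"]]
            if entry["motif"] == "DR1":
                starts = {h.start for h in scan_repeat_elements(seq, spec) if h.strand == "+"}
            else:
                starts = {h.start for h in scan_ets(seq, "extended") if h.strand == "+"}
            assert entry["start"] in starts
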