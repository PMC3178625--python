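"""Motif discovery, comparison, scanning, enrichment and matrix IO."""

import numpy as np
import pandas as pd
import pytest

import reflectchip as rc
from reflectchip.motifs import (FrequencyMatrix, MarkovBackground,
                                best_percent_scores, compare_motifs,
                                discover_motifs, encode, merge_motifs,
                                motif_enrichment_test, profit_scan,
                                read_matrices, revcomp, taatta_matrix,
                                train_background, write_matrices)


class TestBackground:
    def test_order0_on_homopolymer_is_near_one(self):
        bg = train_background(["A" * 2000], order=0)
        assert bg.base_freqs[0] > 0.99

    def test_order0_frequencies_equal_direct_counts(self):
        seq = "ACGTACGGTTAA" * 50
        bg = train_background([seq], order=0)
        counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
        smoothed = (counts + 1) / (counts.sum() + 4)
        assert np.allclose(bg.base_freqs, smoothed)

    def test_order2_parameter_recovery_at_1e6_bp(self):
        truth = MarkovBackground.random(order=2, seed=42)
        rng = np.random.default_rng(7)
        seqs = truth.sample(2000, 500, rng)    # 1e6 bp
        est = train_background(seqs, order=2)
        assert np.max(np.abs(est.trans - truth.trans)) < 0.02

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            train_background(["ACGT"], order=-1)


class TestDiscovery:
    def test_recovers_planted_taatta_consensus(self, planted_seq_sim):
        found = discover_motifs(planted_seq_sim.sequences, width=6)
        assert found[0].consensus == "TAATTA"
        assert found[0].n_sites >= 100

    def test_no_usable_word_gives_empty_list_not_error(self):
        # fully masked sequences contain no scorable w-mer, so no seed can
        # exceed its background expectation: an empty result, not an error
        bg = MarkovBackground.from_gc(0, 0.5)
        found = discover_motifs({"s1": "N" * 40, "s2": "N" * 40},
                                bg, width=4, n_seeds=5)
        assert found == []

    def test_seeds_are_only_overrepresented_words(self, planted_seq_sim):
        # every discovered motif stems from a word observed above its
        # background expectation, so its ranking score is positive
        found = discover_motifs(planted_seq_sim.sequences, width=6)
        assert found and all(rc.MotifDiscovery.score(m) > 0 for m in found)

    def test_deterministic_given_inputs(self, planted_seq_sim):
        a = discover_motifs(planted_seq_sim.sequences, width=6)
        b = discover_motifs(planted_seq_sim.sequences, width=6)
        assert [m.consensus for m in a] == [m.consensus for m in b]
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.probs, mb.probs)


class TestCompareMerge:
    def test_self_comparison_is_identity(self):
        m = taatta_matrix()
        sim, off, strand = compare_motifs(m, m)
        assert sim == pytest.approx(1.0)
        assert (off, strand) == (0, "+")

    def test_reverse_complement_found_on_minus_strand(self):
        m = FrequencyMatrix.from_consensus("TTAAGC", pseudocount=0.05)
        sim, off, strand = compare_motifs(m, m.reverse_complement())
        assert sim == pytest.approx(1.0)
        assert strand == "-"

    def test_hand_computed_column_correlation(self):
        # two 4-column matrices differing in their last column
        a = FrequencyMatrix(np.array([[0.7, 0.1, 0.1, 0.7],
                                      [0.1, 0.7, 0.1, 0.1],
                                      [0.1, 0.1, 0.7, 0.1],
                                      [0.1, 0.1, 0.1, 0.1]]))
        b = FrequencyMatrix(np.array([[0.7, 0.1, 0.1, 0.1],
                                      [0.1, 0.7, 0.1, 0.7],
                                      [0.1, 0.1, 0.7, 0.1],
                                      [0.1, 0.1, 0.1, 0.1]]))
        sim, off, strand = compare_motifs(a, b, min_overlap=4)
        cols = [1.0, 1.0, 1.0]
        v1, v2 = np.array([0.7, 0.1, 0.1, 0.1]), np.array([0.1, 0.7, 0.1, 0.1])
        cols.append(np.corrcoef(v1, v2)[0, 1])
        assert (off, strand) == (0, "+")
        assert sim == pytest.approx(np.mean(cols))

    def test_symmetry(self):
        a = FrequencyMatrix.from_consensus("TAATGG", pseudocount=0.1)
        b = FrequencyMatrix.from_consensus("CATAAT", pseudocount=0.2)
        assert compare_motifs(a, b)[0] == pytest.approx(compare_motifs(b, a)[0])

    def test_merge_identical_matrices_yields_same_matrix(self):
        m = taatta_matrix()
        out = merge_motifs([m, m], similarity_threshold=0.8)
        assert len(out) == 1
        assert np.allclose(out[0].probs, m.probs)

    def test_merge_dissimilar_matrices_stay_separate(self):
        a = FrequencyMatrix.from_consensus("AAAACC", pseudocount=0.05)
        b = FrequencyMatrix.from_consensus("GTGTGT", pseudocount=0.05)
        out = merge_motifs([a, b], similarity_threshold=0.8)
        assert len(out) == 2

    def test_merge_weighted_average_by_hand(self):
        pa = np.array([[0.8, 0.2], [0.1, 0.6], [0.05, 0.1], [0.05, 0.1]])
        pb = np.array([[0.4, 0.1], [0.3, 0.8], [0.2, 0.05], [0.1, 0.05]])
        a = FrequencyMatrix(pa.copy(), n_sites=30, name="a")
        b = FrequencyMatrix(pb.copy(), n_sites=10, name="b")
        out = merge_motifs([a, b], similarity_threshold=0.0, min_overlap=2)
        assert len(out) == 1
        expected = (30 * pa + 10 * pb) / 40
        assert np.allclose(out[0].probs, expected)
        assert out[0].n_sites == 40

    def test_merge_is_idempotent(self):
        merged = merge_motifs([taatta_matrix()], similarity_threshold=0.8)
        again = merge_motifs(merged, similarity_threshold=0.8)
        assert len(again) == len(merged) == 1
        assert np.allclose(again[0].probs, merged[0].probs)


class TestInformationContent:
    @pytest.mark.parametrize("column,bits", [
        ([0.25, 0.25, 0.25, 0.25], 0.0),
        ([1.0, 0.0, 0.0, 0.0], 2.0),
        ([0.5, 0.5, 0.0, 0.0], 1.0),
    ])
    def test_per_column_bits(self, column, bits):
        probs = np.tile(np.array(column)[:, None], (1, 4))
        per_col, total = FrequencyMatrix(probs).information_content()
        assert per_col[0] == pytest.approx(bits)
        assert total == pytest.approx(4 * bits)


class TestProfitScan:
    def test_exact_consensus_scores_hundred_percent(self):
        m = FrequencyMatrix.from_consensus("TAATTA", pseudocount=0.0)
        hits, summary = profit_scan({"s": "GGGGTAATTAGGGG"}, m, 75.0)
        assert summary.best_percent["s"] == pytest.approx(100.0)
        assert (hits["percent"] == 100.0).any()

    def test_mismatch_arithmetic(self):
        m = FrequencyMatrix.from_consensus("TAATTA", pseudocount=0.0)
        one = best_percent_scores({"s": "GGGG" + "TACTTA" + "GGGG"}, m)["s"]
        assert one == pytest.approx(100 * 5 / 6, abs=1e-9)
        two = best_percent_scores({"s": "GGGG" + "TACGTA" + "GGGG"}, m)["s"]
        assert two == pytest.approx(100 * 4 / 6, abs=1e-9)
        _, summary = profit_scan({"s": "GGGGTACTTAGGGG"}, m, 75.0)
        assert summary.n_with_hit == 1     # 83.3 >= 75
        _, summary2 = profit_scan({"s": "GGGGTACGTAGGGG"}, m, 75.0)
        assert summary2.n_with_hit == 0    # 66.7 < 75

    def test_hits_match_brute_force_window_scoring(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 80))
        m = taatta_matrix()
        hits, _ = profit_scan({"s": seq}, m, 60.0)
        smax = m.max_score()
        brute = []
        for strand, probs in (("+", m.probs),
                              ("-", m.reverse_complement().probs)):
            for off in range(len(seq) - 6 + 1):
                window = encode(seq[off:off + 6])
                pct = 100 * probs[window, np.arange(6)].sum() / smax
                if pct >= 60.0:
                    brute.append((off, strand, round(pct, 6)))
        got = sorted((int(r.offset), r.strand, round(r.percent, 6))
                     for r in hits.itertuples())
        assert got == sorted(brute)

    def test_case_insensitive_and_strand_symmetric(self, planted_seq_sim):
        m = taatta_matrix()
        seqs = dict(list(planted_seq_sim.sequences.items())[:30])
        _, s_upper = profit_scan(seqs, m, 75.0)
        _, s_lower = profit_scan({k: v.lower() for k, v in seqs.items()}, m, 75.0)
        pd.testing.assert_series_equal(s_upper.best_percent, s_lower.best_percent)
        _, s_rc = profit_scan({k: revcomp(v) for k, v in seqs.items()}, m, 75.0)
        assert s_rc.n_with_hit == s_upper.n_with_hit
        assert s_rc.total_hits == s_upper.total_hits

    def test_short_sequence_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            _, summary = profit_scan({"tiny": "ACG", "ok": "ACGTACGTAC"},
                                     taatta_matrix(), 75.0)
        assert summary.n_sequences == 1


class TestEnrichmentTest:
    def test_identical_score_multisets_give_zero_statistic(self):
        scores = np.linspace(50, 100, 40)
        stat, dof, p = motif_enrichment_test(scores, scores.copy())
        assert stat == 0.0
        assert p == 1.0

    def test_hand_computed_two_bin_table(self):
        # pos 30 low / 70 high, ctrl 70 low / 30 high -> chi2 = 32, df 1
        pos = [1.0] * 30 + [2.0] * 70
        ctl = [1.0] * 70 + [2.0] * 30
        stat, dof, p = motif_enrichment_test(pos, ctl, n_bins=2)
        assert stat == pytest.approx(32.0)
        assert dof == 1

    def test_planted_motif_strongly_enriched(self, planted_seq_sim):
        controls = rc.simulate_promoter_sequences(rc.SeqSimConfig(
            n_sequences=200, plant_fraction=0.0, seed=4)).sequences
        result = rc.discover_and_test(planted_seq_sim.sequences, controls,
                                      seed=7, width=6)
        assert result["motif"].consensus == "TAATTA"
        assert result["p"] < 1e-6

    def test_too_few_bins_is_an_error(self):
        with pytest.raises(ValueError):
            motif_enrichment_test([1.0] * 50, [1.0] * 50)


class TestMatrixIO:
    @pytest.mark.parametrize("fmt", ["jaspar", "transfac"])
    def test_round_trip(self, tmp_path, fmt, planted_seq_sim):
        found = discover_motifs(planted_seq_sim.sequences, width=6)[:2]
        # integer-ish counts survive the transfac writer's rounding
        path = tmp_path / f"m.{fmt}"
        write_matrices(found, path, fmt)
        back = read_matrices(path, fmt)
        assert len(back) == len(found)
        for orig, rt in zip(found, back):
            assert rt.consensus == orig.consensus
            assert np.allclose(rt.probs, orig.probs, atol=0.02)
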