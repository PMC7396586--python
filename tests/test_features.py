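import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circml import features
from circml.seqio import FeatureTable, IntervalTrack, ScoreTrack, TranscriptRecord

dna = st.text(alphabet="ACGT", min_size=3, max_size=200)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrinucleotideFrequencies:
    def test_homopolymer(self):
        out = features.trinucleotide_frequencies("AAAA")
        assert out[features.TRINUCLEOTIDES.index("AAA")] == 1.0
        assert out.sum() == 1.0

    def test_two_windows(self):
        out = features.trinucleotide_frequencies("ACGT")
        assert out[features.TRINUCLEOTIDES.index("ACG")] == 0.5
        assert out[features.TRINUCLEOTIDES.index("CGT")] == 0.5

    def test_short_sequence_all_zero(self):
        assert features.trinucleotide_frequencies("AC").sum() == 0.0

    def test_matches_naive_window_count(self, rng):
        seq = random_seq(rng, 1000)
        naive = np.zeros(64)
        for i in range(len(seq) - 2):
            naive[features.TRINUCLEOTIDES.index(seq[i : i + 3])] += 1
        naive /= len(seq) - 2
        np.testing.assert_allclose(features.trinucleotide_frequencies(seq), naive)

    @given(dna)
    def test_sums_to_one(self, seq):
        assert abs(features.trinucleotide_frequencies(seq).sum() - 1.0) < 1e-12


class TestCompositionBlock:
    def test_has_exactly_70_features(self):
        assert len(features.composition_block("ACGTACGT")) == 70

    def test_gc_and_length(self):
        block = features.composition_block("ATGC")
        assert block["gc"] == 0.5
        assert block["length"] == 4.0

    def test_overlapping_motif_frequency(self):
        # "AGAG": AG at dimer windows 0 and 2 of 3
        assert features.composition_block("AGAG")["freq_AG"] == pytest.approx(2 / 3)

    def test_motif_longer_than_sequence_is_zero(self):
        assert features.composition_block("AGG")["freq_AGGT"] == 0.0


class TestConservationBlock:
    def test_constant_track(self, record):
        track = ScoreTrack("c", [("chr1", record.start0, record.end0, 0.5)])
        block = features.conservation_block(record, track)
        assert block["cons_mean"] == 0.5
        assert block["cons_max"] == 0.5
        assert block["cons_var"] == 0.0
        assert block["cons_frac_gt_03"] == 1.0
        assert block["cons_frac_gt_06"] == 0.0
        assert block["cons_frac_gt_09"] == 0.0
        assert block["cons_frac_lt_09"] == 1.0

    def test_no_coverage_all_zero(self, record):
        block = features.conservation_block(record, ScoreTrack("c", []))
        assert all(v == 0.0 for v in block.values())

    def test_hand_computed_statistics(self):
        rec = TranscriptRecord("t", "ACGT", "chr1", 1, 4, "+")
        track = ScoreTrack(
            "c",
            [("chr1", 0, 1, 0.2), ("chr1", 1, 2, 0.4), ("chr1", 2, 4, 0.95)],
        )
        block = features.conservation_block(rec, track)
        scores = np.array([0.2, 0.4, 0.95, 0.95])
        assert block["cons_frac_gt_09"] == 0.5
        assert block["cons_frac_gt_03"] == 0.75
        assert block["cons_mean"] == pytest.approx(scores.mean())
        assert block["cons_var"] == pytest.approx(scores.var())

    def test_missing_coordinates_zero(self):
        rec = TranscriptRecord("t", "ACGT")
        block = features.conservation_block(rec, ScoreTrack("c", []))
        assert set(block.values()) == {0.0}

    def test_default_block_has_12_statistics(self, record):
        assert len(features.conservation_block(record, ScoreTrack("c", []))) == 12


class TestOverlapCount:
    def test_overlapping_interval(self):
        rec = TranscriptRecord("t", "A" * 100, "chr1", 101, 200, "+")
        assert features.overlap_count(rec, IntervalTrack("a", [("chr1", 150, 160)])) == 1

    def test_wrong_chromosome(self):
        rec = TranscriptRecord("t", "A" * 100, "chr1", 101, 200, "+")
        assert features.overlap_count(rec, IntervalTrack("a", [("chr2", 150, 160)])) == 0

    def test_adjacent_interval_does_not_count(self):
        rec = TranscriptRecord("t", "A" * 100, "chr1", 101, 200, "+")
        # [200, 210) touches but does not intersect [100, 200)
        assert features.overlap_count(rec, IntervalTrack("a", [("chr1", 200, 210)])) == 0

    def test_matches_pairwise_oracle(self, rng):
        rec = TranscriptRecord("t", "A" * 500, "chr1", 1001, 1500, "+")
        intervals = []
        for _ in range(100):
            chrom = "chr1" if rng.random() < 0.8 else "chr2"
            s = int(rng.integers(0, 2500))
            e = s + int(rng.integers(1, 400))
            intervals.append((chrom, s, e))
        track = IntervalTrack("a", intervals)
        brute = sum(
            1
            for chrom, s, e in intervals
            if chrom == "chr1" and s < rec.end0 and e > rec.start0
        )
        assert features.overlap_count(rec, track) == brute


class TestDensities:
    def test_atoi_count_and_density(self):
        rec = TranscriptRecord("t", "A" * 300, "chr1", 1, 300, "+")
        track = IntervalTrack("atoi", [("chr1", 10, 11), ("chr1", 50, 51), ("chr1", 299, 300)])
        assert features.atoi_features(rec, track) == (3, pytest.approx(0.01))

    def test_no_sites(self):
        rec = TranscriptRecord("t", "A" * 300, "chr1", 1, 300, "+")
        assert features.atoi_features(rec, IntervalTrack("atoi", [])) == (0, 0.0)

    def test_snp_density(self):
        rec = TranscriptRecord("t", "A" * 1000, "chr1", 1, 1000, "+")
        track = IntervalTrack("snp", [("chr1", i * 10, i * 10 + 1) for i in range(10)])
        assert features.snp_density(rec, track) == pytest.approx(0.01)


class TestLongestOrf:
    def test_whole_sequence_is_one_orf(self):
        assert features.longest_orf("ATGAAATAG") == (9, 1.0)

    def test_no_start_codon(self):
        assert features.longest_orf("CCCCCC") == (0, 0.0)

    def test_orf_requires_stop(self):
        assert features.longest_orf("ATGAAAAAA") == (0, 0.0)

    def test_orf_ends_at_first_inframe_stop(self):
        # ATG AAA TAA (stop) ... second ATG opens a longer reading frame later
        seq = "ATGAAATAAATGAAAAAATAG"
        length, prop = features.longest_orf(seq)
        assert length == 12
        assert prop == pytest.approx(12 / len(seq))

    @staticmethod
    def brute_force(seq):
        best = 0
        stops = features.STOP_CODONS
        for start in range(len(seq) - 2):
            if seq[start : start + 3] != "ATG":
                continue
            for stop in range(start + 3, len(seq) - 2, 3):
                if seq[stop : stop + 3] in stops:
                    best = max(best, stop + 3 - start)
                    break
        return best

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 2000)
        length, prop = features.longest_orf(seq)
        assert length == self.brute_force(seq)
        assert prop == length / len(seq)


class TestTandemRepeats:
    def test_dinucleotide_run(self):
        assert features.tandem_repeat_freq("ACACACACAC") == pytest.approx(0.1)

    def test_no_qualifying_run(self):
        assert features.tandem_repeat_freq("ACGTACGATCGG") == 0.0

    def test_homopolymer_counts_once(self):
        assert features.tandem_repeat_freq("AAAAAA") == pytest.approx(1 / 6)

    def test_two_separate_runs(self):
        seq = "AAAAAA" + "GTCA" + "ACACACAC"
        assert len(features.tandem_repeat_runs(seq)) == 2

    def test_external_count_overrides_detector(self):
        assert features.tandem_repeat_freq("ACGT" * 10, external_count=4) == pytest.approx(0.1)


class TestGraphFeatureSelect:
    def make_matrix(self, n_cols=200):
        names = [f"g{j}" for j in range(n_cols)]
        return FeatureTable(["t1", "t2"], names, np.arange(2 * n_cols, dtype=float).reshape(2, n_cols)), names

    def test_top_101_in_ranking_order(self):
        matrix, names = self.make_matrix()
        ranking = names[::-1]
        out = features.graph_feature_select(matrix, ranking, k=101)
        assert out.feature_names == ranking[:101]
        assert out.n_features == 101

    def test_k_one(self):
        matrix, names = self.make_matrix()
        out = features.graph_feature_select(matrix, names, k=1)
        assert out.feature_names == [names[0]]

    def test_unknown_id_named_in_error(self):
        matrix, names = self.make_matrix(5)
        with pytest.raises(KeyError, match="nope"):
            features.graph_feature_select(matrix, ["nope"] + names, k=3)


class TestIresScore:
    def test_passthrough(self):
        assert features.ires_score("x", {"x": 0.9}) == 0.9

    def test_absent_id_defaults_zero(self):
        assert features.ires_score("y", {"x": 0.9}) == 0.0

    def test_out_of_range_clipped(self):
        assert features.ires_score("x", {"x": 1.7}) == 1.0
        assert features.ires_score("x", {"x": -0.2}) == 0.0


class TestNormalize:
    def make(self, col):
        return FeatureTable([f"t{i}" for i in range(len(col))], ["f"],
                            np.array(col, dtype=float).reshape(-1, 1))

    def test_linear_scaling(self):
        table, _ = features.normalize(self.make([0, 5, 10]))
        np.testing.assert_allclose(table.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        table, _ = features.normalize(self.make([3, 3]))
        np.testing.assert_array_equal(table.values[:, 0], [0.0, 0.0])

    def test_held_out_values_clipped(self):
        fit_table = self.make([0, 5, 10])
        _, params = features.normalize(fit_table)
        held_out = features.apply_normalization(self.make([12]), params)
        assert held_out.values[0, 0] == 1.0

    def test_fit_rows_restrict_min_max(self):
        table = self.make([0, 5, 10, 100])
        normed, _ = features.normalize(table, fit_rows=[0, 1, 2])
        assert normed.values[3, 0] == 1.0  # clipped against fit max of 10

    def test_idempotent_on_fitted_data(self, rng):
        raw = FeatureTable([f"t{i}" for i in range(20)], ["a", "b"], rng.normal(size=(20, 2)))
        once, _ = features.normalize(raw)
        twice, _ = features.normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-15)


class TestAssembly:
    def test_full_mode_emits_191(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        tracks = features.TrackSet(
            alu=s["tracks"]["alu"], snp=s["tracks"]["snp"], atoi=s["tracks"]["atoi"],
            conservation=s["tracks"]["conservation"],
        )
        table = features.assemble_circlgb(
            s["records"], tracks, graph_matrix=s["graph"], graph_ranking=s["ranking"],
            mode="full", labels=s["labels"],
        )
        assert table.n_features == 191
        census = {g: list(table.group_of.values()).count(g) for g in set(table.group_of.values())}
        assert census == {"composition": 70, "graph": 101, "conservation": 12, "atos": 5, "new": 3}
        assert table.values.min() >= 0.0 and table.values.max() <= 1.0

    def test_baseline_mode_emits_188(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        tracks = features.TrackSet(conservation=s["tracks"]["conservation"])
        table = features.assemble_circlgb(
            s["records"], tracks, graph_matrix=s["graph"], graph_ranking=s["ranking"],
            mode="baseline",
        )
        assert table.n_features == 188
        assert "atoi_count" not in table.feature_names

    def test_circmrt_emits_182(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        tracks = features.TrackSet(
            alu=s["tracks"]["alu"], snp=s["tracks"]["snp"], atoi=s["tracks"]["atoi"],
            conservation=s["tracks"]["conservation"],
        )
        table = features.assemble_circmrt(
            s["records"], tracks, annotations=s["annotations"],
            graph_matrix=s["graph"], graph_ranking=s["ranking"], labels=s["labels"],
        )
        assert table.n_features == 182
        census = {g: list(table.group_of.values()).count(g) for g in set(table.group_of.values())}
        assert census == {"sequence": 71, "graph": 101, "genome_context": 7, "regulatory": 3}

    def test_circmrt_without_annotations_encodes_zero(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        table = features.assemble_circmrt(
            s["records"][:3], features.TrackSet(),
            graph_matrix=s["graph"], graph_ranking=s["ranking"], do_normalize=False,
        )
        for name in ("junction", "mirna_binding", "tf", "methylation", "h3k27ac"):
            np.testing.assert_array_equal(table.column(name), 0.0)

    def test_missing_graph_matrix_rejected(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        with pytest.raises(ValueError, match="graph"):
            features.assemble_circlgb(s["records"], features.TrackSet())

    def test_rerun_is_bit_identical(self, synth_pipeline_inputs):
        s = synth_pipeline_inputs
        tracks = features.TrackSet(conservation=s["tracks"]["conservation"])
        kwargs = dict(graph_matrix=s["graph"], graph_ranking=s["ranking"], mode="full")
        a = features.assemble_circlgb(s["records"], tracks, **kwargs)
        b = features.assemble_circlgb(s["records"], tracks, **kwargs)
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.values, b.values)
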