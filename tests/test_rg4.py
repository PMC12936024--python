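"""rG4 scanner: G-run detection, motif chaining, scoring, region assignment."""

import itertools

import numpy as np
import pytest

from raquant.rg4 import (
    G4Motif,
    RG4ScanConfig,
    Transcript,
    annotate_region,
    assemble_motifs,
    find_g_runs,
    positivity_stats,
    profile_genes,
    score_motif,
    summarize_structures,
    threshold_sweep,
)
from raquant.synth import TranscriptSpec, gen_transcripts

from conftest import stub_profiles


class TestFindGRuns:
    @pytest.mark.parametrize(
        "seq, min_len, expected",
        [
            ("GGGG", 3, [(0, 4, 4)]),
            ("ATATAT", 3, []),
            ("GGGAGGGTGGGAGGG", 3, [(0, 3, 3), (4, 7, 3), (8, 11, 3), (12, 15, 3)]),
            ("GGAGG", 2, [(0, 2, 2), (3, 5, 2)]),
            ("GGGUGGG", 3, [(0, 3, 3), (4, 7, 3)]),  # RNA alphabet accepted
            ("GGGNGGG", 3, [(0, 3, 3), (4, 7, 3)]),  # N never part of a run
        ],
    )
    def test_maximal_runs(self, seq, min_len, expected):
        assert find_g_runs(seq, min_len) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_g_runs("", 3)

    def test_bad_character_reported_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_g_runs("GGGXGGG", 3)


def _brute_force_max_motifs(runs, config):
    """Maximum number of valid non-overlapping 4-tract chains, by enumeration."""
    k = config.n_tracts

    def valid(window):
        return all(
            config.loop_min <= window[t + 1][0] - window[t][1] <= config.loop_max
            for t in range(k - 1)
        )

    windows = [i for i in range(len(runs) - k + 1) if valid(runs[i : i + k])]
    best = 0
    for subset in itertools.chain.from_iterable(
        itertools.combinations(windows, m) for m in range(len(windows), 0, -1)
    ):
        if all(b - a >= k for a, b in zip(subset, subset[1:])):
            best = max(best, len(subset))
            break
    return best


class TestAssembleMotifs:
    def test_single_forced_motif(self):
        seq = "GGGAGGGTGGGAGGG"
        motifs = assemble_motifs(find_g_runs(seq, 3), seq)
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.start, m.end) == (0, 15)
        assert m.loop_lengths == [1, 1, 1]
        assert m.tract_lengths == [3, 3, 3, 3]
        assert m.layers == 3

    def test_long_loop_blocks_chaining(self):
        seq = "GGG" + "A" * 8 + "GGGTGGGTGGG"
        assert assemble_motifs(find_g_runs(seq, 3), seq) == []

    def test_eight_runs_greedy_matches_enumeration(self):
        seq = "A".join(["GGG"] * 8)  # 8 runs, all loops 1 nt
        runs = find_g_runs(seq, 3)
        config = RG4ScanConfig()
        motifs = assemble_motifs(runs, seq, config)
        assert len(motifs) == 2 == _brute_force_max_motifs(runs, config)
        # leftmost-greedy: first motif starts at the first run
        assert motifs[0].start == 0

    def test_runs_never_shared_between_motifs(self, rng):
        bases = np.array(list("GAT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, p=[0.5, 0.3, 0.2], size=120))
            runs = find_g_runs(seq, 3)
            motifs = assemble_motifs(runs, seq)
            spans = [(m.start, m.end) for m in motifs]
            assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))


class TestScoreMotif:
    def _motif(self, start, end):
        return G4Motif(start, end, [4] * 4, [1, 1, 1], 4, 1)

    def test_all_g_window_scores_one(self):
        seq = "G" * 20
        assert score_motif(self._motif(0, 20), seq) == 1.0

    def test_balanced_gc_window_scores_zero(self):
        seq = "G" * 10 + "C" * 10
        assert score_motif(self._motif(0, 20), seq) == 0.0

    def test_hand_summed_window_mean(self):
        # motif span 15 inside a 20-nt sequence; window truncates to [0, 18)
        seq = "GGGAGGGTGGGAGGG" + "AAAAA"
        motif = G4Motif(0, 15, [3] * 4, [1, 1, 1], 3, 1)
        # per-base: 12 G-bases in runs of 3 contribute 3 each = 36; window len 18
        assert score_motif(motif, seq) == pytest.approx(36 / 18 / 4)

    def test_invariant_to_bases_outside_window(self, rng):
        seq = list("T" * 30 + "GGGGAGGGGAGGGGAGGGG" + "T" * 30)
        motif = G4Motif(30, 49, [4] * 4, [1, 1, 1], 4, 1)
        baseline = score_motif(motif, "".join(seq))
        lo, hi = 30 - 1, 49 + 1  # window is span padded to 20 nt: one base each side
        for _ in range(20):
            mutated = seq.copy()
            for pos in rng.integers(0, len(seq), size=10):
                if pos < lo or pos >= hi:
                    mutated[pos] = str(rng.choice(list("ACGT")))
            assert score_motif(motif, "".join(mutated)) == baseline

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            score_motif(self._motif(0, 50), "G" * 20)


class TestAnnotateRegion:
    tx = Transcript.from_boundaries("T1", "A" * 600, 100, 400)

    def _motif(self, start, end):
        return G4Motif(start, end, [3] * 4, [1, 1, 1], 3, 1)

    @pytest.mark.parametrize(
        "span, expected",
        [
            ((450, 465), "3UTR"),
            ((390, 405), "CDS"),  # 10 nt CDS vs 5 nt 3'UTR: majority
            ((395, 405), "3UTR"),  # exact 50/50 tie goes downstream
            ((0, 50), "5UTR"),
        ],
    )
    def test_majority_with_downstream_ties(self, span, expected):
        assert annotate_region(self._motif(*span), self.tx) == expected

    def test_agrees_with_per_base_overlap_count(self, rng):
        spans = self.tx.region_spans()
        for _ in range(1000):
            start = int(rng.integers(0, 590))
            end = start + int(rng.integers(1, min(60, 600 - start) + 1))
            counts = {
                r: sum(1 for i in range(start, end) if s <= i < e)
                for r, (s, e) in spans.items()
            }
            best = max(counts.values())
            # downstream-most region among the tied maxima
            expected = [r for r in ("5UTR", "CDS", "3UTR") if counts[r] == best][-1]
            assert annotate_region(self._motif(start, end), self.tx) == expected

    def test_out_of_bounds(self):
        with pytest.raises(ValueError, match="outside transcript"):
            annotate_region(self._motif(590, 610), self.tx)


class TestProfiles:
    def test_planted_cohort_recovered(self):
        transcripts, gene_truth, _ = gen_transcripts(
            TranscriptSpec(n_genes=10, n_positive=6), seed=7
        )
        profiles = profile_genes(transcripts)
        found = {p.gene_symbol for p in profiles if p.positive}
        planted = set(gene_truth[gene_truth["positive"]]["gene"])
        assert found == planted
        for p in profiles:
            assert sum(p.region_counts.values()) == p.n_rg4 == len(p.motifs)

    def test_empty_input(self):
        assert profile_genes([]) == []

    def test_below_threshold_motif_not_counted(self):
        # canonical motif with 3-G tracts and long loops scores below 0.5
        seq = "GGGAAAAAAAGGGAAAAAAAGGGAAAAAAAGGG" + "A" * 20
        tx = Transcript.from_boundaries("LOW", seq, 5, 30)
        (profile,) = profile_genes([tx])
        assert not profile.positive and profile.n_rg4 == 0

    def test_duplicate_genes_rejected(self):
        tx = Transcript.from_boundaries("DUP", "ATATAT", 2, 4)
        with pytest.raises(ValueError, match="duplicate"):
            profile_genes([tx, tx])


class TestSummaries:
    def test_region_percentages_from_element_counts(self):
        profiles = stub_profiles(42, 25, region_plan={"5UTR": 23, "CDS": 47, "3UTR": 58})
        summary = summarize_structures(profiles)
        assert summary.n_motifs == 128
        assert summary.region_table["5UTR"] == (23, 17.97)
        assert summary.region_table["CDS"] == (47, 36.72)
        assert summary.region_table["3UTR"] == (58, 45.31)
        pct_sum = sum(p for _, p in summary.region_table.values())
        assert abs(pct_sum - 100.0) < 0.05

    def test_gene_count_bins(self):
        # 19 genes with 1 motif, 14 with 2, 9 with 3 -> 42 positive genes
        plan = [1] * 19 + [2] * 14 + [3] * 9
        profiles = []
        for i, n in enumerate(plan):
            stub = stub_profiles(1, 0, region_plan={"3UTR": n})[0]
            stub.gene_symbol = f"G{i}"
            profiles.append(stub)
        summary = summarize_structures(profiles)
        assert summary.gene_count_bins["1"] == (19, 45.24)
        assert summary.gene_count_bins["2"] == (14, 33.33)
        assert summary.gene_count_bins[">=3"] == (9, 21.43)

    def test_single_motif_is_total(self):
        summary = summarize_structures(stub_profiles(1, 0, region_plan={"CDS": 1}))
        assert summary.gene_count_bins["1"] == (1, 100.0)

    def test_zero_motifs_has_absent_percentages(self):
        summary = summarize_structures(stub_profiles(0, 3))
        assert summary.n_motifs == 0
        assert summary.region_table == {}

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            summarize_structures([])


class TestPositivityStats:
    def test_cohort_rates(self):
        profiles = stub_profiles(42, 25)
        directions = {}
        positives = [p.gene_symbol for p in profiles if p.positive]
        negatives = [p.gene_symbol for p in profiles if not p.positive]
        for g in positives[:31] + negatives[:21]:
            directions[g] = "up"
        for g in positives[31:] + negatives[21:]:
            directions[g] = "down"
        stats = positivity_stats(profiles, directions)
        assert stats == {"overall_rate": 62.69, "up_rate": 59.62, "down_rate": 73.33}

    def test_zero_positive(self):
        profiles = stub_profiles(0, 5)
        stats = positivity_stats(profiles, {p.gene_symbol: "up" for p in profiles})
        assert stats["overall_rate"] == 0.0

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="missing direction"):
            positivity_stats(stub_profiles(1, 0), {})


class TestThresholdSweep:
    def test_nested_and_non_increasing(self):
        transcripts, _, _ = gen_transcripts(TranscriptSpec(n_genes=20, n_positive=14), seed=3)
        config = RG4ScanConfig()
        sweep = threshold_sweep(transcripts, config, [0.4, 0.5, 0.55, 0.6])
        n_pos = sweep["n_positive"].tolist()
        assert n_pos == sorted(n_pos, reverse=True)
        # nestedness via brute-force re-scan at each threshold
        for theta, row in zip(sweep["threshold"], sweep.itertuples()):
            pos = {
                p.gene_symbol
                for p in profile_genes(
                    transcripts,
                    RG4ScanConfig(prob_threshold=float(theta)),
                )
                if p.positive
            }
            assert len(pos) == row.n_positive
        strict = {
            p.gene_symbol
            for p in profile_genes(transcripts, RG4ScanConfig(prob_threshold=0.6))
            if p.positive
        }
        default = {
            p.gene_symbol
            for p in profile_genes(transcripts, RG4ScanConfig(prob_threshold=0.5))
            if p.positive
        }
        assert strict <= default

    def test_threshold_zero_keeps_every_motif_carrier(self):
        transcripts, gene_truth, _ = gen_transcripts(
            TranscriptSpec(n_genes=8, n_positive=5), seed=11
        )
        sweep = threshold_sweep(transcripts, RG4ScanConfig(), [0.0])
        assert sweep.iloc[0]["n_positive"] == gene_truth["positive"].sum()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], RG4ScanConfig(), [1.5])
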