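import numpy as np
import pytest

from igmaf.correction import (
    CorrectedRecord,
    UIDGroup,
    bias_correct,
    build_consensus,
    correct_dataset,
    group_by_rid,
)
from igmaf.preprocess import ParsedRead
from igmaf.simulate import SimulatorParams, simulate_dataset
from igmaf.preprocess import parse_reads


def mk_read(rid, insert, qual=None, fid="AAAAAAAAAA", read_id="r"):
    qual = qual or "F" * len(insert)
    mean_q = float(np.mean([ord(c) - 33 for c in qual]))
    return ParsedRead(read_id, fid, rid, insert, qual, mean_q)


RID_A = "AAAAAAAAAAAA"
RID_B = "CCCCCCCCCCCC"
RID_C = "GGGGGGGGGGGG"


class TestGrouping:
    def test_exact_grouping_sizes(self):
        reads = (
            [mk_read(RID_A, "ACGT", read_id=f"a{i}") for i in range(4)]
            + [mk_read(RID_B, "ACGT", read_id=f"b{i}") for i in range(3)]
            + [mk_read(RID_C, "ACGT", read_id=f"c{i}") for i in range(2)]
        )
        groups, report = group_by_rid(reads)
        assert sorted(g.size for g in groups) == [2, 3, 4]
        assert report.size_histogram == {4: 1, 3: 1, 2: 1}

    def test_near_rid_absorption(self):
        near = RID_A[:-1] + "T"
        reads = [mk_read(RID_A, "ACGT", read_id=f"a{i}") for i in range(5)]
        reads.append(mk_read(near, "ACGT", read_id="s"))
        groups, report = group_by_rid(reads, merge_near_rids=True)
        assert len(groups) == 1 and groups[0].size == 6
        assert report.n_absorbed == 1
        # default off: two groups
        groups_off, _ = group_by_rid(reads, merge_near_rids=False)
        assert len(groups_off) == 2

    def test_empty_input(self):
        groups, report = group_by_rid([])
        assert groups == [] and report.n_groups == 0


class TestConsensus:
    def test_unanimous(self):
        g = UIDGroup(RID_A, [mk_read(RID_A, "ACGT") for _ in range(3)])
        rec = build_consensus(g)
        assert rec.sequence == "ACGT" and rec.provenance == "corrected"

    def test_majority_vote(self):
        g = UIDGroup(RID_A, [mk_read(RID_A, s) for s in ["ACGT", "ACGA", "ACGT"]])
        assert build_consensus(g).sequence == "ACGT"

    def test_low_coverage_passthrough_picks_best_quality(self):
        r1 = mk_read(RID_A, "ACGT", qual="FFFF", read_id="hi")
        r2 = mk_read(RID_A, "ACGA", qual="0000", read_id="lo")
        rec = build_consensus(UIDGroup(RID_A, [r2, r1]))
        assert rec.provenance == "passthrough"
        assert rec.sequence == "ACGT"

    def test_tie_broken_by_summed_phred(self):
        # position 4 splits 2/2; Phred sums 74 (T) vs 52 (A): T wins
        reads = [
            mk_read(RID_A, "ACGT", qual="FFF" + chr(37 + 33)),   # T, q37
            mk_read(RID_A, "ACGT", qual="FFF" + chr(37 + 33)),   # T, q37
            mk_read(RID_A, "ACGA", qual="FFF" + chr(26 + 33)),   # A, q26
            mk_read(RID_A, "ACGA", qual="FFF" + chr(26 + 33)),   # A, q26
        ]
        rec = build_consensus(UIDGroup(RID_A, reads))
        assert rec.sequence == "ACGT"

    def test_modal_length_restriction_prefers_longer_on_tie(self):
        reads = [
            mk_read(RID_A, "ACGTA"),
            mk_read(RID_A, "ACGTA"),
            mk_read(RID_A, "ACG"),
            mk_read(RID_A, "ACG"),
        ]
        assert build_consensus(UIDGroup(RID_A, reads)).sequence == "ACGTA"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        reads = [
            mk_read(RID_A, "".join(rng.choice(list("ACGT"), 30)), read_id=f"r{i}")
            for i in range(7)
        ]
        base = build_consensus(UIDGroup(RID_A, list(reads))).sequence
        for _ in range(5):
            rng.shuffle(reads)
            assert build_consensus(UIDGroup(RID_A, list(reads))).sequence == base


class TestCorrectDataset:
    def test_aggregation_and_conservation(self):
        groups = [
            UIDGroup(RID_A, [mk_read(RID_A, "ACGT") for _ in range(3)]),
            UIDGroup(RID_B, [mk_read(RID_B, "ACGT", fid="CCCCCCCCCC") for _ in range(4)]),
            UIDGroup(RID_C, [mk_read(RID_C, "ACGT") for _ in range(3)]),
        ]
        records = correct_dataset(groups)
        assert len(records) == 1
        rec = records[0]
        assert rec.rid_count == 3 and rec.read_count == 10
        assert sum(r.rid_count for r in records) == len(groups)

    def test_strict_mode_drops_low_coverage(self):
        groups = [
            UIDGroup(RID_A, [mk_read(RID_A, "ACGT") for _ in range(3)]),
            UIDGroup(RID_B, [mk_read(RID_B, "TTTT")]),
        ]
        assert len(correct_dataset(groups)) == 2
        assert len(correct_dataset(groups, strict=True)) == 1

    def test_zero_noise_simulation_identity(self, small_set, layout_config):
        params = SimulatorParams(n_transcripts=100, seq_error_rate=0.0,
                                 pcr_error_rate=0.0, seed=2)
        sim = simulate_dataset(params, pool=small_set)
        parsed, _ = parse_reads(sim.reads, layout_config)
        groups, _ = group_by_rid(parsed)
        records = correct_dataset(groups)
        assert {r.sequence for r in records} == {m.true_sequence for m in sim.molecules}
        assert sum(r.rid_count for r in records) == len(groups)

    def test_noisy_consensus_recovers_truth(self, small_set, layout_config):
        """At 0.5% error and >=5 reads/molecule every consensus is exact."""
        params = SimulatorParams(n_transcripts=200, seq_error_rate=0.005,
                                 pcr_error_rate=0.0, reads_per_molecule_mean=8.0,
                                 seed=6)
        sim = simulate_dataset(params, pool=small_set)
        parsed, _ = parse_reads(sim.reads, layout_config)
        groups, _ = group_by_rid(parsed, merge_near_rids=True)
        rid2true = {m.rid: m.true_sequence for m in sim.molecules}
        for g in groups:
            rec = build_consensus(g, 5)
            if rec.provenance == "corrected" and g.rid in rid2true:
                assert rec.sequence == rid2true[g.rid]

    def test_monotone_repair(self, small_set, layout_config):
        """Correction never increases distinct sequences and never collapses
        below the true molecular diversity."""
        params = SimulatorParams(n_transcripts=150, seq_error_rate=0.003,
                                 pcr_error_rate=0.0, seed=14)
        sim = simulate_dataset(params, pool=small_set)
        parsed, _ = parse_reads(sim.reads, layout_config)
        groups, _ = group_by_rid(parsed, merge_near_rids=True)
        records = correct_dataset(groups)
        raw_distinct = len({p.insert for p in parsed})
        corrected_distinct = len({r.sequence for r in records})
        true_distinct = len({m.true_sequence for m in sim.molecules})
        assert corrected_distinct <= raw_distinct
        assert corrected_distinct >= true_distinct


class TestBiasCorrect:
    def test_uniform_ratios_are_identity(self):
        out = bias_correct([("a", 100, 300), ("b", 50, 150)])
        freqs = {c.key: c.corrected_frequency for c in out}
        assert freqs["a"] == pytest.approx(100 / 150)
        assert freqs["b"] == pytest.approx(50 / 150)

    def test_hand_worked_two_clone_example(self):
        # R=100 each, a1=4, a2=2 -> a_bar=3, corrected 75 and 150
        out = {c.key: c for c in bias_correct([("x", 100, 400), ("y", 100, 200)])}
        assert out["x"].amplification_ratio == 4
        assert out["y"].amplification_ratio == 2
        assert out["x"].corrected_count == pytest.approx(75)
        assert out["y"].corrected_count == pytest.approx(150)
        assert out["x"].corrected_frequency == pytest.approx(1 / 3)
        assert out["y"].corrected_frequency == pytest.approx(2 / 3)

    def test_single_clone_frequency_one(self):
        out = bias_correct([("only", 7, 21)])
        assert out[0].corrected_frequency == 1.0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        items = [(f"c{i}", int(rng.integers(1, 50)), int(rng.integers(1, 200)))
                 for i in range(20)]
        items = [(k, r, max(r, f)) for k, r, f in items]
        out = bias_correct(items)
        assert sum(c.corrected_frequency for c in out) == pytest.approx(1.0)

    def test_zero_rid_rejected(self):
        with pytest.raises(ValueError):
            bias_correct([("a", 0, 1)])
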