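import numpy as np
import pandas as pd
import pytest

from igmaf._util import random_nt
from igmaf.annotate import (
    annotate_records,
    assign_isotype,
    assign_j,
    assign_v,
    count_shm,
    extract_cdr3,
    separate_spikeins,
)
from igmaf.correction import CorrectedRecord
from igmaf.pipeline import run_sample
from igmaf.simulate import (
    RepertoireParams,
    SimulatorParams,
    generate_repertoire,
    simulate_dataset,
)


def as_records(seqs):
    return [CorrectedRecord(s, 1, 1, 1, "corrected") for s in seqs]


class TestSegmentAssignment:
    def test_zero_noise_v_call(self, db, small_set):
        for std in small_set.standards[:5]:
            aln = assign_v(std.full_sequence, db.v_segments)
            assert aln.name == std.v_name
            assert aln.n_mismatches == len(std.designed_mutations)
            assert sorted(aln.mismatch_query_positions) == sorted(
                m[0] for m in std.designed_mutations
            )

    def test_planted_v_substitutions_located(self, db, small_set):
        std = next(s for s in small_set.standards if not s.designed_mutations)
        seq = std.full_sequence
        prefix = len(small_set.layout.conserved_5p) + len(small_set.layout.leader)
        planted = [30, 101, 205]
        s = list(seq)
        for p in planted:
            s[prefix + p] = "A" if s[prefix + p] != "A" else "G"
        aln = assign_v("".join(s), db.v_segments)
        assert aln.name == std.v_name
        assert sorted(aln.mismatch_query_positions) == planted

    def test_random_sequence_gets_no_call(self, db):
        rng = np.random.default_rng(987654)
        for _ in range(5):
            assert assign_v(random_nt(rng, 400), db.v_segments) is None

    def test_j_mirror_cases(self, db, small_set):
        std = small_set.standards[0]
        v = db.v_segments[std.v_name]
        va = assign_v(std.full_sequence, db.v_segments)
        ja = assign_j(std.full_sequence, db.j_segments,
                      search_from=va.query_to_target[v.anchor_offset] + 3)
        assert ja.name == std.j_name and ja.n_mismatches == 0
        rng = np.random.default_rng(1)
        assert assign_j(random_nt(rng, 200), db.j_segments) is None


class TestCdr3:
    def test_designed_cdr3_recovered(self, db, small_set):
        for std in small_set.standards:
            v = db.v_segments[std.v_name]
            j = db.j_segments[std.j_name]
            va = assign_v(std.full_sequence, db.v_segments)
            ja = assign_j(std.full_sequence, db.j_segments,
                          search_from=va.query_to_target[v.anchor_offset] + 3)
            nt, aa, productive, fail = extract_cdr3(std.full_sequence, v, j, va, ja)
            assert (nt, aa) == (std.cdr3_nt, std.cdr3_aa)
            assert productive and fail is None
            assert aa.startswith("C") and aa.endswith("W")

    def test_internal_stop_flagged_nonproductive(self, db, layout):
        from igmaf.standards import assemble_full_sequence

        v = next(iter(db.v_segments.values()))
        j = next(iter(db.j_segments.values()))
        cdr3 = v.anchor_codon + "TAG" + "GCA" + j.anchor_codon
        seq = assemble_full_sequence(layout, v, j, cdr3, [], "IgG1")
        va = assign_v(seq, db.v_segments)
        ja = assign_j(seq, db.j_segments,
                      search_from=va.query_to_target[v.anchor_offset] + 3)
        nt, aa, productive, fail = extract_cdr3(seq, v, j, va, ja)
        assert not productive and fail == "stop_codon"


class TestShm:
    def test_footprint_mutations_excluded(self, db, small_set):
        std = next(s for s in small_set.standards if not s.designed_mutations)
        prefix = len(small_set.layout.conserved_5p) + len(small_set.layout.leader)
        v = db.v_segments[std.v_name]
        j = db.j_segments[std.j_name]
        s = list(std.full_sequence)
        outside = [40, 90, 140, 190, 240]
        inside = [5]  # within the (0, 21) primer footprint
        for p in outside + inside:
            s[prefix + p] = "A" if s[prefix + p] != "A" else "G"
        seq = "".join(s)
        va = assign_v(seq, db.v_segments)
        ja = assign_j(seq, db.j_segments,
                      search_from=va.query_to_target[v.anchor_offset] + 3)
        shm, indels = count_shm(v, j, va, ja, (0, 21))
        assert shm == 5 and indels == 0

    def test_memory_repertoire_shm_recovered_exactly(self, db):
        params = RepertoireParams(subset="memory", n_clones=40, n_replicates=2,
                                  cells_per_replicate=500, seed=11)
        clones = generate_repertoire(db, params)
        for cl in clones:
            v = db.v_segments[cl.v_name]
            j = db.j_segments[cl.j_name]
            for var in cl.variants:
                va = assign_v(var.sequence, db.v_segments)
                ja = assign_j(var.sequence, db.j_segments,
                              search_from=va.query_to_target[v.anchor_offset] + 3)
                shm, _ = count_shm(v, j, va, ja, (0, 21))
                assert shm == len(var.shm_positions)


class TestIsotype:
    def test_exact_prefixes_recovered(self, db):
        prefixes = db.constant_prefixes()
        for label, seq in prefixes.items():
            assert assign_isotype("GCA" * 20 + seq, prefixes) == label

    def test_equidistant_prefix_ambiguous(self):
        prefixes = {"IgG1": "AAAAAAAA", "IgG2": "AAAATTTT"}
        # 2 mismatches to each reference
        assert assign_isotype("AAAAAATT", prefixes) == "ambiguous"

    def test_zero_noise_simulation_recovers_subclasses(self, db, small_set, layout_config):
        params = SimulatorParams(n_transcripts=60, seq_error_rate=0.0,
                                 pcr_error_rate=0.0, seed=9)
        sim = simulate_dataset(params, pool=small_set)
        res = run_sample(sim.reads, db, layout_config, standards=small_set,
                         identifier=small_set.layout.synthetic_identifier, cluster=False)
        truth = {m.true_sequence: m.subclass_label for m in sim.molecules}
        for _, row in res.annotated.iterrows():
            assert row["subclass"] == truth[row["sequence"]]


class TestSpikeinSeparation:
    def test_simulated_spikeins_matched_to_source(self, db, small_set, layout_config):
        params = SimulatorParams(n_transcripts=60, seq_error_rate=0.0,
                                 pcr_error_rate=0.0, seed=10)
        sim = simulate_dataset(params, pool=small_set)
        res = run_sample(sim.reads, db, layout_config, standards=small_set,
                         identifier=small_set.layout.synthetic_identifier, cluster=False)
        truth = {m.true_sequence: m.source for m in sim.molecules}
        for _, row in res.annotated.iterrows():
            assert bool(row["is_spikein"])
            assert row["matched_standard_id"] == truth[row["sequence"]]

    def test_biological_reads_not_flagged(self, db, layout, layout_config):
        rp = RepertoireParams(subset="naive", n_clones=10, n_replicates=1,
                              cells_per_replicate=100, seed=3)
        rep = generate_repertoire(db, rp)
        params = SimulatorParams(n_transcripts=30, seq_error_rate=0.0,
                                 pcr_error_rate=0.0, seed=3)
        sim = simulate_dataset(params, repertoire=rep)
        res = run_sample(sim.reads, db, layout_config, standards=None,
                         identifier=layout.synthetic_identifier, cluster=False)
        assert not res.annotated["is_spikein"].any()

    def test_identifier_with_one_mismatch_still_separated(self, db, small_set):
        ident = small_set.layout.synthetic_identifier
        std = small_set.standards[0]
        pos = std.full_sequence.index(ident) + 3
        s = list(std.full_sequence)
        s[pos] = "A" if s[pos] != "A" else "G"
        df = annotate_records(as_records(["".join(s)]), db)
        out = separate_spikeins(df, ident, small_set)
        assert bool(out["is_spikein"].iloc[0])
        assert out["matched_standard_id"].iloc[0] == std.standard_id


def test_annotation_order_independent(db, small_set):
    seqs = [s.full_sequence for s in small_set.standards[:6]]
    fwd = annotate_records(as_records(seqs), db)
    rev = annotate_records(as_records(seqs[::-1]), db)
    fwd_sorted = fwd.sort_values("sequence").reset_index(drop=True)
    rev_sorted = rev.sort_values("sequence").reset_index(drop=True)
    cols = ["sequence", "v_call", "j_call", "junction_aa", "shm_count", "subclass"]
    pd.testing.assert_frame_equal(fwd_sorted[cols], rev_sorted[cols])
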