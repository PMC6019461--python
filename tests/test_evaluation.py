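import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from igmaf.evaluation import (
    assign_error_class,
    clr_transform,
    correction_efficacy,
    error_variant_report,
    feature_summary,
    fisher_exact_2x2,
    frequency_recovery,
    lda_axis,
)
from ._oracles import fisher_exact_enumeration


class FakeStandard:
    def __init__(self, sid, seq, aa):
        self.standard_id = sid
        self.full_sequence = seq
        self.cdr3_aa = aa


class TestErrorClasses:
    STD = FakeStandard("STD-001", "AAACCCGGGTTT", "CARW")

    def test_exact(self):
        assert assign_error_class("AAACCCGGGTTT", "CARW", self.STD) == "exact"

    def test_cdr3_difference_dominates(self):
        assert assign_error_class("AAACCCGGGTTT", "CGRW", self.STD) == "cdr3_error_variant"

    def test_nt_only_difference(self):
        assert assign_error_class("AAACCCGGGTTA", "CARW", self.STD) == "vdj_nt_error_variant"


def spike_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["matched_standard_id", "sequence", "junction_aa",
                 "duplicate_count", "consensus_count", "fid_count"],
    )


class FakeSet:
    def __init__(self, standards):
        self.standards = standards

    def by_id(self):
        return {s.standard_id: s for s in self.standards}


class TestErrorVariantReport:
    def test_zero_noise_counts_zero(self):
        std = FakeStandard("STD-001", "AAAA", "CW")
        df = spike_frame([("STD-001", "AAAA", "CW", 10, 5, 5)])
        report = error_variant_report(df, FakeSet([std]))
        assert report.total("cdr3_error_variant") == 0
        assert report.total("vdj_nt_error_variant") == 0

    def test_distinct_variant_keys_and_normalization(self):
        std = FakeStandard("STD-001", "AAAA", "CW")
        df = spike_frame([
            ("STD-001", "AAAA", "CW", 50_000, 1, 1),   # exact
            ("STD-001", "AAAT", "CW", 25_000, 1, 1),   # nt variant
            ("STD-001", "AATT", "CW", 12_500, 1, 1),   # another nt variant
            ("STD-001", "TTTT", "CY", 12_500, 1, 1),   # cdr3 variant
            ("STD-001", "GGGG", "CY", 0, 1, 1),        # same a.a. variant: 1 distinct
        ])
        report = error_variant_report(df, FakeSet([std]), aligned_read_total=100_000)
        row = report.per_standard.iloc[0]
        assert row["cdr3_errors"] == 1
        assert row["vdj_errors"] == 2
        assert row["cdr3_errors_per_100k"] == 1.0

    def test_error_load_correlates_with_concentration(self):
        rng = np.random.default_rng(0)
        standards, rows, manifest = [], [], {}
        conc = np.geomspace(0.001, 0.1, 30)
        conc = conc / conc.sum()
        for i, c in enumerate(conc):
            sid = f"STD-{i:03d}"
            standards.append(FakeStandard(sid, "A" * 20, "CW"))
            manifest[sid] = float(c)
            n_err = rng.poisson(c * 2000)  # error yield proportional to abundance
            for k in range(n_err):
                rows.append((sid, f"err-{i}-{k}", "CW", 1, 1, 1))
            rows.append((sid, "A" * 20, "CW", 1, 1, 1))
        report = error_variant_report(spike_frame(rows), FakeSet(standards),
                                      manifest=manifest)
        assert report.concentration_correlation > 0.5


class TestCorrectionEfficacy:
    def _report(self, cdr3, vdj):
        df = pd.DataFrame({
            "standard_id": ["S"], "cdr3_errors": [cdr3], "vdj_errors": [vdj],
            "cdr3_errors_per_100k": [0.0], "vdj_errors_per_100k": [0.0],
        })
        from igmaf.evaluation import ErrorVariantReport
        return ErrorVariantReport(df, 1, 0, 0, 0, 0)

    def test_full_removal(self):
        out = correction_efficacy(self._report(100, 100), self._report(0, 0))
        assert out["cdr3_error_variant"] == 100.0

    def test_partial_removal_arithmetic(self):
        out = correction_efficacy(self._report(40, 40), self._report(1, 1))
        assert out["cdr3_error_variant"] == pytest.approx(97.5)

    def test_na_when_no_raw_errors(self):
        out = correction_efficacy(self._report(0, 5), self._report(0, 0))
        assert out["cdr3_error_variant"] is None


class TestFrequencyRecovery:
    def test_identity_is_perfect(self):
        df = spike_frame([("A", "x", "CW", 60, 6, 6), ("B", "y", "CW", 40, 4, 4)])
        rep = frequency_recovery(df, {"A": 0.6, "B": 0.4}, mode="reads")
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mse_pp2 == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # expected (0.25, 0.75), observed (0.35, 0.65):
        # MSE = (10^2 + 10^2)/2 = 100 pp^2; R^2 = 1 - 0.02/0.125 = 0.84
        df = spike_frame([("A", "x", "CW", 35, 35, 35), ("B", "y", "CW", 65, 65, 65)])
        rep = frequency_recovery(df, {"A": 0.25, "B": 0.75}, mode="reads")
        assert rep.mse_pp2 == pytest.approx(100.0)
        assert rep.r_squared == pytest.approx(0.84)

    def test_absent_standard_counted_as_zero(self):
        df = spike_frame([("A", "x", "CW", 10, 1, 1)])
        rep = frequency_recovery(df, {"A": 0.5, "B": 0.5}, mode="rids")
        tab = rep.table.set_index("standard_id")
        assert tab.loc["B", "observed"] == 0.0

    def test_corrected_mode_downweights_overamplified(self):
        # equal RID counts, clone A over-amplified 2x
        df = spike_frame([("A", "x", "CW", 100, 100, 400),
                          ("B", "y", "CW", 100, 100, 200)])
        rep = frequency_recovery(df, {"A": 0.5, "B": 0.5}, mode="corrected")
        tab = rep.table.set_index("standard_id")
        assert tab.loc["A", "observed"] == pytest.approx(1 / 3)
        assert tab.loc["B", "observed"] == pytest.approx(2 / 3)


class TestFeatureSummary:
    def _records(self):
        return pd.DataFrame({
            "v_gene": ["IGHV1-1"] * 4 + ["IGHV4-2"] * 6,
            "junction_aa": ["CARW"] * 4 + ["CARRW"] * 6,
            "shm_count": [0] * 4 + [5] * 6,
            "subclass": ["IgG1"] * 7 + ["ambiguous"] * 3,
        })

    def test_v_family_fractions(self):
        out = feature_summary(self._records(), "v_family_usage")
        by = out.set_index("category")["fraction"]
        assert by["IGHV1"] == pytest.approx(0.4)
        assert by["IGHV4"] == pytest.approx(0.6)

    def test_fractions_sum_to_one_with_ambiguous_category(self):
        out = feature_summary(self._records(), "subclass_usage")
        assert out["fraction"].sum() == pytest.approx(1.0)
        assert "ambiguous" in set(out["category"])

    def test_cdr3_length_distribution(self):
        out = feature_summary(self._records(), "cdr3_length_dist")
        assert out.set_index("category")["count"].to_dict() == {4: 4, 5: 6}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            feature_summary(pd.DataFrame(), "v_family_usage")


class TestClr:
    def test_hand_values(self):
        out = clr_transform([0.25, 0.25, 0.5])
        assert out == pytest.approx([-0.2310, -0.2310, 0.4621], abs=5e-5)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_maps_to_zero(self):
        assert np.allclose(clr_transform([0.2] * 5), 0.0)

    def test_zero_with_pseudocount(self):
        out = clr_transform([0.5, 0.5, 0.0], pseudocount=1e-6)
        assert np.isfinite(out).all()
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clr_transform([0.5, 0.0, 0.5])


class TestLda:
    def _clouds(self, seed=0, n=20, sep=4.0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(0, 1, (n, 5))
        X1 = rng.normal(0, 1, (n, 5))
        X1[:, 2] += sep  # planted discriminating component
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        groups = np.tile([0, 1, 2, 3], n // 2)
        return X, y, groups

    def test_separable_clouds_perfect_holdout(self):
        X, y, groups = self._clouds()
        res = lda_axis(X, y, groups=groups)
        assert res.holdout_accuracy == 1.0

    def test_planted_component_dominates_loadings(self):
        X, y, _ = self._clouds(seed=3)
        res = lda_axis(X, y)
        assert np.abs(res.loadings).argmax() == 2

    def test_permuted_labels_near_chance(self):
        X, y, groups = self._clouds(seed=5)
        rng = np.random.default_rng(7)
        yp = rng.permutation(y)
        res = lda_axis(X, yp, groups=groups)
        n = len(y)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5) / n
        assert lo <= res.holdout_accuracy <= hi

    def test_degenerate_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            lda_axis(X, [0, 0, 1])


class TestFisherExact:
    def test_known_value(self):
        # margins (2,2)/(2,2): table probs 1/6, 4/6, 1/6 -> two-sided p = 1/3
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_symmetry(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(
            fisher_exact_2x2([[5, 0], [0, 5]])
        )

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[3, 0], [4, 0]]) == 1.0

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)).filter(
        lambda t: 0 < sum(t) <= 40))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_exact_enumeration(table), abs=1e-9
        )
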