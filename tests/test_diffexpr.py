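import numpy as np
import pytest
from scipy import stats

from lncarray import diffexpr, synthetic_data as sd
from lncarray.diffexpr import (
    bh_fdr,
    fold_change,
    normalize_quantile,
    screen,
    t_test_unpaired,
    top_table,
)
from lncarray.iofmt import ExpressionMatrix


def make_matrix(values, n_case, n_ctrl, probe_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        probe_ids,
        [f"s{i}" for i in range(n_case + n_ctrl)],
        ["case"] * n_case + ["control"] * n_ctrl,
        values,
    )


def brute_force_bh(p):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = running
    return adjusted


class TestNormalizeQuantile:
    def test_hand_example(self):
        # columns [1,3] and [2,6]; sorted means are [1.5, 4.5]
        m = make_matrix([[1, 2], [3, 6]], 1, 1)
        out = normalize_quantile(m)
        np.testing.assert_allclose(out.values, [[1.5, 1.5], [4.5, 4.5]])

    def test_permutation_fixed_point(self, rng):
        base = rng.uniform(1, 100, size=10)
        cols = np.stack([rng.permutation(base) for _ in range(4)], axis=1)
        m = make_matrix(cols, 2, 2)
        out = normalize_quantile(m)
        for j in range(4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), np.sort(base))

    def test_column_means_equal(self, rng):
        m = make_matrix(rng.uniform(1, 50, size=(30, 6)), 3, 3)
        out = normalize_quantile(m)
        means = out.values.mean(axis=0)
        np.testing.assert_allclose(means, means[0])

    def test_tie_handling_mean_of_targets(self):
        # column with a tie gets the mean of the tied reference values
        m = make_matrix([[5, 1], [5, 2], [9, 3]], 1, 1)
        out = normalize_quantile(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        expected_tied = 0.5 * (ref[0] + ref[1])
        np.testing.assert_allclose(out.values[:2, 0], expected_tied)


class TestTTest:
    def test_identical_groups(self):
        m = make_matrix([[4, 4, 4, 4, 4, 4]], 3, 3)
        t, df, p = t_test_unpaired(m, "P0")
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_matches_brute_force_pooled_formula(self):
        a = np.array([2.0, 3.5, 4.1])
        b = np.array([1.0, 1.4, 0.9])
        m = make_matrix(np.exp2([np.concatenate([a, b])]), 3, 3)
        t, df, p = t_test_unpaired(m, "P0")
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_expect, rel=1e-12)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expect), 4), rel=1e-12)

    def test_published_dbp_summary_reproduced(self):
        # the summary-statistics route shares this kernel
        from lncarray.clinical_stats import GroupSummary, t_test_from_summary

        _, _, p = t_test_from_summary(
            GroupSummary(90.20, 8.67, 5), GroupSummary(63.67, 8.39, 3)
        )
        assert round(p, 3) == 0.005

    def test_zero_variance_unequal_means(self):
        m = make_matrix([[8, 8, 2, 2]], 2, 2)
        t, _, p = t_test_unpaired(m, "P0")
        assert np.isinf(t) and p == 0.0


class TestFoldChange:
    def test_up(self):
        m = make_matrix([[8, 8, 2, 2]], 2, 2)
        assert fold_change(m, "P0") == (4.0, "Up")

    def test_down_reciprocal(self):
        m = make_matrix([[2, 2, 8, 8]], 2, 2)
        assert fold_change(m, "P0") == (4.0, "Down")

    def test_tie_goes_up(self):
        m = make_matrix([[3, 3, 3, 3]], 2, 2)
        assert fold_change(m, "P0") == (1.0, "Up")

    def test_label_swap_antisymmetry(self, rng):
        values = rng.uniform(1, 100, size=(20, 8))
        m = make_matrix(values, 5, 3)
        swapped = ExpressionMatrix(
            list(m.probe_ids),
            list(m.sample_ids),
            ["control"] * 5 + ["case"] * 3,
            values,
        )
        for p in m.probe_ids:
            fc1, reg1 = fold_change(m, p)
            fc2, reg2 = fold_change(swapped, p)
            assert fc1 == pytest.approx(fc2, rel=1e-12)
            if fc1 != 1.0:
                assert {reg1, reg2} == {"Up", "Down"}


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_constant_vector(self):
        np.testing.assert_allclose(bh_fdr([0.5] * 10), [0.5] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            np.testing.assert_array_equal(bh_fdr(p), brute_force_bh(list(p)))


class TestScreen:
    def _annotated(self, matrix, seed=0):
        return sd.annotation_for(matrix, seed=seed)

    def test_boundary_fc_excluded(self):
        # noiseless probe at exactly FC = 2 with a tiny-P neighbour
        values = np.exp2(
            np.array(
                [
                    [3.0, 3.0, 3.001, 2.999, 3.0, 2.0, 2.001, 1.999],
                    [9.0, 9.0, 9.001, 8.999, 9.0, 2.0, 2.001, 1.999],
                ]
            )
        )
        m = ExpressionMatrix(
            ["LNC000000", "LNC000001"],
            [f"s{i}" for i in range(8)],
            ["case"] * 5 + ["control"] * 3,
            values,
        )
        up, down = screen(m, self._annotated(m))
        names = set(up["probe_name"]) | set(down["probe_name"])
        fc0, _ = fold_change(m, "LNC000000")
        assert fc0 < 2.0000001  # near the boundary by construction
        assert "LNC000001" in names

    def test_exact_boundary_strict(self):
        values = np.array([[4.0, 4.0, 4.0, 2.0, 2.0]])
        m = ExpressionMatrix(
            ["LNC000000"], [f"s{i}" for i in range(5)],
            ["case"] * 3 + ["control"] * 2, values,
        )
        fc, _ = fold_change(m, "LNC000000")
        assert fc == 2.0
        up, down = screen(m, self._annotated(m))
        assert len(up) == 0 and len(down) == 0

    def test_planted_probe_recovered_up(self):
        m, truth = sd.simulate_expression(
            1, n_lnc=20, n_mrna=20, frac_de=0.1, fc_log2_range=(2.0, 2.0), sigma_log2=0.0
        )
        up, down = screen(m, self._annotated(m))
        found = set(up["probe_name"]) | set(down["probe_name"])
        for probe, (direction, _) in truth.de_probes.items():
            assert probe in found
            table = up if direction == "Up" else down
            assert probe in set(table["probe_name"])

    def test_unannotated_probe_error(self, tiny_matrix):
        m, _ = sd.simulate_expression(1, n_lnc=5, n_mrna=5)
        ann = sd.annotation_for(m)
        ann.table = ann.table.iloc[:-1]
        with pytest.raises(Exception, match="unannotated"):
            screen(m, sd.annotation_for(m).__class__(ann.table))

    def test_null_false_positive_rate_sane(self):
        m, _ = sd.simulate_expression(13, n_lnc=700, n_mrna=300, frac_de=0.0)
        up, down = screen(m, self._annotated(m))
        n_hits = len(up) + len(down)
        # gate requires both P < 0.05 and FC > 2: hits are at most the raw
        # P rejections, bounded by binomial(1000, 0.05) + 5 sigma
        assert n_hits <= 0.05 * 1000 + 5 * np.sqrt(1000 * 0.05 * 0.95)

    def test_partition_disjoint(self):
        m, _ = sd.simulate_expression(2, n_lnc=100, n_mrna=50)
        up, down = screen(m, self._annotated(m))
        assert not (set(up["probe_name"]) & set(down["probe_name"]))
        assert len(up) + len(down) <= 150


class TestTopTable:
    def _records(self, fcs, ps):
        import pandas as pd

        return pd.DataFrame(
            {
                "seqname": [f"T{i}" for i in range(len(fcs))],
                "probe_name": [f"P{i}" for i in range(len(fcs))],
                "p_value": ps,
                "fdr": ps,
                "fc": fcs,
                "regulation": ["Up"] * len(fcs),
                "chrom": ["chr1"] * len(fcs),
                "strand": ["+"] * len(fcs),
            }
        )

    def test_fc_descending(self):
        out = top_table(self._records([5, 9, 7], [0.01, 0.01, 0.01]))
        assert list(out["fc"]) == [9, 7, 5]

    def test_p_tie_break(self):
        out = top_table(self._records([5, 5], [0.02, 0.01]))
        assert list(out["p_value"]) == [0.01, 0.02]

    def test_k_larger_than_list(self):
        out = top_table(self._records([5, 6], [0.01, 0.01]), k=100)
        assert len(out) == 2

    def test_k_nonpositive(self):
        with pytest.raises(ValueError):
            top_table(self._records([5], [0.1]), k=0)
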