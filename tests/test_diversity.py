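"""Alpha/beta diversity: closed-form examples, invariants, and a cross-check
of the in-package PERMANOVA against the scikit-bio implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myconet as mc
from myconet.containers import AsvTable


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, tiny_table):
        depth = int(tiny_table.sample_sums().min())
        out = mc.rarefy(tiny_table, depth=depth, seed=0)
        kept = out.counts[out.sample_ids]
        assert (kept.sum(axis=0) == depth).all()

    def test_single_taxon_column_has_one_outcome(self):
        t = AsvTable(pd.DataFrame({"s1": [10, 0, 0], "s2": [8, 8, 8]}, index=list("abc")))
        out = mc.rarefy(t, depth=5, seed=0)
        assert out.counts["s1"].tolist() == [5, 0, 0]

    def test_auto_depth_equals_minimum_column_sum(self, standard_dataset):
        _, table, *_ = standard_dataset
        noisy = AsvTable(table.counts.iloc[:, :6].copy())
        noisy.counts.iloc[0, 0] -= 100  # make depths unequal
        out = mc.rarefy(AsvTable(noisy.counts), depth="auto", seed=1)
        assert (out.sample_sums() == noisy.sample_sums().min()).all()

    def test_shallow_samples_dropped_not_silent(self, caplog):
        t = AsvTable(pd.DataFrame({"s1": [100], "s2": [3]}, index=["a"]))
        with caplog.at_level("WARNING", logger="myconet"):
            out = mc.rarefy(t, depth=10, seed=0)
        assert out.sample_ids == ["s1"]
        assert any("dropping" in r.message for r in caplog.records)

    def test_reproducible_from_seed(self, standard_dataset):
        _, table, *_ = standard_dataset
        a = mc.rarefy(table, depth=5000, seed=9)
        b = mc.rarefy(table, depth=5000, seed=9)
        assert a.counts.equals(b.counts)


class TestAlpha:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ((5, 5, 5), 3.0),            # no singletons -> observed richness
            ((1, 1, 2, 0), 3.5),         # 3 + 2*1/(2*(1+1))
            ((0, 0, 0), 0.0),
            ((1, 0, 0), 1.0),            # F1=1 -> correction term vanishes
        ],
    )
    def test_chao1_closed_forms(self, column, expected):
        assert mc.chao1(np.array(column)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "column,expected",
        [
            ((7, 0, 0), 0.0),
            ((5, 5), np.log(2)),
            ((1, 1, 1, 1), np.log(4)),
        ],
    )
    def test_shannon_closed_forms(self, column, expected):
        assert mc.shannon(np.array(column)) == pytest.approx(expected)

    def test_shannon_rejects_zero_sum(self):
        with pytest.raises(mc.ValidationError):
            mc.shannon(np.zeros(3))

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_alpha_inequalities(self, column):
        col = np.array(column)
        if col.sum() == 0:
            assert mc.chao1(col) == 0
            return
        richness = int((col > 0).sum())
        assert mc.chao1(col) >= richness
        assert mc.shannon(col) <= np.log(max(richness, 1)) + 1e-12


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = AsvTable(pd.DataFrame({"a": [1, 2], "b": [1, 2]}, index=["x", "y"]))
        assert mc.bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_columns_one(self):
        t = AsvTable(pd.DataFrame({"a": [3, 0], "b": [0, 7]}, index=["x", "y"]))
        assert mc.bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = AsvTable(pd.DataFrame({"a": [1, 2], "b": [2, 1]}, index=["x", "y"]))
        assert mc.bray_curtis(t)["a", "b"] == pytest.approx(1 / 3)

    def test_entries_in_unit_interval(self, standard_dataset):
        _, table, *_ = standard_dataset
        dm = mc.bray_curtis(table)
        assert dm.data.min() >= 0 and dm.data.max() <= 1


class TestPcoa:
    def test_equilateral_points_have_equal_eigenvalues(self):
        from skbio.stats.distance import DistanceMatrix

        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc"))
        _, evals, _ = mc.pcoa(d, k=2)
        assert evals[0] == pytest.approx(evals[1])

    def test_collinear_points_single_axis(self):
        from skbio.stats.distance import DistanceMatrix

        pts = np.array([0.0, 1.0, 2.0, 3.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abcd"))
        _, evals, prop = mc.pcoa(d, k=3)
        assert prop[0] == pytest.approx(1.0)

    def test_stress_decreases_with_more_axes(self, standard_dataset):
        _, table, *_ = standard_dataset
        sub = AsvTable(table.counts.iloc[:, :6].copy())
        dm = mc.bray_curtis(sub)
        errs = []
        for k in (1, 2, 3, 4, 5):
            coords, *_ = mc.pcoa(dm, k=k)
            x = coords.to_numpy()
            approx = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            errs.append(np.abs(approx - dm.data).sum())
        assert all(errs[i] >= errs[i + 1] - 1e-9 for i in range(len(errs) - 1))

    def test_matches_skbio_proportions(self, standard_dataset):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        _, table, *_ = standard_dataset
        dm = mc.bray_curtis(AsvTable(table.counts.iloc[:, :8].copy()))
        _, _, prop = mc.pcoa(dm, k=3)
        ref = skbio_pcoa(dm)
        assert prop[:3] == pytest.approx(ref.proportion_explained.to_numpy()[:3], abs=1e-6)

    def test_non_symmetric_rejected(self):
        from skbio.stats.distance import DistanceMatrixError

        with pytest.raises((mc.ValidationError, DistanceMatrixError)):
            from skbio.stats.distance import DistanceMatrix

            DistanceMatrix(np.array([[0, 1], [2, 0]], float), ids=list("ab"))


class TestPermanova:
    def _separated(self):
        from skbio.stats.distance import DistanceMatrix

        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        meta = pd.DataFrame(
            {"sample_id": list("abcdef"), "treatment": ["g1"] * 3 + ["g2"] * 3}
        )
        return DistanceMatrix(d, ids=list("abcdef")), meta

    def test_perfect_separation_small_p(self):
        """Two internally identical, fully separated groups: every
        non-partition-preserving permutation scores lower, so p approaches
        the fraction of label permutations preserving the split (72/720 for
        3+3, since ties at F = inf are counted by the >= rule)."""
        dm, meta = self._separated()
        _, p = mc.permanova(dm, meta, n_perm=199, seed=0)
        assert 1 / 200 <= p <= 0.15

    def test_sample_order_invariance(self, standard_dataset):
        _, table, _, metadata, _ = standard_dataset
        cols = list(range(0, 6)) + list(range(15, 21))  # six CK + six CF
        sub = AsvTable(table.counts.iloc[:, cols].copy())
        meta = metadata[metadata["sample_id"].isin(sub.sample_ids)].reset_index(drop=True)
        dm = mc.bray_curtis(sub)
        f1, _ = mc.permanova(dm, meta, n_perm=9, seed=0)
        shuffled = AsvTable(sub.counts.iloc[:, ::-1].copy())
        dm2 = mc.bray_curtis(shuffled)
        f2, _ = mc.permanova(dm2, meta.iloc[::-1].reset_index(drop=True), n_perm=9, seed=0)
        assert f1 == pytest.approx(f2)

    def test_single_sample_group_rejected(self):
        dm, meta = self._separated()
        meta.loc[5, "treatment"] = "g3"
        with pytest.raises(mc.ValidationError, match="fewer than 2"):
            mc.permanova(dm, meta, n_perm=9, seed=0)

    def test_pseudo_f_matches_skbio(self, standard_dataset):
        """Independent oracle: skbio's permanova statistic on the same data."""
        from skbio.stats.distance import permanova as skbio_permanova

        _, table, _, metadata, _ = standard_dataset
        sub = AsvTable(table.counts.iloc[:, list(range(0, 6)) + list(range(15, 21))].copy())
        meta = metadata[metadata["sample_id"].isin(sub.sample_ids)].reset_index(drop=True)
        dm = mc.bray_curtis(sub)
        f_ours, _ = mc.permanova(dm, meta, n_perm=9, seed=0)
        grouping = meta.set_index("sample_id").loc[list(dm.ids), "treatment"]
        res = skbio_permanova(dm, grouping.to_numpy(), permutations=9)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-9)
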