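"""RPM, expression filter, worst-case fold change, PCA, Fisher, ΔΔCt."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from socialphys import (delta_delta_ct, filter_expressed, fisher_enrichment,
                        intersect_de, pca_transform, rpm_normalize,
                        worst_case_fc)


def _rpm(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestRpm:
    def test_simple_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 10**6 - 10]}, index=["g1", "g2"])
        rpm = rpm_normalize(counts)
        assert rpm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (50, 6)))
        np.testing.assert_allclose(rpm_normalize(counts).sum(axis=0), 1e6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)))
        rpm = rpm_normalize(counts)
        for g, s in product(range(20), range(4)):
            assert rpm.iloc[g, s] == pytest.approx(
                counts.iloc[g, s] / counts.iloc[:, s].sum() * 1e6)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"ok": [5, 5], "empty": [0, 0]})
        with pytest.raises(ValueError, match="zero-total"):
            rpm_normalize(counts)


class TestFilterExpressed:
    def test_boundary_exactly_10_removed(self):
        rpm = _rpm({"g": [10.0, 10.0, 10.0]})
        assert len(filter_expressed(rpm)) == 0  # strict >

    def test_11_rpm_kept(self):
        rpm = _rpm({"g": [11.0, 11.0]})
        assert list(filter_expressed(rpm).index) == ["g"]

    def test_rule_semantics(self):
        rpm = _rpm({"g": [5.0, 15.0]})
        assert len(filter_expressed(rpm, rule="all")) == 0
        assert len(filter_expressed(rpm, rule="any")) == 1
        assert len(filter_expressed(rpm, rule="mean")) == 0  # mean 10, strict


class TestWorstCaseFc:
    def _run(self, a_vals, b_vals, **kw):
        rpm = pd.DataFrame([a_vals + b_vals], index=["g"],
                           columns=["a1", "a2", "b1", "b2"])
        return worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"], **kw)

    def test_printed_selected_example(self):
        """A = {10, 12}, B = {20, 30}: all four pair ratios exceed 1; the
        least favourable pair is 20/12 = 1.667, above the 1.5 threshold."""
        res = self._run([10.0, 12.0], [20.0, 30.0])
        row = res.table.loc["g"]
        assert row.wcfc == pytest.approx(20.0 / 12.0)
        assert row.direction == "up" and row.selected
        assert row.pair == "a2|b1"

    def test_printed_rejected_example(self):
        """A = {10, 12}, B = {14, 30}: worst pair 14/12 = 1.167 < 1.5."""
        res = self._run([10.0, 12.0], [14.0, 30.0])
        row = res.table.loc["g"]
        assert row.wcfc == pytest.approx(14.0 / 12.0)
        assert not row.selected

    def test_constant_gene_not_selected(self):
        res = self._run([7.0, 7.0], [7.0, 7.0])
        assert res.table.loc["g", "wcfc"] == 1.0
        assert not res.table.loc["g", "selected"]

    def test_discordant_direction_never_selected(self):
        res = self._run([10.0, 10.0], [5.0, 40.0])  # down and up pairs
        row = res.table.loc["g"]
        assert row.direction == "discordant" and not row.selected

    def test_group_swap_flips_direction_keeps_magnitude(self):
        rpm = pd.DataFrame([[10.0, 12.0, 20.0, 30.0]], index=["g"],
                           columns=["a1", "a2", "b1", "b2"])
        ab = worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"])
        ba = worst_case_fc(rpm, ["b1", "b2"], ["a1", "a2"])
        assert ab.table.loc["g", "wcfc"] == pytest.approx(
            ba.table.loc["g", "wcfc"])
        assert {ab.table.loc["g", "direction"],
                ba.table.loc["g", "direction"]} == {"up", "down"}

    def test_extra_replicate_never_increases_wcfc(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(10, 100, (30, 5))
        rpm = pd.DataFrame(vals, columns=["a1", "a2", "a3", "b1", "b2"])
        small = worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"])
        big = worst_case_fc(rpm, ["a1", "a2", "a3"], ["b1", "b2"])
        assert (big.table.wcfc <= small.table.wcfc + 1e-12).all()

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rpm = pd.DataFrame(rng.uniform(10, 100, (100, 4)),
                           columns=["a1", "a2", "b1", "b2"])
        loose = worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"], threshold=1.2)
        tight = worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"], threshold=1.8)
        assert set(tight.selected) <= set(loose.selected)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1.0, 1000.0), min_size=4, max_size=4))
    def test_wcfc_at_least_one_and_matches_enumeration(self, vals):
        rpm = pd.DataFrame([vals], index=["g"],
                           columns=["a1", "a2", "b1", "b2"])
        res = worst_case_fc(rpm, ["a1", "a2"], ["b1", "b2"])
        ratios = [b / a for a in vals[:2] for b in vals[2:]]
        concordant = all(r > 1 for r in ratios) or all(r < 1 for r in ratios)
        expected = min(max(r, 1 / r) for r in ratios) if concordant else 1.0
        assert res.table.loc["g", "wcfc"] >= 1.0
        assert res.table.loc["g", "wcfc"] == pytest.approx(expected)

    def test_singleton_group_rejected(self):
        rpm = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a1", "b1", "b2"])
        with pytest.raises(ValueError, match="replicates"):
            worst_case_fc(rpm, ["a1"], ["b1", "b2"])


class TestIntersect:
    def _result(self, genes, selected):
        import socialphys.transcripts as tx
        tbl = pd.DataFrame({"wcfc": 2.0, "direction": "up",
                            "selected": [g in selected for g in genes],
                            "pair": ""}, index=genes)
        return tx.WcfcResult(table=tbl, threshold=1.5, group_a=[], group_b=[])

    def test_identical_selections_share_all(self):
        genes = ["g1", "g2", "g3"]
        out = intersect_de({"p1": self._result(genes, {"g1", "g2"}),
                            "p2": self._result(genes, {"g1", "g2"})})
        assert out["shared"] == {"g1", "g2"}
        assert out["union"] == {"g1", "g2"}
        assert all(out["direction_agrees"].values())

    def test_disjoint_selections_share_nothing(self):
        genes = ["g1", "g2", "g3", "g4"]
        out = intersect_de({"p1": self._result(genes, {"g1"}),
                            "p2": self._result(genes, {"g2"})})
        assert out["shared"] == set()
        assert out["unique"]["p1"] == {"g1"}

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        s1 = set(rng.choice(genes, 20, replace=False))
        s2 = set(rng.choice(genes, 20, replace=False))
        out = intersect_de({"p1": self._result(genes, s1),
                            "p2": self._result(genes, s2)})
        assert out["shared"] == s1 & s2
        assert out["union"] == s1 | s2


class TestPca:
    def test_two_groups_separate_on_pc1(self):
        a = np.tile([[100.0], [10.0], [50.0]], (1, 3))
        b = np.tile([[10.0], [100.0], [50.0]], (1, 3))
        rpm = pd.DataFrame(np.hstack([a, b]),
                           columns=[f"s{i}" for i in range(6)])
        out = pca_transform(rpm)
        pc1 = out["scores"]["PC1"]
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)
        assert np.sign(pc1[:3]).nunique() == 1
        assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:]))

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        rpm = pd.DataFrame(rng.uniform(1, 100, (40, 8)))
        out = pca_transform(rpm)
        assert out["explained_variance_ratio"].sum() == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        rpm = pd.DataFrame(np.full((5, 4), 3.0))
        with pytest.raises(ValueError, match="degenerate"):
            pca_transform(rpm)


def _hypergeom_tail(k, n_sel, n_ann, n_universe):
    """Brute-force one-sided Fisher p: P(overlap >= k) by enumeration."""
    total = comb(n_universe, n_sel, exact=True)
    p = 0
    for x in range(k, min(n_sel, n_ann) + 1):
        p += comb(n_ann, x, exact=True) * \
            comb(n_universe - n_ann, n_sel - x, exact=True)
    return p / total


class TestFisher:
    def test_symmetric_table(self):
        universe = {f"g{i}" for i in range(40)}
        selected = {f"g{i}" for i in range(20)}
        annotation = {f"g{i}" for i in range(10, 30)}
        res = fisher_enrichment(selected, annotation, universe)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(_hypergeom_tail(10, 20, 20, 40))
        two = fisher_enrichment(selected, annotation, universe,
                                alternative="two-sided")
        assert two.p_value == pytest.approx(1.0)

    def test_selection_inside_universe_wide_annotation(self):
        universe = {f"g{i}" for i in range(30)}
        res = fisher_enrichment({"g1", "g2"}, universe, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration_small_margins(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(25)]
        for _ in range(20):
            ns, na = rng.integers(2, 15, 2)
            sel = set(rng.choice(genes, ns, replace=False))
            ann = set(rng.choice(genes, na, replace=False))
            res = fisher_enrichment(sel, ann, set(genes))
            k = len(sel & ann)
            assert res.p_value == pytest.approx(
                _hypergeom_tail(k, ns, na, 25), abs=1e-12)

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subsets"):
            fisher_enrichment({"x"}, {"g1"}, {"g1", "g2"})


class TestDeltaDeltaCt:
    def _ct(self):
        return pd.DataFrame({
            "group": ["ctrl", "ctrl", "treat", "treat"],
            "target": [24.0, 25.0, 23.0, 22.5],
            "ref": [18.0, 19.0, 18.0, 18.0],
        })

    def test_control_at_mean_is_one(self):
        ct = pd.DataFrame({"group": ["ctrl"] * 3,
                           "target": [24.0, 24.0, 24.0],
                           "ref": [18.0, 18.0, 18.0]})
        out = delta_delta_ct(ct, "target", "ref", "group", "ctrl")
        np.testing.assert_allclose(out["rel_expression"], 1.0)

    def test_one_cycle_doubling(self):
        ct = self._ct()
        out = delta_delta_ct(ct, "target", "ref", "group", "ctrl")
        # ctrl ΔCt = {6, 6} → mean 6; sample with ΔCt 5 → ΔΔCt −1 → 2×
        assert out.loc[2, "rel_expression"] == pytest.approx(2.0)

    def test_matches_spreadsheet_recomputation(self):
        rng = np.random.default_rng(7)
        ct = pd.DataFrame({"group": ["ctrl"] * 3 + ["treat"] * 3,
                           "target": rng.uniform(20, 30, 6),
                           "ref": rng.uniform(15, 20, 6)})
        out = delta_delta_ct(ct, "target", "ref", "group", "ctrl")
        dct = ct["target"] - ct["ref"]
        ddct = dct - dct[:3].mean()
        np.testing.assert_allclose(out["rel_expression"], 2.0 ** (-ddct))

    def test_missing_reference_is_error(self):
        with pytest.raises(ValueError, match="missing column"):
            delta_delta_ct(self._ct(), "target", "nope", "group", "ctrl")
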