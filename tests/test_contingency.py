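"""Contingency/enrichment machinery: published-table arithmetic, an
independent chi-squared oracle, permutation calibration, set overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from dyeswap.contingency import (
    CLASS_ORDER,
    build_contingency,
    contingency_from_counts,
    enrichment_report,
    format_ratio,
    set_overlap,
    triple_overlap,
    venn_counts,
)
from dyeswap.reference_tables import load_reference_counts, reproduce_reference_table


def _vector(rng, n, p_up=0.05, p_down=0.05, prefix="P"):
    cls = rng.choice(["UP", "NC", "DOWN"], size=n, p=[p_up, 1 - p_up - p_down, p_down])
    return pd.Series(cls, index=[f"{prefix}{i:05d}" for i in range(n)])


class TestPublishedTables:
    def test_wortmannin_edelfosine_theoretical_cells(self):
        res = reproduce_reference_table("w30_edelfosine")
        theo = res.analysis.theoretical
        assert theo.loc["UP", "UP"] == pytest.approx(21.83, abs=0.005)
        assert theo.loc["UP", "NC"] == pytest.approx(1251.05, abs=0.005)
        assert theo.loc["DOWN", "UP"] == pytest.approx(27.30, abs=0.005)
        assert theo.loc["UP", "DOWN"] == pytest.approx(27.12, abs=0.005)
        assert theo.loc["DOWN", "DOWN"] == pytest.approx(33.93, abs=0.005)
        assert theo.loc["NC", "UP"] == pytest.approx(362.87, abs=0.005)
        assert theo.loc["NC", "DOWN"] == pytest.approx(450.95, abs=0.005)
        assert theo.loc["DOWN", "NC"] == pytest.approx(1564.77, abs=0.005)
        assert res.analysis.p < 2.2e-16
        assert res.analysis.p_string == "< 2.2e-16"

    def test_ratio_display_convention(self):
        res = reproduce_reference_table("w30_edelfosine")
        assert format_ratio(res.analysis.ratio.loc["UP", "UP"]) == "10.5"
        res1 = reproduce_reference_table("edelfosine_u73122")
        assert format_ratio(res1.analysis.ratio.loc["UP", "DOWN"]) == "0"

    def test_butanol_tables(self):
        a = reproduce_reference_table("nbutoh_edelfosine").analysis
        assert a.theoretical.loc["UP", "UP"] == pytest.approx(21.59, abs=0.005)
        assert format_ratio(a.ratio.loc["DOWN", "DOWN"]) == "5.81"
        b = reproduce_reference_table("nbutoh_r59022").analysis
        assert b.theoretical.loc["UP", "UP"] == pytest.approx(9.53, abs=0.005)
        assert format_ratio(b.ratio.loc["UP", "UP"]) == "3.88"
        assert format_ratio(b.ratio.loc["DOWN", "DOWN"]) == "6.45"

    def test_report_renders_observed_theoretical_ratio_layout(self):
        res = reproduce_reference_table("w30_edelfosine")
        text = enrichment_report(res.analysis)
        assert "Observed (Theoretical) ratio" in text
        assert "(21.83)" in text and "10.5" in text
        assert "< 2.2e-16" in text


class TestContingency:
    def test_exact_independence_yields_unit_ratios(self):
        rows = np.array([100.0, 800, 100])
        cols = np.array([50.0, 900, 50])
        obs = pd.DataFrame(np.outer(rows, cols) / 1000, index=CLASS_ORDER, columns=CLASS_ORDER)
        a = contingency_from_counts(obs)
        assert np.allclose(a.ratio, 1.0)
        assert a.chi2 == pytest.approx(0.0, abs=1e-12)
        assert a.p == pytest.approx(1.0)

    def test_chi2_and_p_match_numerical_oracle(self):
        rng = np.random.default_rng(5)
        obs = pd.DataFrame(
            rng.multinomial(200, np.full(9, 1 / 9)).reshape(3, 3).astype(float),
            index=CLASS_ORDER, columns=CLASS_ORDER,
        )
        a = contingency_from_counts(obs)
        # brute-force cell enumeration
        n = obs.to_numpy().sum()
        chi2 = 0.0
        for i, j in itertools.product(range(3), range(3)):
            e = obs.to_numpy()[i].sum() * obs.to_numpy()[:, j].sum() / n
            chi2 += (obs.to_numpy()[i, j] - e) ** 2 / e
        assert a.chi2 == pytest.approx(chi2, rel=1e-12)
        # p by numerical integration of the chi-squared density, df 4
        p_num, _ = quad(lambda x: stats.chi2.pdf(x, 4), chi2, np.inf)
        assert a.p == pytest.approx(p_num, rel=1e-8)
        # and against the standard library implementation
        sp = stats.chi2_contingency(obs.to_numpy(), correction=False)
        assert a.chi2 == pytest.approx(sp.statistic, rel=1e-12)
        assert a.p == pytest.approx(sp.pvalue, rel=1e-10)
        assert a.df == 4

    def test_symmetry_under_transposition(self):
        rng = np.random.default_rng(6)
        v1, v2 = _vector(rng, 3000), _vector(rng, 3000)
        assert build_contingency(v1, v2).chi2 == pytest.approx(build_contingency(v2, v1).chi2)

    def test_restriction_to_common_probes(self):
        rng = np.random.default_rng(7)
        v1 = _vector(rng, 1000)
        v2 = _vector(rng, 1000).iloc[200:]
        a = build_contingency(v1, v2)
        assert a.n_common == 800
        assert a.observed.to_numpy().sum() == 800

    def test_zero_marginal_reduces_df(self):
        rng = np.random.default_rng(8)
        v1 = _vector(rng, 2000)
        v2 = _vector(rng, 2000, p_down=0.0)  # no DOWN calls at all
        a = build_contingency(v1, v2)
        assert a.degenerate
        assert a.df == 2 * 1
        assert a.ratio.loc[:, "DOWN"].isna().all()

    def test_empty_intersection_and_duplicates_rejected(self):
        rng = np.random.default_rng(9)
        v1 = _vector(rng, 50, prefix="A")
        v2 = _vector(rng, 50, prefix="B")
        with pytest.raises(ValueError):
            build_contingency(v1, v2)
        dup = pd.concat([v1, v1])
        with pytest.raises(ValueError):
            build_contingency(dup, v1)

    @given(st.integers(min_value=1, max_value=5))
    @settings(deadline=None, max_examples=5)
    def test_ratios_invariant_under_duplication(self, mult):
        rng = np.random.default_rng(10)
        obs = pd.DataFrame(
            rng.multinomial(500, np.full(9, 1 / 9)).reshape(3, 3).astype(float),
            index=CLASS_ORDER, columns=CLASS_ORDER,
        )
        a = contingency_from_counts(obs)
        b = contingency_from_counts(obs * mult)
        pd.testing.assert_frame_equal(a.ratio, b.ratio)

    def test_permutation_null_p_values_are_uniform(self):
        rng = np.random.default_rng(11)
        v1 = _vector(rng, 5000)
        v2 = _vector(rng, 5000)
        ps = []
        for _ in range(500):
            shuffled = pd.Series(rng.permutation(v2.to_numpy()), index=v2.index)
            ps.append(build_contingency(v1, shuffled).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestTripleOverlap:
    def test_identical_vectors_perfect_dependence(self):
        rng = np.random.default_rng(12)
        v = _vector(rng, 1000, p_up=0.1, p_down=0.0)
        v[:] = np.where(np.arange(1000) < 100, "UP", "NC")  # exactly 10% UP
        res = triple_overlap(v, v, v)
        cell = res.cell("UP", "UP", "UP")
        assert cell["observed"] == 100
        assert cell["expected"] == pytest.approx(1.0)
        assert res.table["expected"].sum() == pytest.approx(1000.0)

    def test_shuffled_vectors_match_independence(self):
        rng = np.random.default_rng(13)
        v = _vector(rng, 4000, p_up=0.1, p_down=0.1)
        devs = []
        for _ in range(20):
            vs = [pd.Series(rng.permutation(v.to_numpy()), index=v.index) for _ in range(3)]
            res = triple_overlap(*vs)
            cell = res.cell("UP", "UP", "UP")
            devs.append(cell["observed"] - cell["expected"])
        expected = res.cell("UP", "UP", "UP")["expected"]
        assert abs(np.mean(devs)) <= 3 * np.sqrt(expected)

    def test_observed_equals_direct_joint_recount(self):
        rng = np.random.default_rng(14)
        vs = [_vector(rng, 500, p_up=0.2, p_down=0.2) for _ in range(3)]
        res = triple_overlap(*vs)
        joint = pd.concat(vs, axis=1)
        for _, row in res.table.iterrows():
            direct = (
                (joint.iloc[:, 0] == row["class_1"])
                & (joint.iloc[:, 1] == row["class_2"])
                & (joint.iloc[:, 2] == row["class_3"])
            ).sum()
            assert row["observed"] == direct


class TestVennAndOverlap:
    @staticmethod
    def _from_sets(sets):
        return {
            label: pd.Series("UP", index=sorted(s)) for label, s in sets.items()
        }

    def test_two_set_example(self):
        v = self._from_sets({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        regions = venn_counts(v, "UP")
        assert regions[("A",)] == 1 and regions[("B",)] == 1 and regions[("A", "B")] == 1

    def test_disjoint_sets_have_empty_intersection(self):
        v = self._from_sets({"A": {"g1"}, "B": {"g2"}})
        assert venn_counts(v, "UP")[("A", "B")] == 0

    @given(st.data())
    @settings(deadline=None, max_examples=25)
    def test_three_set_regions_match_set_algebra(self, data):
        universe = [f"g{i}" for i in range(30)]
        sets = {
            k: set(data.draw(st.lists(st.sampled_from(universe), unique=True)))
            for k in "ABC"
        }
        regions = venn_counts(self._from_sets(sets), "UP")
        total = sum(regions.values())
        assert total == len(sets["A"] | sets["B"] | sets["C"])
        assert regions[("A", "B", "C")] == len(sets["A"] & sets["B"] & sets["C"])
        assert regions[("A",)] == len(sets["A"] - sets["B"] - sets["C"])

    def test_more_than_three_sets_unsupported(self):
        v = self._from_sets({k: {"g"} for k in "ABCD"})
        with pytest.raises(ValueError):
            venn_counts(v, "UP")

    def test_identical_lists_overlap_fully(self):
        res = set_overlap(range(10), range(10), 100)
        assert res.overlap == 10
        assert res.expected == pytest.approx(1.0)
        assert res.p_upper < 1e-10

    def test_overlap_mean_matches_hypergeometric_expectation(self):
        rng = np.random.default_rng(15)
        u, na, nb = 500, 60, 80
        overlaps = [
            set_overlap(rng.choice(u, na, replace=False), rng.choice(u, nb, replace=False), u).overlap
            for _ in range(1000)
        ]
        expected = na * nb / u
        sd = np.std(overlaps) / np.sqrt(len(overlaps))
        assert abs(np.mean(overlaps) - expected) <= 3 * sd + 1e-9

    def test_list_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            set_overlap(range(20), range(5), 10)


def test_reference_fixture_counts_are_internally_summed(tmp_path):
    # sanity on the packaged fixture: column sums rebuild the printed marginals
    cells = load_reference_counts("w30_edelfosine")
    obs = cells.pivot(index="row_class", columns="col_class", values="observed")
    assert obs.to_numpy().sum() == 24539
    assert sorted(obs.sum(axis=0).tolist()) == sorted([412, 23615, 512])
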