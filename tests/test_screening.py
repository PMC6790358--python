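"""ANOVA screening, robust correlation and Meta-ID grouping."""
import numpy as np
import pytest

from plantmet.models import Component, ComponentTable
from plantmet.registration import nnc_register
from plantmet.screening import (anova_screen, assign_meta_ids, one_way_anova,
                                robust_pairwise_correlation)

from conftest import gaussian_peak


def anova_oracle(groups):
    """Textbook sums-of-squares one-way ANOVA, written independently."""
    import scipy.stats

    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, scipy.stats.f.sf(f, dfb, dfw)


def make_table(height_rows, samples):
    """ComponentTable from a dense heights matrix (rows = components)."""
    comps = []
    peaks_all = []
    for cid, row in enumerate(height_rows):
        members = {}
        for s, h in zip(samples, row):
            if np.isnan(h):
                continue
            p = gaussian_peak(s, 2.0 + 0.5 * cid, 200 + 10 * cid, height=h,
                              peak_id=len(peaks_all))
            p.height = float(h)
            members[s] = p
            peaks_all.append(p)
        c = Component(cid, members)
        c.recompute_means()
        comps.append(c)
    import pandas as pd

    heights = pd.DataFrame([[c.members[s].height if s in c.members else np.nan
                             for s in samples] for c in comps],
                           index=[c.component_id for c in comps], columns=samples)
    return ComponentTable(components=comps, samples=list(samples),
                          heights=heights, areas=heights.copy())


SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]
GROUPS = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}


class TestAnova:
    def test_no_between_variance(self):
        f, p = one_way_anova([np.array([10.0, 10, 10]), np.array([10.0, 10, 10])])
        assert (f, p) == (0.0, 1.0)

    def test_hand_computed_case(self):
        f, p = one_way_anova([np.array([1.0, 2, 3]), np.array([11.0, 12, 13])])
        assert f == pytest.approx(150.0)
        assert p == pytest.approx(2.552e-4, rel=1e-3)

    def test_matches_oracle_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(0, 5), 1, int(rng.integers(3, 9)))
                      for _ in range(k)]
            f, p = one_way_anova(groups)
            fo, po = anova_oracle(groups)
            assert f == pytest.approx(fo, rel=1e-10)
            assert p == pytest.approx(po, rel=1e-10)

    def test_screen_flags_effect_components(self):
        rng = np.random.default_rng(1)
        hit = 0
        n_rep = 100
        for rep in range(n_rep):
            rows = []
            for _ in range(5):  # 4-fold effect, CV 10%
                base = rng.uniform(1e4, 1e5)
                rows.append(np.r_[base * rng.lognormal(0, 0.1, 3),
                                  4 * base * rng.lognormal(0, 0.1, 3)])
            for _ in range(45):  # nulls
                base = rng.uniform(1e4, 1e5)
                rows.append(base * rng.lognormal(0, 0.1, 6))
            table = make_table(rows, SAMPLES)
            res = {r.component_id: r for r in anova_screen(table, GROUPS, alpha=0.01)}
            if all(res[cid].significant for cid in range(5)):
                hit += 1
        assert hit / n_rep >= 0.95

    def test_untestable_component_excluded(self):
        rows = [[1e4, 2e4, 1.5e4, np.nan, np.nan, np.nan]]
        res = anova_screen(make_table(rows, SAMPLES), GROUPS)
        assert not res[0].testable and not res[0].significant

    def test_type_one_error_rate_null_tables(self):
        rng = np.random.default_rng(2)
        alpha = 0.05
        n_tests = rejected = 0
        for _ in range(200):
            rows = [rng.lognormal(10, 0.3) * rng.lognormal(0, 0.1, 6) for _ in range(10)]
            res = anova_screen(make_table(rows, SAMPLES), GROUPS, alpha=alpha)
            n_tests += len(res)
            rejected += sum(r.significant for r in res)
        rate = rejected / n_tests
        # binomial 99% bounds around alpha
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 2.58 * se + 1e-12

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(3)
        rows = [rng.lognormal(10, 0.3) * rng.lognormal(0, 0.15, 6) for _ in range(40)]
        table = make_table(rows, SAMPLES)
        raw = sum(r.significant for r in anova_screen(table, GROUPS, alpha=0.2))
        bh = sum(r.significant for r in anova_screen(table, GROUPS, alpha=0.2, p_adjust="BH"))
        assert bh <= raw


class TestRobustCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 11)
        assert robust_pairwise_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_outlier_rejected(self):
        x = np.append(np.arange(1.0, 10), 1.0)
        y = np.append(2 * np.arange(1.0, 10), 100.0)
        r = robust_pairwise_correlation(x, y, mcd_support=0.75)
        assert r >= 0.99
        assert np.corrcoef(x, y)[0, 1] < 0.9  # plain Pearson is distorted

    def test_null_rarely_exceeds_half(self):
        rng = np.random.default_rng(4)
        hits = sum(abs(robust_pairwise_correlation(rng.normal(size=20),
                                                   rng.normal(size=20))) >= 0.5
                   for _ in range(200))
        assert hits / 200 <= 0.05

    def test_too_few_points_undefined(self):
        assert robust_pairwise_correlation(np.arange(4.0), np.arange(4.0)) is None

    def test_zero_variance_gives_zero(self):
        assert robust_pairwise_correlation(np.full(8, 3.0), np.arange(8.0)) == 0.0

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, 5, np.nan, 7.0])
        y = 2 * x
        assert robust_pairwise_correlation(x, y) == pytest.approx(1.0)

    def test_stable_under_20pct_gross_outliers(self):
        x = np.arange(1.0, 21)
        y = 3 * x
        r_clean = robust_pairwise_correlation(x, y)
        x2, y2 = x.copy(), y.copy()
        x2[:4] = [1, 2, 3, 4]
        y2[:4] = [500, 400, 300, 200]
        r_out = robust_pairwise_correlation(x2, y2)
        assert abs(r_out - r_clean) < 0.02


class TestMetaIds:
    def _correlated_rows(self, rng, n_rows, base_profile, cv=0.05):
        return [base_profile * rng.lognormal(0, cv, 6) * rng.uniform(0.2, 2)
                for _ in range(n_rows)]

    def test_coeluting_correlated_components_group(self):
        rng = np.random.default_rng(5)
        prof = np.array([1, 1.2, 0.9, 4, 4.4, 3.8]) * 1e4
        rows = self._correlated_rows(rng, 3, prof)
        table = make_table(rows, SAMPLES)
        for c in table.components:  # force co-elution
            c.mean_rt = 2.0
        res = anova_screen(table, GROUPS, alpha=0.05)
        metas = assign_meta_ids(res, table, corr_threshold=0.9)
        assert len(metas) == 1
        assert sorted(metas[0].member_component_ids) == [0, 1, 2]

    def test_transitive_closure_groups_weak_pair(self):
        # connected-component rule: A-B and B-C edges pull in A-C
        import networkx as nx

        G = nx.Graph()
        G.add_edges_from([("A", "B"), ("B", "C")])
        comps = list(nx.connected_components(G))
        assert len(comps) == 1  # documents the rule assign_meta_ids relies on

    def test_rt_gate_separates_distant_correlated_components(self):
        rng = np.random.default_rng(6)
        prof = np.array([1, 1.1, 0.95, 4, 4.2, 3.9]) * 1e4
        rows = self._correlated_rows(rng, 2, prof)
        table = make_table(rows, SAMPLES)
        table.components[0].mean_rt = 2.29
        table.components[1].mean_rt = 8.50
        res = anova_screen(table, GROUPS, alpha=0.05)
        metas = assign_meta_ids(res, table, corr_threshold=0.9)
        assert len(metas) == 2

    def test_meta_ids_ordered_by_rt(self):
        rng = np.random.default_rng(7)
        prof = np.array([1, 1.1, 0.95, 4, 4.2, 3.9]) * 1e4
        rows = self._correlated_rows(rng, 4, prof)
        table = make_table(rows, SAMPLES)
        rts = [8.0, 8.02, 1.5, 1.52]
        for c, rt in zip(table.components, rts):
            c.mean_rt = rt
        res = anova_screen(table, GROUPS, alpha=0.05)
        metas = assign_meta_ids(res, table, corr_threshold=0.9)
        assert len(metas) == 2
        assert sorted(metas[0].member_component_ids) == [2, 3]  # early rt first
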