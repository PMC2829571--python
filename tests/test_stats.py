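"""Statistical-stage tests: median aggregation, Friedman, rank-sum post-hocs."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import swallowflow as sf
from swallowflow.core import InsufficientDataError
from swallowflow.stats import (BlockMatrix, aggregate_medians, friedman_test,
                               posthoc_pairwise, ranksum_test,
                               run_stimulus_analysis)


def _table(rows):
    return pd.DataFrame(rows, columns=["participant", "stimulus", "task",
                                       "repetition", "swallow_index",
                                       "feature_name", "value"])


def _full_table(n_participants=5, rng=None, feature="f", effect=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_participants):
        for s_idx, stim in enumerate(sf.STIMULI):
            for task in sf.TASKS:
                for k in range(4):
                    val = rng.normal(s_idx * (effect or 0.0), 1.0) + p * 0.5
                    rows.append((f"P{p}", stim, task, 1, k, feature, val))
    return _table(rows)


class TestAggregateMedians:
    def test_median_is_outlier_robust(self):
        rows = [("P%d" % p, s, "discrete", 1, k, "f", v)
                for p in range(3) for s in sf.STIMULI
                for k, v in enumerate([1.0, 2.0, 100.0])]
        m = aggregate_medians(_table(rows), "f", "discrete")
        assert np.all(m.values == 2.0)

    def test_single_value_cell(self):
        rows = [("P%d" % p, s, "discrete", 1, 0, "f", 5.0)
                for p in range(3) for s in sf.STIMULI]
        m = aggregate_medians(_table(rows), "f", "discrete")
        assert np.all(m.values == 5.0)

    def test_participant_missing_a_stimulus_is_dropped(self):
        table = _full_table(4)
        table = table[~((table.participant == "P3") & (table.stimulus == "honey"))]
        with pytest.warns(UserWarning, match="P3"):
            m = aggregate_medians(table, "f", "discrete")
        assert "P3" not in m.participants
        assert len(m.participants) == 3

    def test_too_few_participants_rejected(self):
        with pytest.raises(InsufficientDataError):
            aggregate_medians(_full_table(2), "f", "discrete")

    def test_missing_values_ignored_in_cells(self):
        table = _full_table(3)
        table.loc[table.index[:2], "value"] = np.nan
        m = aggregate_medians(table, "f", "discrete")
        assert np.all(np.isfinite(m.values))


class TestFriedman:
    def test_unanimous_ranking_closed_form(self):
        # b blocks ranking k treatments identically, no ties: chi2 = b*(k-1)
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1)) + \
            np.arange(6)[:, None] * 10
        stat, p = friedman_test(vals)
        assert stat == pytest.approx(18.0)
        assert p == pytest.approx(sstats.chi2.sf(18.0, df=3), rel=1e-6)
        assert p < 0.001

    def test_all_constant_rows_null_result(self):
        stat, p = friedman_test(np.ones((5, 4)))
        assert stat == 0.0 and p == 1.0

    def test_single_block_rejected(self):
        with pytest.raises(InsufficientDataError):
            friedman_test(np.array([[1.0, 2.0, 3.0, 4.0]]))

    def test_monotone_transform_invariance(self, rng):
        vals = rng.standard_normal((8, 4))
        s1, p1 = friedman_test(vals)
        s2, p2 = friedman_test(np.exp(3 * vals))  # strictly increasing map
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_type_one_error_quick(self, rng):
        rej = sum(friedman_test(rng.standard_normal((17, 4)))[1] < 0.05
                  for _ in range(300))
        assert 0.02 <= rej / 300 <= 0.09


def _exact_ranksum_p(a, b):
    """Exhaustive-enumeration two-sided rank-sum p-value (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2
    count = total = 0
    for comb in combinations(range(len(pooled)), na):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestRanksum:
    def test_separated_triples_exact_p(self):
        _, p = ranksum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_identical_degenerate_samples(self):
        _, p = ranksum_test(np.ones(5), np.ones(5))
        assert p == 1.0

    @pytest.mark.parametrize("na, nb", [(3, 3), (4, 5), (6, 8), (8, 8)])
    def test_exact_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(5):
            a = rng.standard_normal(na)
            b = rng.standard_normal(nb) + rng.uniform(-1, 1)
            _, p = ranksum_test(a, b)
            assert p == pytest.approx(_exact_ranksum_p(a, b), rel=1e-9)


class TestPosthoc:
    def test_bonferroni_adjustment_and_gate(self):
        rng = np.random.default_rng(1)
        vals = np.column_stack([rng.standard_normal(8) + 3 * j for j in range(4)])
        m = BlockMatrix("f", "discrete", [f"P{i}" for i in range(8)], vals)
        results = posthoc_pairwise(m)
        assert len(results) == 6
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))
            assert r.significant == (r.p_adjusted < 0.05)

    def test_published_threshold_example(self):
        # a raw p of 0.0079 survives Bonferroni over six pairs
        assert min(1.0, 6 * 0.0079) == pytest.approx(0.0474)
        assert 6 * 0.0079 < 0.05


class TestRunAnalysis:
    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            run_stimulus_analysis(pd.DataFrame(
                columns=["participant", "stimulus", "task", "repetition",
                         "swallow_index", "feature_name", "value"]))

    def test_reports_have_posthoc_only_when_significant(self):
        table = pd.concat([
            _full_table(6, np.random.default_rng(3), "strong", effect=3.0),
            _full_table(6, np.random.default_rng(4), "null", effect=0.0),
        ])
        reports = run_stimulus_analysis(table, features=("strong", "null"))
        for task in sf.TASKS:
            rep = reports[task]
            by_name = {f.feature_name: f for f in rep.features}
            assert by_name["strong"].significant
            assert by_name["strong"].posthoc
            assert not by_name["null"].posthoc
            assert "strong" in rep.significant_features

    def test_markdown_summary_lists_significant_features(self):
        table = _full_table(6, np.random.default_rng(3), "f", effect=3.0)
        reports = run_stimulus_analysis(table, features=("f",))
        md = reports["discrete"].summary_markdown()
        assert "| f |" in md and "p-value" in md

    def test_label_permutation_kills_significance_rate(self):
        """Shuffling stimulus labels within participant destroys the effect:
        the per-feature rejection rate drops to the nominal alpha level."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_tests = 60
        for _ in range(n_tests):
            table = _full_table(8, rng, "f", effect=2.0)
            perm = table.copy()
            for p in perm.participant.unique():
                for task in sf.TASKS:
                    mask = (perm.participant == p) & (perm.task == task)
                    perm.loc[mask, "stimulus"] = rng.permutation(
                        perm.loc[mask, "stimulus"].to_numpy())
            m = aggregate_medians(perm, "f", "discrete")
            rejections += friedman_test(m)[1] < 0.05
        assert rejections / n_tests < 0.2
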