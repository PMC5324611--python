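"""Vertebral morphometrics: summaries, comparisons, counterfactuals."""

import numpy as np
import pandas as pd
import pytest

from tailkit import (VertebralColumn, compare_groups, decomposition_fit,
                     insertion_counterfactual, profile_compare, size_correct,
                     summarize_column, tail_body_stats)
from tailkit.vertebrae import ColumnSummary


def column(lengths, ind="x", pop="p", hab="nonforest"):
    return VertebralColumn(individual_id=ind, lengths_mm=np.asarray(lengths),
                           population=pop, habitat=hab)


def make_summary(ind, longest, count, total, sacral=18.0):
    caudal = np.full(count, total / count)
    caudal[0] = longest  # not used by decomposition beyond the named fields
    return ColumnSummary(individual_id=ind, population="p", habitat="h",
                         sacral_sum=sacral, caudal_count=count,
                         caudal_total=total, longest_caudal=longest,
                         longest_position=1, caudal_lengths=caudal)


class TestSummarize:
    def test_construction_example(self):
        s = summarize_column(column([1, 1, 1, 1, 1, 1, 2, 3, 2]))
        assert s.sacral_sum == 6
        assert s.caudal_count == 3
        assert s.caudal_total == 7
        assert s.longest_caudal == 3
        assert s.longest_position == 2

    def test_sacral_only_column_rejected(self):
        with pytest.raises(ValueError, match="at least 7"):
            column([1, 1, 1, 1, 1, 1])

    def test_totals_match_summation_oracle(self, rng):
        for _ in range(20):
            lengths = rng.uniform(0.5, 6.0, rng.integers(8, 30))
            s = summarize_column(column(lengths))
            assert s.caudal_total == pytest.approx(sum(lengths[6:]), abs=1e-9)
            assert s.longest_caudal == pytest.approx(max(lengths[6:]), abs=1e-12)


class TestSizeCorrect:
    def _summaries(self, sacral, response):
        return [make_summary(f"i{k}", 5.0, 20, float(r), sacral=float(s))
                for k, (s, r) in enumerate(zip(sacral, response))]

    def test_perfect_allometry_gives_zero_residuals(self, rng):
        sacral = rng.uniform(15, 22, 12)
        summ = self._summaries(sacral, 3.0 * sacral)
        slope, intercept, r2 = size_correct(summ, "caudal_total")
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(3.0, abs=1e-9)
        assert all(abs(s.residual["caudal_total"]) < 1e-9 for s in summ)

    def test_independent_response_keeps_centered_values(self, rng):
        sacral = rng.uniform(15, 22, 200)
        resp = rng.normal(80, 5, 200)
        summ = self._summaries(sacral, resp)
        _, _, r2 = size_correct(summ, "caudal_total")
        assert r2 < 0.05
        resid = np.array([s.residual["caudal_total"] for s in summ])
        assert np.corrcoef(resid, resp - resp.mean())[0, 1] > 0.97

    def test_residuals_sum_to_zero(self, rng):
        sacral = rng.uniform(15, 22, 30)
        summ = self._summaries(sacral, rng.normal(80, 8, 30) + 2 * sacral)
        size_correct(summ, "caudal_total")
        assert sum(s.residual["caudal_total"] for s in summ) == pytest.approx(
            0.0, abs=1e-9)

    def test_zero_sacral_variance_raises(self):
        summ = self._summaries([18.0] * 5, [80.0] * 5)
        with pytest.raises(ValueError, match="variance"):
            size_correct(summ, "caudal_total")


class TestCompareGroups:
    def _group(self, rng, n, hab, pop, count_mu, scale=1.0):
        cols = []
        for k in range(n):
            count = int(rng.integers(count_mu - 1, count_mu + 2))
            lengths = np.concatenate([rng.uniform(2.5, 3.1, 6),
                                      scale * rng.uniform(3.0, 4.5, count)])
            cols.append(column(lengths, ind=f"{pop}{k}", pop=pop, hab=hab))
        return [summarize_column(c) for c in cols]

    def test_identical_groups_not_significant(self, rng):
        a = self._group(rng, 12, "forest", "a", 20)
        b = self._group(rng, 12, "nonforest", "b", 20)
        rep = compare_groups(a + b)
        assert rep["ranksum_caudal_count"]["p"] > 0.05
        assert rep["kruskal_caudal_count"]["p"] > 0.05

    def test_count_difference_detected(self, rng):
        a = self._group(rng, 15, "forest", "a", 23)
        b = self._group(rng, 15, "nonforest", "b", 20)
        rep = compare_groups(a + b)
        assert rep["ranksum_caudal_count"]["p"] < 0.001
        assert rep["ancova_caudal_total"]["C(habitat)"]["p"] < 0.05

    def test_kruskal_statistic_matches_rank_formula(self):
        # 3 groups of 3, all values distinct -> closed-form H without ties
        vals = {"g1": [19, 22, 25], "g2": [20, 23, 26], "g3": [21, 24, 27]}
        summaries = []
        j = 0
        for g, counts in vals.items():
            hab = {"g1": "forest", "g2": "nonforest", "g3": "forest"}[g]
            for k, c in enumerate(counts):
                j += 1
                lengths = np.concatenate([np.full(6, 3.0 + 0.02 * j),
                                          np.linspace(4, 2, c)])
                summaries.append(summarize_column(
                    column(lengths, ind=f"{g}_{k}", pop=g, hab=hab)))
        rep = compare_groups(summaries, group_field="population",
                             two_way_field="habitat")
        n = 9
        ranks = {"g1": [1, 4, 7], "g2": [2, 5, 8], "g3": [3, 6, 9]}
        h = 12.0 / (n * (n + 1)) * sum(
            3 * (np.mean(r) - (n + 1) / 2) ** 2 for r in ranks.values())
        assert rep["kruskal_caudal_count"]["chi2"] == pytest.approx(h, abs=1e-10)

    def test_small_group_rejected(self, rng):
        a = self._group(rng, 1, "forest", "a", 22)
        b = self._group(rng, 5, "nonforest", "b", 20)
        with pytest.raises(ValueError, match="at least two members"):
            compare_groups(a + b)


class TestProfileCompare:
    def _cols(self, rng, n, hab, factor=1.0, window=(4, 15)):
        base = np.interp(np.arange(1, 21), [1, 6, 20], [2.8, 4.2, 2.0])
        out = []
        for k in range(n):
            caudal = base * rng.normal(1.0, 0.02, 20)
            if factor != 1.0:
                caudal[window[0] - 1: window[1]] *= factor
            out.append(column(np.concatenate([np.full(6, 3.0), caudal]),
                              ind=f"{hab}{k}", hab=hab))
        return out

    def test_same_group_has_empty_segment(self, rng):
        a = self._cols(rng, 15, "forest")
        assert profile_compare(a, a).elongated_segment is None

    def test_null_groups_have_coinciding_profiles(self, rng):
        a = self._cols(rng, 15, "forest")
        b = self._cols(rng, 15, "nonforest")
        prof = profile_compare(a, b)
        both = prof.positions - 1
        assert np.nanmax(np.abs(prof.median_a[both]
                                - prof.median_b[both])) < 0.15
        if prof.elongated_segment is not None:  # at most a noise blip
            lo, hi = prof.elongated_segment
            assert hi - lo + 1 <= 2

    def test_constructed_elongation_found_inside_window(self, rng):
        a = self._cols(rng, 15, "forest", factor=1.3, window=(4, 15))
        b = self._cols(rng, 15, "nonforest")
        seg = profile_compare(a, b).elongated_segment
        assert seg is not None
        lo, hi = seg
        assert 4 <= lo and hi <= 15

    def test_ragged_trailing_positions_flagged(self, rng):
        a = self._cols(rng, 10, "forest")
        a[0] = column(np.r_[np.full(6, 3.0), np.full(25, 3.0)], ind="long",
                      hab="forest")
        prof = profile_compare(a, self._cols(rng, 10, "nonforest"))
        assert all(p > 20 for p in prof.flagged_positions)

    def test_empty_group_raises(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            profile_compare([], self._cols(rng, 3, "b"))


class TestInsertionCounterfactual:
    def _prairie(self, rng, n=12):
        out = []
        for k in range(n):
            count = int(rng.integers(18, 23))
            caudal = np.interp(np.arange(1, count + 1), [1, 6, count],
                               [2.8, 4.2, 2.0]) * rng.normal(1, 0.03, count)
            out.append(column(np.r_[np.full(6, 3.0), caudal], ind=f"p{k}",
                              hab="nonforest"))
        return out

    def test_k_zero_gives_zero_compensation(self, rng):
        prairie = self._prairie(rng)
        forest = self._prairie(rng)
        for c in forest:
            c.lengths_mm = c.lengths_mm * 1.2  # make denominator positive
        res = insertion_counterfactual(prairie, forest, k=0)
        assert res.compensation == pytest.approx(0.0, abs=1e-12)

    def test_pure_count_construction_fully_compensated(self, rng):
        prairie = self._prairie(rng)
        forest = []
        for c in prairie:
            caudal = c.caudal
            mid = len(caudal) // 2
            extra = np.repeat(caudal.max(), 3)
            forest.append(column(
                np.r_[c.lengths_mm[:6], caudal[:mid], extra, caudal[mid:]],
                ind=f"f_{c.individual_id}", hab="forest"))
        res = insertion_counterfactual(prairie, forest, k=3)
        assert res.compensation == pytest.approx(1.0, abs=1e-12)
        assert res.k == 3

    def test_default_k_is_rounded_count_difference(self, rng):
        prairie = self._prairie(rng)
        forest = [column(np.r_[c.lengths_mm, [2.0, 2.0, 2.0]],
                         ind=f"f{c.individual_id}", hab="forest")
                  for c in prairie]
        res = insertion_counterfactual(prairie, forest)
        assert res.k == 3

    def test_pure_elongation_matches_arithmetic_oracle(self, rng):
        prairie = self._prairie(rng)
        forest = []
        for c in prairie:
            stretched = c.lengths_mm.copy()
            stretched[6:] = stretched[6:] * 1.25
            forest.append(column(stretched, ind=f"f{c.individual_id}",
                                 hab="forest"))
        k = 2
        res = insertion_counterfactual(prairie, forest, k=k)
        mean_longest = np.mean([c.caudal.max() for c in prairie])
        delta = 0.25 * np.mean([c.caudal.sum() for c in prairie])
        assert res.compensation == pytest.approx(k * mean_longest / delta,
                                                 abs=1e-10)

    def test_monotone_in_k(self, rng):
        prairie = self._prairie(rng)
        forest = self._prairie(rng)
        for c in forest:
            c.lengths_mm = c.lengths_mm * 1.3
        comps = [insertion_counterfactual(prairie, forest, k=k).compensation
                 for k in range(6)]
        assert all(b >= a for a, b in zip(comps, comps[1:]))

    def test_not_longer_forest_gives_undefined(self, rng):
        prairie = self._prairie(rng)
        res = insertion_counterfactual(prairie, prairie, k=3)
        assert res.compensation is None

    def test_order_invariance(self, rng):
        prairie = self._prairie(rng)
        forest = self._prairie(rng)
        for c in forest:
            c.lengths_mm = c.lengths_mm * 1.3
        r1 = insertion_counterfactual(prairie, forest, k=3)
        r2 = insertion_counterfactual(prairie[::-1], forest[::-1], k=3)
        assert r1.compensation == pytest.approx(r2.compensation, abs=1e-12)


class TestDecomposition:
    def test_exact_model_recovered(self, rng):
        summaries = [make_summary(f"i{k}", lo, int(c), 2.0 * lo + 1.5 * c)
                     for k, (lo, c) in enumerate(
                         zip(rng.uniform(3, 6, 20), rng.integers(18, 25, 20)))]
        fit = decomposition_fit(summaries)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.coef_longest == pytest.approx(2.0, abs=1e-8)
        assert fit.coef_count == pytest.approx(1.5, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        longest = rng.uniform(3, 6, 25)
        count = rng.integers(18, 25, 25).astype(float)
        total = rng.normal(80, 8, 25)
        summaries = [make_summary(f"i{k}", lo, int(c), t)
                     for k, (lo, c, t) in enumerate(zip(longest, count, total))]
        fit = decomposition_fit(summaries)
        x = np.column_stack([np.ones(25), longest, count])
        beta = np.linalg.solve(x.T @ x, x.T @ total)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.coef_longest == pytest.approx(beta[1], abs=1e-8)
        assert fit.coef_count == pytest.approx(beta[2], abs=1e-8)

    def test_r2_invariant_to_unit_change(self, rng):
        longest = rng.uniform(3, 6, 15)
        count = rng.integers(18, 25, 15).astype(float)
        total = 2 * longest + 1.5 * count + rng.normal(0, 1, 15)
        s_mm = [make_summary(f"i{k}", lo, int(c), t)
                for k, (lo, c, t) in enumerate(zip(longest, count, total))]
        s_cm = [make_summary(f"i{k}", lo / 10, int(c), t / 10)
                for k, (lo, c, t) in enumerate(zip(longest, count, total))]
        assert decomposition_fit(s_mm).r2 == pytest.approx(
            decomposition_fit(s_cm).r2, abs=1e-10)

    def test_constant_predictor_rejected(self):
        summaries = [make_summary(f"i{k}", 5.0, 20, 70.0 + k)
                     for k in range(6)]
        with pytest.raises(ValueError, match="constant predictor"):
            decomposition_fit(summaries)


class TestTailBodyStats:
    def test_filters_and_ratio(self):
        df = pd.DataFrame({
            "tail_mm": [90.0, 45.0, 80.0, -3.0, 70.0],
            "body_mm": [90.0, 80.0, 85.0, 90.0, 75.0],
            "habitat": ["forest", "forest", "nonforest", "forest",
                        "nonforest"]})
        rep = tail_body_stats(df)
        assert rep["n_rejected_nonpositive"] == 1
        assert rep["n_excluded_juvenile"] == 1    # tail 45 < 46 mm
        assert rep["n_retained"] == 3
        ratios = rep["ratios"]
        assert ratios["ratio"].iloc[0] == pytest.approx(1.0)

    def test_boundary_values_retained(self):
        # exactly at the adult minima -> kept
        df = pd.DataFrame({"tail_mm": [46.0, 60.0, 55.0, 58.0],
                           "body_mm": [60.0, 70.0, 62.0, 66.0],
                           "habitat": ["forest", "forest", "nonforest",
                                       "nonforest"]})
        rep = tail_body_stats(df)
        assert rep["n_retained"] == 4

    def test_identical_groups_kw_near_one(self):
        df = pd.DataFrame({"tail_mm": [80.0, 81, 82, 80, 81, 82],
                           "body_mm": [90.0, 90, 90, 90, 90, 90],
                           "habitat": ["forest"] * 3 + ["nonforest"] * 3})
        rep = tail_body_stats(df)
        assert rep["kruskal"]["p"] > 0.9
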