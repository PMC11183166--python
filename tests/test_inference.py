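"""Permutation tests, BH-FDR, NBS and demographics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphnet as mn


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = mn.permutation_test_auc(vals, vals.copy(), n_perm=500, seed=0)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_mode_matches_enumeration(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(3), rng.random(3) + 0.3
        res = mn.permutation_test_auc(a, b, seed=0)  # auto-exhaustive at n=6
        assert res.exhaustive and res.n_perm == 20  # C(6,3)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = sum(
            abs(pooled[list(idx)].mean() - np.delete(pooled, list(idx)).mean())
            >= abs(obs) - 1e-15
            for idx in combinations(range(6), 3)
        )
        assert res.p_value == pytest.approx(count / 20)

    def test_monte_carlo_matches_exhaustive_within_sampling_error(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(4), rng.random(4) + 0.2
        exact = mn.permutation_test_auc(a, b, exhaustive=True)
        mc = mn.permutation_test_auc(a, b, n_perm=20_000, seed=3, exhaustive=False)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20_000)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 1e-3

    def test_p_value_invariant_to_group_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(8), rng.random(9) + 0.1
        r1 = mn.permutation_test_auc(a, b, n_perm=2000, seed=4)
        r2 = mn.permutation_test_auc(b, a, n_perm=2000, seed=4)
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.02)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)

    def test_type_one_error_calibrated(self):
        """Null data rejected at ~5% over replicate runs (Monte-Carlo)."""
        rng = np.random.default_rng(5)
        n_rep, n = 400, 12
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(size=2 * n)
            res = mn.permutation_test_auc(x[:n], x[n:], n_perm=400,
                                          seed=int(rng.integers(2**31)),
                                          exhaustive=False)
            rejections += res.p_value < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi + 2  # small MC slack on 400-perm p granularity

    def test_large_shift_always_detected(self):
        rng = np.random.default_rng(6)
        detected = 0
        for _ in range(30):
            a = rng.normal(0, 1, 38)
            b = rng.normal(2.0, 1, 38)  # 2 pooled SDs
            res = mn.permutation_test_auc(a, b, n_perm=1000,
                                          seed=int(rng.integers(2**31)),
                                          exhaustive=False)
            detected += res.p_value < 0.05
        assert detected >= 29

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mn.permutation_test_auc([1.0], [2.0, 3.0])

    def test_smoothed_mode_never_returns_zero(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 12), rng.normal(8, 1, 12)  # huge separation
        raw = mn.permutation_test_auc(a, b, n_perm=200, seed=0, exhaustive=False)
        sm = mn.permutation_test_auc(a, b, n_perm=200, seed=0, exhaustive=False,
                                     smoothed=True)
        assert raw.p_value == 0.0
        assert sm.p_value == pytest.approx(1 / 201)


class TestBHFDR:
    def test_hand_executed_step_up_on_five_values(self):
        res = mn.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), q=0.05)
        # p_(i) <= (i/5)*0.05 holds at i=5 (0.05 <= 0.05) -> all rejected
        assert res.significant.all()
        assert np.allclose(res.p_adjusted, 0.05)

    def test_all_ones_nothing_significant(self):
        res = mn.bh_fdr(np.ones(7))
        assert not res.significant.any()
        assert np.allclose(res.p_adjusted, 1.0)

    def test_single_p_reduces_to_raw_comparison(self):
        res = mn.bh_fdr(np.array([0.04]), q=0.05)
        assert res.significant[0]
        assert res.p_adjusted[0] == pytest.approx(0.04)

    def test_adjusted_never_below_raw_and_never_more_than_uncorrected(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        res = mn.bh_fdr(p)
        assert (res.p_adjusted >= p - 1e-15).all()
        assert res.significant.sum() <= (p < 0.05).sum()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mn.bh_fdr(np.array([0.1, 1.2]))


def random_similarity_stack(rng, n_subj, n_nodes):
    """Exchangeable null stack of symmetric matrices with unit diagonal."""
    base = rng.random((n_nodes, n_nodes)) * 0.5 + 0.25
    base = (base + base.T) / 2
    stack = base[None] + 0.05 * rng.normal(size=(n_subj, n_nodes, n_nodes))
    stack = (stack + stack.transpose(0, 2, 1)) / 2
    stack = np.clip(stack, 0, 1)
    idx = np.arange(n_nodes)
    stack[:, idx, idx] = 1.0
    return stack


class TestNBS:
    def test_planted_clique_recovered(self):
        """Edges of a 6-node clique shifted by 2 SDs in one group are found
        as one significant component covering the planted edges."""
        rng = np.random.default_rng(8)
        stack = random_similarity_stack(rng, 76, 20)
        labels = np.zeros(76, dtype=bool)
        labels[:38] = True
        clique = [2, 5, 8, 11, 14, 17]
        for i in clique:
            for j in clique:
                if i < j:
                    stack[labels, i, j] += 0.10  # 2 x the 0.05 subject SD
                    stack[labels, j, i] = stack[labels, i, j]
        res = mn.nbs(stack, labels, primary_t=3.2, n_perm=500,
                     direction="patient>control", seed=9)
        assert res.components, "no component found"
        comp = res.components[0]
        assert comp.corrected_p <= 0.05
        planted = {(i, j) for i in clique for j in clique if i < j}
        found = {tuple(sorted(e)) for e in comp.edges}
        overlap = len(planted & found) / len(planted)
        assert overlap >= 0.8

    def test_familywise_error_near_nominal_under_null(self):
        rng = np.random.default_rng(10)
        false_pos = 0
        n_rep = 30
        for _ in range(n_rep):
            stack = random_similarity_stack(rng, 40, 12)
            labels = np.zeros(40, dtype=bool)
            labels[:20] = True
            res = mn.nbs(stack, labels, primary_t=3.2, n_perm=200,
                         seed=int(rng.integers(2**31)))
            if any(c.corrected_p < 0.05 for c in res.components):
                false_pos += 1
        # binomial 95% upper bound at p=0.05, n=30 is ~4
        assert false_pos <= 4

    def test_two_node_mask_single_edge_component(self):
        rng = np.random.default_rng(11)
        stack = random_similarity_stack(rng, 30, 6)
        labels = np.zeros(30, dtype=bool)
        labels[:15] = True
        stack[labels, 1, 4] += 0.3
        stack[labels, 4, 1] = stack[labels, 1, 4]
        res = mn.nbs(stack, labels, node_mask=np.array([1, 4]), primary_t=3.2,
                     n_perm=100, seed=12)
        assert len(res.components) == 1
        assert res.components[0].size == 1
        assert set(res.components[0].nodes) == {1, 4}

    def test_no_suprathreshold_edges_is_empty_not_error(self):
        rng = np.random.default_rng(13)
        stack = random_similarity_stack(rng, 30, 8)
        labels = np.zeros(30, dtype=bool)
        labels[:15] = True
        res = mn.nbs(stack, labels, primary_t=50.0, n_perm=50, seed=14)
        assert res.components == ()

    def test_direction_selects_sign(self):
        rng = np.random.default_rng(15)
        stack = random_similarity_stack(rng, 60, 10)
        labels = np.zeros(60, dtype=bool)
        labels[:30] = True
        stack[~labels, 2, 7] += 0.3  # controls higher
        stack[~labels, 7, 2] = stack[~labels, 2, 7]
        hyper = mn.nbs(stack, labels, primary_t=4.0, n_perm=50,
                       direction="patient>control", seed=16)
        hypo = mn.nbs(stack, labels, primary_t=4.0, n_perm=50,
                      direction="patient<control", seed=16)
        hyper_edges = {tuple(sorted(e)) for c in hyper.components for e in c.edges}
        hypo_edges = {tuple(sorted(e)) for c in hypo.components for e in c.edges}
        assert (2, 7) in hypo_edges
        assert (2, 7) not in hyper_edges


class TestDemographics:
    def make_clinical(self, age_p, age_c, sex_p, sex_c):
        rows = []
        for i, (a, s) in enumerate(zip(age_p, sex_p)):
            rows.append({"subject_id": f"P{i}", "group": "patient", "age": a,
                         "sex": s, "onset": 2.0, "duration": 5.0, "hfmse": 30})
        for i, (a, s) in enumerate(zip(age_c, sex_c)):
            rows.append({"subject_id": f"C{i}", "group": "control", "age": a,
                         "sex": s, "onset": np.nan, "duration": np.nan,
                         "hfmse": np.nan})
        return pd.DataFrame(rows)

    def test_matched_sex_counts_give_zero_chi_square(self):
        sex = ["M"] * 24 + ["F"] * 14
        rng = np.random.default_rng(17)
        clin = self.make_clinical(rng.uniform(5, 17, 38), rng.uniform(6, 20, 38),
                                  sex, list(sex))
        out = mn.compare_demographics(clin)
        row = out[out.variable == "sex (M:F)"].iloc[0]
        assert row.statistic == 0.0
        assert row.p_value == 1.0
        assert row.patient_summary == "24:14"

    def test_identical_ages_give_zero_t(self):
        ages = np.linspace(6, 16, 10)
        clin = self.make_clinical(ages, ages, ["M"] * 10, ["M"] * 10)
        out = mn.compare_demographics(clin)
        row = out[out.variable == "age"].iloc[0]
        assert row.statistic == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_textbook_pooled_formula(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(10, 3, 12), rng.normal(12, 3, 15)
        clin = self.make_clinical(a, b, ["M"] * 12, ["F"] * 15)
        out = mn.compare_demographics(clin)
        row = out[out.variable == "age"].iloc[0]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert row.statistic == pytest.approx(t, abs=1e-12)

    def test_single_subject_group_rejected(self):
        clin = self.make_clinical([10.0], [11.0, 12.0], ["M"], ["M", "F"])
        with pytest.raises(ValueError, match="at least 2"):
            mn.compare_demographics(clin)
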