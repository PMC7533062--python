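"""Subject-adjusted partial correlations and permutation inference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ampconn.couplingstats import (
    amplitude_group_ttest,
    coupling_frame,
    coupling_profile,
    demographics_ttests,
    partial_correlation,
    permutation_group_difference,
)
from ampconn.synthcohort import table1_fixture
from oracles import exhaustive_diff_distribution, partial_r_oracle


def make_subject_data(rng, n_subjects=5, n_nodes=30, rho=0.5, offsets=True):
    data = {}
    for s in range(n_subjects):
        x = rng.standard_normal(n_nodes)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n_nodes)
        if offsets:
            x = x + rng.normal(0, 5)
            y = y + rng.normal(0, 5)
        data[f"S{s}"] = (x, y)
    return data


class TestPartialCorrelation:
    def test_single_subject_equals_plain_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        r, _, _ = partial_correlation(x, y, ["s"] * 40)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_subject_offsets_removed(self, rng):
        x = np.concatenate([rng.standard_normal(20) for _ in range(3)])
        subj = np.repeat(["a", "b", "c"], 20)
        y = x + np.select([subj == "a", subj == "b", subj == "c"], [10.0, -4.0, 2.0])
        r, _, _ = partial_correlation(x, y, subj)
        assert r == pytest.approx(1.0)

    def test_matches_dummy_regression_oracle(self, rng):
        data = make_subject_data(rng, n_subjects=4, n_nodes=25, rho=0.4)
        xs = np.concatenate([d[0] for d in data.values()])
        ys = np.concatenate([d[1] for d in data.values()])
        subj = np.repeat(list(data), 25)
        r, _, _ = partial_correlation(xs, ys, subj)
        assert r == pytest.approx(partial_r_oracle(xs, ys, subj), abs=1e-10)

    def test_zero_residual_variance_flagged(self):
        x = np.ones(20)
        y = np.arange(20.0)
        r, ci, p = partial_correlation(x, y, ["s"] * 20)
        assert np.isnan(r) and np.isnan(p)

    def test_ci_covers_known_correlation(self, rng):
        """Fisher-z CI with subject-adjusted df: nominal coverage on a known model."""
        rho = 0.5
        hits = 0
        for _ in range(100):
            data = make_subject_data(rng, n_subjects=5, n_nodes=100, rho=rho)
            xs = np.concatenate([d[0] for d in data.values()])
            ys = np.concatenate([d[1] for d in data.values()])
            subj = np.repeat(list(data), 100)
            _, (lo, hi), _ = partial_correlation(xs, ys, subj)
            hits += lo <= rho <= hi
        assert hits >= 93

    @given(shift=st.floats(-50, 50))
    def test_invariant_to_per_subject_constants(self, shift):
        rng = np.random.default_rng(13)
        data = make_subject_data(rng, n_subjects=3, n_nodes=20, rho=0.3)
        xs = np.concatenate([d[0] for d in data.values()])
        ys = np.concatenate([d[1] for d in data.values()])
        subj = np.repeat(list(data), 20)
        r0, _, _ = partial_correlation(xs, ys, subj)
        xs2 = xs + np.where(subj == "S1", shift, 0.0)
        r1, _, _ = partial_correlation(xs2, ys, subj)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestCouplingProfile:
    def make_tables(self, rng, rho_by_group):
        rows = []
        for group, rho in rho_by_group.items():
            for s in range(5):
                x = rng.standard_normal(24)
                y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(24)
                for xi, yi in zip(x, y):
                    rows.append(
                        {"group": group, "subject": f"{group}{s}", "stage": "t4",
                         "m": 24, "amplitude": xi, "DEG": yi}
                    )
        return pd.DataFrame(rows)

    def test_recovers_planted_signs(self, rng):
        tables = self.make_tables(rng, {"broca": 0.6, "control": -0.6})
        results = coupling_profile(tables, "DEG")
        by_group = {r.group: r for r in results}
        assert by_group["broca"].r > 0 and by_group["broca"].significant
        assert by_group["control"].r < 0 and by_group["control"].significant

    def test_identical_inputs_identical_r(self, rng):
        tables = self.make_tables(rng, {"a": 0.4})
        dup = tables.copy()
        dup["group"] = "b"
        both = pd.concat([tables, dup])
        results = coupling_profile(both, "DEG")
        assert results[0].r == pytest.approx(results[1].r)

    def test_missing_m_skipped(self, rng, caplog):
        tables = self.make_tables(rng, {"a": 0.4})
        with caplog.at_level("INFO"):
            results = coupling_profile(tables, "DEG", m_values=[24, 999])
        assert len(results) == 1
        frame = coupling_frame(results)
        assert list(frame["m"]) == [24]


class TestPermutationGroupDifference:
    def test_same_seed_reproducible(self, rng):
        data = make_subject_data(rng, n_subjects=10, n_nodes=20, rho=0.0)
        groups = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(data)}
        a = permutation_group_difference(data, groups, n_perm=300, seed=4)
        b = permutation_group_difference(data, groups, n_perm=300, seed=4)
        assert (a.perm_ci_low, a.perm_ci_high) == (b.perm_ci_low, b.perm_ci_high)

    def test_sampled_ci_converges_to_exhaustive(self, rng):
        data = make_subject_data(rng, n_subjects=10, n_nodes=15, rho=0.3)
        groups = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(data)}
        res = permutation_group_difference(data, groups, n_perm=4000, seed=8)
        observed, diffs = exhaustive_diff_distribution(data, groups)
        assert res.observed_diff == pytest.approx(observed, abs=1e-9)
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        spread = diffs.max() - diffs.min()
        assert res.perm_ci_low == pytest.approx(lo, abs=0.1 * spread)
        assert res.perm_ci_high == pytest.approx(hi, abs=0.1 * spread)

    def test_opposite_couplings_detected(self, rng):
        data = {}
        groups = {}
        for i in range(10):
            rho = 0.7 if i < 5 else -0.7
            x = rng.standard_normal(40)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(40)
            data[f"S{i}"] = (x, y)
            groups[f"S{i}"] = "g1" if i < 5 else "g2"
        res = permutation_group_difference(data, groups, n_perm=1000, seed=2)
        assert res.significant
        assert res.observed_diff > 1.0

    def test_too_few_subjects_rejected(self, rng):
        data = make_subject_data(rng, n_subjects=3, n_nodes=10)
        groups = {"S0": "a", "S1": "a", "S2": "b"}
        with pytest.raises(ValueError):
            permutation_group_difference(data, groups)


class TestAmplitudeTtest:
    def make_table(self, rng, shift_node=None, shift=0.0):
        values = rng.standard_normal((10, 8))
        if shift_node is not None:
            values[:5, shift_node] += shift
        idx = [f"S{i}" for i in range(10)]
        return pd.DataFrame(values, index=idx), {
            s: ("g1" if i < 5 else "g2") for i, s in enumerate(idx)
        }

    def test_identical_groups_not_significant(self, rng):
        tbl, groups = self.make_table(rng)
        res = amplitude_group_ttest(tbl, groups, n_perm=500, seed=3)
        assert (res["p"] > 0.05).sum() >= 7  # at most chance-level hits

    def test_planted_shift_detected(self, rng):
        tbl, groups = self.make_table(rng, shift_node=2, shift=3.0)
        res = amplitude_group_ttest(tbl, groups, n_perm=1000, seed=3)
        assert res["p"].iloc[2] < 0.05

    def test_p_resolution_and_constant_nodes(self, rng):
        tbl, groups = self.make_table(rng)
        tbl.iloc[:, 0] = 5.0  # constant amplitude node
        res = amplitude_group_ttest(tbl, groups, n_perm=1000, seed=1)
        assert res["p"].iloc[0] == 1.0
        assert res["p"].min() >= 1.0 / 1001.0


class TestDemographics:
    def test_unequal_groups_rejected(self):
        t = table1_fixture().iloc[:-1]
        with pytest.raises(ValueError):
            demographics_ttests(t)

    def test_paired_tests_match_published_rounding(self):
        p = demographics_ttests(table1_fixture())
        assert round(p["age_years"], 2) == 0.30
        assert round(p["education_years"], 2) == 0.24
        assert f"{p['AQ']:.2g}" == "0.00092"
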