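import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from silkstudy.stats import (AncovaResult, ContingencyTable2x2, GroupSummary,
                             PowerSpec, SingularDesignError, ancova_change,
                             dose_response_ancova, fisher_exact_2x2,
                             pearson_chi2_2x2, pooled_t_from_summary,
                             power_two_sample)


class TestChi2:
    def test_balanced_table_is_null(self):
        chi2, p = pearson_chi2_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(ContingencyTable2x2(0, 0, 3, 4))

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 12)] * 4))
    def test_transpose_invariance(self, counts):
        a, b, c, d = counts
        chi1, _ = pearson_chi2_2x2(ContingencyTable2x2(a, b, c, d))
        chi2_, _ = pearson_chi2_2x2(ContingencyTable2x2(a, c, b, d))
        assert chi1 == pytest.approx(chi2_, rel=1e-12)


class TestFisher:
    def test_diagonal_two_by_two(self):
        """Exhaustive enumeration over k = 0, 1, 2 gives 1/3 + ... = 1/3
        for the perfectly discordant 2x2 with margins (2, 2)."""
        assert fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)) == \
            pytest.approx(1 / 3)

    def test_expected_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(4, 6, 6, 9)) == \
            pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_hypergeometric_enumeration(self, counts):
        """For every small table, the two-sided p equals the summed
        hypergeometric mass of tables no more probable than observed."""
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        tbl = ContingencyTable2x2(a, b, c, d)
        n, r1, c1 = a + b + c + d, a + b, a + c
        p_obs = sps.hypergeom.pmf(a, n, r1, c1)
        total = 0.0
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            pk = sps.hypergeom.pmf(k, n, r1, c1)
            if pk <= p_obs * (1 + 1e-9):
                total += pk
        assert fisher_exact_2x2(tbl) == pytest.approx(min(total, 1.0),
                                                      rel=1e-9, abs=1e-12)


class TestPooledT:
    def test_identical_groups_null(self):
        g = GroupSummary(5.0, 1.0, 10)
        t, df, p = pooled_t_from_summary(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        g1, g2 = GroupSummary(10.0, 2.0, 8), GroupSummary(12.0, 3.0, 10)
        t, df, p = pooled_t_from_summary(g1, g2)
        sp2 = (7 * 4 + 9 * 9) / 16
        t_hand = -2.0 / np.sqrt(sp2 * (1 / 8 + 1 / 10))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 16
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), 16), abs=1e-12)


class TestAncova:
    @staticmethod
    def _toy(n=40, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "treatment": np.r_[["placebo"] * (n // 2),
                               ["posiphen"] * (n // 2)],
            "age": rng.uniform(55, 89, n),
            "sex": rng.choice(["female", "male"], n),
        })
        noise = rng.normal(0, 1.0, n)
        df["change"] = (0.05 * df["age"] + 0.3 * (df["sex"] == "male")
                        + delta * (df["treatment"] == "posiphen") + noise)
        return df

    def test_identical_outcomes_zero_difference(self):
        df = self._toy()
        df["change"] = 1.0
        res = ancova_change(df)
        assert res.difference == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self):
        """Coefficients equal the hand-solved least-squares system on a
        small fixed dataset."""
        df = pd.DataFrame({
            "treatment": ["placebo"] * 4 + ["posiphen"] * 4,
            "age": [60, 70, 65, 80, 62, 72, 68, 78.0],
            "sex": ["female", "male"] * 4,
            "change": [1.0, 2.0, 1.5, 3.0, 2.5, 3.5, 2.8, 4.0],
        })
        res = ancova_change(df)
        X = np.column_stack([
            np.ones(8),
            (df["treatment"] == "posiphen").astype(float),
            df["age"].astype(float),
            (df["sex"] == "male").astype(float),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["change"].to_numpy())
        assert res.difference == pytest.approx(beta[1], abs=1e-10)

    def test_reduces_to_pooled_t_with_constant_covariates(self):
        df = self._toy(n=20, delta=1.0, seed=4)
        df["age"] = 70.0
        df = df[df["sex"] == df["sex"].iloc[0]].copy() if False else df
        df["sex"] = "female"
        with pytest.raises(SingularDesignError):
            ancova_change(df)         # constant covariates alias the intercept
        res = ancova_change(df, covariates=())
        x = df.loc[df.treatment == "placebo", "change"]
        y = df.loc[df.treatment == "posiphen", "change"]
        t, df_, p = pooled_t_from_summary(
            GroupSummary(x.mean(), x.std(ddof=1), len(x)),
            GroupSummary(y.mean(), y.std(ddof=1), len(y)))
        assert res.difference == pytest.approx(y.mean() - x.mean(), abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_estimator_is_unbiased_for_injected_effect(self):
        """Mean estimated difference over replicates sits within Monte-Carlo
        error of the injected effect."""
        delta, reps = 0.8, 300
        ests = [ancova_change(self._toy(n=30, delta=delta, seed=s)).difference
                for s in range(reps)]
        se = np.std(ests, ddof=1) / np.sqrt(reps)
        assert np.mean(ests) == pytest.approx(delta, abs=4 * se)


class TestDoseResponse:
    def test_toy_table_matches_normal_equations(self):
        df = pd.DataFrame({
            "arm": ["placebo"] * 3 + ["QD60"] * 3 + ["BID120"] * 3,
            "r_app": [1.0, 1.1, 0.9, 0.8, 0.9, 0.85, 0.7, 0.75, 0.8],
            "baseline": [5.0, 5.5, 4.8, 4.6, 4.9, 4.7, 4.0, 4.2, 4.1],
        })
        res = dose_response_ancova(df, outcome="r_app", dose="arm",
                                   baseline="baseline")
        lv = sorted(["QD60", "BID120"])
        X = np.column_stack([
            np.ones(9),
            *[(df["arm"] == l).astype(float) for l in lv],
            df["baseline"].to_numpy(),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["r_app"].to_numpy())
        got = res.set_index("arm")["adjusted_difference"]
        for i, l in enumerate(lv):
            assert got[l] == pytest.approx(beta[1 + i], abs=1e-10)

    def test_detects_direction_of_top_dose_effect(self):
        """With a 20% reduction at the top dose and a correlated baseline,
        the adjusted contrast is negative in nearly all replicates."""
        hits = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(s)
            base_prod = rng.lognormal(0, 0.2, 16)
            arm = np.r_[["placebo"] * 8, ["TID180"] * 8]
            eff = np.where(arm == "TID180", 0.8, 1.0)
            r_app = base_prod * eff * rng.lognormal(0, 0.05, 16)
            baseline = base_prod * rng.lognormal(0, 0.05, 16)
            df = pd.DataFrame({"arm": arm, "r_app": r_app,
                               "baseline": baseline})
            res = dose_response_ancova(df, outcome="r_app", dose="arm",
                                       baseline="baseline")
            if res.loc[0, "adjusted_difference"] < 0:
                hits += 1
        assert hits / reps >= 0.95


class TestPower:
    def test_zero_effect_gives_alpha(self):
        spec = PowerSpec(5, 9, 0.05, 0.0, 0.0361, 0.00954)
        assert power_two_sample(spec) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_sample_size(self):
        powers = [power_two_sample(PowerSpec(n, 9, 0.05, 27.0, 0.0361,
                                             0.00954))
                  for n in (4, 6, 10, 20)]
        assert np.all(np.diff(powers) > 0)

    def test_matches_monte_carlo_simulation(self):
        """Analytic noncentral-t power vs a large vectorized two-sample
        t-test simulation."""
        spec = PowerSpec(8, 8, 0.05, 30.0, 1.0, 0.6)
        reps = 100_000
        rng = np.random.default_rng(12)
        shift = spec.percent_change / 100 * spec.reference_mean
        x = rng.normal(0.0, spec.reference_sd, (reps, spec.n1))
        y = rng.normal(shift, spec.reference_sd, (reps, spec.n2))
        sp2 = ((spec.n1 - 1) * x.var(axis=1, ddof=1)
               + (spec.n2 - 1) * y.var(axis=1, ddof=1)) / (
                   spec.n1 + spec.n2 - 2)
        t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(
            sp2 * (1 / spec.n1 + 1 / spec.n2))
        crit = sps.t.ppf(0.975, spec.n1 + spec.n2 - 2)
        mc = np.mean(np.abs(t) > crit)
        assert power_two_sample(spec) == pytest.approx(mc, abs=0.01)
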