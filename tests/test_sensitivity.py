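"""Tornado analysis, distribution fitting, PSA, CEAC and quadrants."""

import math

import numpy as np
import pytest

from markovcea.params import ParameterSpec, WtpConfig, default_parameter_specs
from markovcea.sensitivity import (
    ceac,
    fit_distribution,
    one_way,
    quadrant_proportions,
    reference_icer,
    run_psa,
    tornado,
)


def spec_by_role(role):
    return next(s for s in default_parameter_specs() if s.role == role)


class TestFitDistribution:
    def test_gamma_moment_matching(self):
        dist = fit_distribution(spec_by_role("dp_cost_per_cycle"))
        sd = (1451.95 - 967.97) / (2 * 1.96)
        assert sd == pytest.approx(123.46, abs=0.01)
        assert dist.mean() == pytest.approx(1209.96, rel=1e-12)
        assert dist.std() == pytest.approx(sd, rel=1e-12)
        assert dist.kwds["a"] == pytest.approx(96.05, abs=0.01)
        assert dist.kwds["scale"] == pytest.approx(12.60, abs=0.01)

    def test_beta_moment_matching(self):
        dist = fit_distribution(spec_by_role("u_pfs_erlotinib"))
        sd = (0.87 - 0.26) / (2 * 1.96)
        assert sd == pytest.approx(0.1556, abs=1e-4)
        assert dist.kwds["a"] == pytest.approx(5.46, abs=0.01)
        assert dist.kwds["b"] == pytest.approx(2.94, abs=0.01)
        assert dist.mean() == pytest.approx(0.65, rel=1e-12)
        assert dist.std() == pytest.approx(sd, rel=1e-12)

    def test_lognormal_moment_matching(self):
        dist = fit_distribution(spec_by_role("erl_tt_per_cycle"))
        sd = (2365.4 - 1576.9) / (2 * 1.96)
        assert dist.mean() == pytest.approx(1971.1, rel=1e-12)
        assert dist.std() == pytest.approx(sd, rel=1e-9)

    def test_constant_family_is_point_mass(self):
        dist = fit_distribution(spec_by_role("discount_rate_annual"))
        assert np.all(dist.rvs(size=5) == 0.03)

    def test_sample_mean_recovers_base(self):
        rng = np.random.default_rng(7)
        for role in ("dp_cost_per_cycle", "u_dp", "cg_bsc_per_cycle"):
            spec = spec_by_role(role)
            draws = fit_distribution(spec).rvs(size=1_000_000, random_state=rng)
            assert np.mean(draws) == pytest.approx(spec.base, rel=0.01)

    def test_impossible_beta_named(self):
        bad = ParameterSpec("tiny mean wide range", 0.03, 0.0, 0.67,
                            "beta", "u_dp")
        with pytest.raises(ValueError, match="tiny mean wide range"):
            fit_distribution(bad)

    def test_degenerate_range_rejected(self):
        flat = ParameterSpec("flat", 5.0, 5.0, 5.0, "gamma", "dp_cost_per_cycle")
        with pytest.raises(ValueError):
            fit_distribution(flat)


class TestTornado:
    def test_dp_utility_ranked_first(self, results):
        df = tornado(results)
        assert df.iloc[0]["role"] == "u_dp"
        assert len(df) == 17
        assert np.all(np.diff(df["spread"].fillna(-1).to_numpy()) <= 1e-9)

    def test_order_invariance(self, results):
        specs = list(default_parameter_specs())
        df1 = tornado(results, specs)
        df2 = tornado(results, list(reversed(specs)))
        assert list(df1["parameter"]) == list(df2["parameter"])
        np.testing.assert_allclose(df1["spread"], df2["spread"])

    def test_shared_dp_cost_leaves_effects_unchanged(self, results):
        """Varying the shared DP cost moves costs in both arms but cannot
        move incremental QALYs."""
        spec = spec_by_role("dp_cost_per_cycle")
        base_dq = results.incremental.delta_qaly
        for v in (spec.low, spec.high):
            out = results.reevaluate(results.bundle.with_value(spec.role, v))
            assert out["incremental"].delta_qaly == pytest.approx(base_dq, abs=1e-12)

    def test_unstable_entry_flagged_with_sentinel(self, results):
        """A DP utility low enough to flip the QALY difference has no
        meaningful ICER and must be flagged."""
        flip = ParameterSpec("DP wide", 0.47, 0.0, 0.58, "beta", "u_dp")
        entry = one_way(flip, results)
        assert entry.unstable
        assert math.isinf(entry.icer_at_low)
        assert entry.spread == math.inf

    def test_discount_rate_moves_icer(self, results):
        entry = one_way(spec_by_role("discount_rate_annual"), results)
        assert entry.icer_at_low != pytest.approx(entry.icer_at_high, rel=1e-3)


class TestPSA:
    def test_same_seed_identical(self, results):
        a = run_psa(results, n_iter=25, seed=11)
        b = run_psa(results, n_iter=25, seed=11)
        assert a.samples.equals(b.samples)

    def test_different_seed_differs(self, results):
        a = run_psa(results, n_iter=25, seed=11)
        b = run_psa(results, n_iter=25, seed=12)
        assert not a.samples.equals(b.samples)

    def test_all_constant_degenerates_to_base_case(self, results):
        constant_specs = [
            ParameterSpec(s.name, s.base, s.low, s.high, "constant", s.role)
            for s in default_parameter_specs()
        ]
        psa = run_psa(results, n_iter=5, seed=3, specs=constant_specs)
        inc = results.incremental
        np.testing.assert_allclose(psa.samples["delta_cost"], inc.delta_cost)
        np.testing.assert_allclose(psa.samples["delta_qaly"], inc.delta_qaly)

    def test_quadrant_labels_consistent_with_signs(self, psa_1000):
        s = psa_1000.samples
        for _, row in s.sample(50, random_state=0).iterrows():
            ns = "N" if row["delta_cost"] >= 0 else "S"
            ew = "E" if row["delta_qaly"] >= 0 else "W"
            assert row["quadrant"] == ns + ew

    def test_quadrant_partition(self, psa_1000):
        fractions = quadrant_proportions(psa_1000.samples)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_quadrant_fractions_match_binomial_error(self, results):
        """Two independent 10^4-draw estimates of the NE fraction agree
        within 3 pooled binomial standard errors."""
        n = 10_000
        a = run_psa(results, n_iter=n, seed=101).quadrant_proportions()["NE"]
        b = run_psa(results, n_iter=n, seed=202).quadrant_proportions()["NE"]
        p = (a + b) / 2
        se = math.sqrt(2 * p * (1 - p) / n)
        assert abs(a - b) <= 3 * se


class TestCEAC:
    def test_complementarity(self, psa_1000):
        curve = ceac(psa_1000.samples)
        np.testing.assert_allclose(curve["p_cg"] + curve["p_erlotinib"], 1.0,
                                   atol=1e-12)

    def test_zero_wtp_limit(self, psa_1000):
        curve = ceac(psa_1000.samples, WtpConfig(wtp_grid=(0.0, 1.0)))
        frac_cheaper = float((psa_1000.samples["delta_cost"] < 0).mean())
        assert curve["p_cg"].iloc[0] == pytest.approx(frac_cheaper)

    def test_cg_curve_nondecreasing_when_gains_positive(self, psa_1000):
        sub = psa_1000.samples[psa_1000.samples["delta_qaly"] >= 0]
        curve = ceac(sub)
        assert np.all(np.diff(curve["p_cg"]) >= -1e-12)

    def test_crossing_near_deterministic_icer(self, results, psa_1000):
        crossing = psa_1000.ceac_crossing(0.5)
        det = results.incremental.icer_per_qaly
        assert det / 2 <= crossing <= det * 2


class TestReferenceReanalysis:
    def test_base_utilities_near_published_icer(self):
        """Recomposing from the printed occupancies lands within the
        rounding slack of the printed ICER."""
        assert reference_icer() == pytest.approx(85927.41, rel=0.015)

    def test_endpoints_bracket_base(self):
        assert reference_icer(u_dp=0.58) < reference_icer() < reference_icer(
            u_dp=0.30)
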