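"""RR statistic, model fits, enrichment, bootstrap agreement, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cypddi
from cypddi.stats import _wald_logrr_from_counts


class TestRRStatistic:
    @pytest.mark.parametrize(
        "r1,r2,r12,expected",
        [
            (0.022, 0.033, 0.093, 1.69),
            (0.022, 0.029, 0.095, 1.86),
            (0.020, 0.047, 0.130, 1.94),
            (0.020, 0.018, 0.122, 3.21),
            (0.011, 0.020, 0.093, 3.00),
        ],
    )
    def test_published_risk_triples(self, r1, r2, r12, expected):
        assert round(cypddi.rr_statistic(r1, r2, r12), 2) == expected

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.5])
    def test_exact_additivity_gives_unity(self, r):
        assert cypddi.rr_statistic(r, r, 2 * r) == pytest.approx(1.0)

    def test_zero_denominator_undefined(self):
        with pytest.raises(ValueError):
            cypddi.rr_statistic(0.0, 0.0, 0.1)


class TestBonferroni:
    def test_study_family(self):
        assert cypddi.bonferroni_threshold(0.05, 3670) == pytest.approx(1.36e-5, rel=5e-3)

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.01, 100, 1e-4)])
    def test_simple_cases(self, alpha, n, expected):
        assert cypddi.bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_zero_tests_invalid(self):
        with pytest.raises(ValueError):
            cypddi.bonferroni_threshold(0.05, 0)


def _episodes_from_counts(m1, n1, m2, n2, m12, n12):
    rows = []
    for group, m, n in (
        ("substrate_alone", m1, n1), ("inhibitor_alone", m2, n2), ("joint", m12, n12)
    ):
        for i in range(n):
            rows.append({"person_id": f"{group}{i}", "group": group,
                         "outcome": i < m, "sex": "F", "age_at_anchor": 40.0,
                         "comed_count": 0})
    return pd.DataFrame(rows)


class TestFitSynergistic:
    def test_covariate_free_reduces_to_raw_proportions(self):
        ep = _episodes_from_counts(5, 100, 8, 120, 9, 60)
        res = cypddi.fit_synergistic(ep)
        assert res.risk1 == 5 / 100
        assert res.risk2 == 8 / 120
        assert res.risk12 == 9 / 60
        assert res.rr == pytest.approx(
            cypddi.rr_statistic(5 / 100, 8 / 120, 9 / 60)
        )
        assert res.counts_label() == "(5/100, 8/120, 9/60)"

    def test_empty_group_error_names_group(self):
        ep = _episodes_from_counts(5, 100, 8, 120, 9, 60)
        ep = ep[ep["group"] != "inhibitor_alone"]
        with pytest.raises(ValueError, match="inhibitor_alone"):
            cypddi.fit_synergistic(ep)

    def test_covariate_fit_recovers_theta_under_confounding(self):
        df = cypddi.simulate_exposure_groups(
            15_000, 15_000, 5_000, risk1=0.02, risk2=0.02, theta=2.0,
            with_covariates=True, seed=3,
        )
        res = cypddi.fit_synergistic(df, covariates=("age", "sex"))
        assert res.covariates_used == ("age", "sex")
        assert abs(res.rr - 2.0) / 2.0 < 0.15
        assert res.p_value < 1e-4

    def test_zero_joint_events_do_not_reject(self):
        ep = _episodes_from_counts(5, 100, 8, 120, 0, 60)
        res = cypddi.fit_synergistic(ep)
        assert res.p_value == 1.0

    def test_bootstrap_and_delta_agree_on_decisions(self):
        """Rejection decisions agree on >=95% of simulated datasets."""
        rng = np.random.default_rng(42)
        agree = 0
        n_sets = 60
        for k in range(n_sets):
            theta = 2.0 if k % 2 else 1.0
            m1 = rng.binomial(5000, 0.02)
            m2 = rng.binomial(5000, 0.02)
            m12 = rng.binomial(500, theta * 0.04)
            ep_counts = (int(m1), 5000, int(m2), 5000, int(m12), 500)
            ep = _episodes_from_counts(*ep_counts)
            delta = cypddi.fit_synergistic(ep, method="delta")
            boot = cypddi.fit_synergistic(ep, method="bootstrap", n_boot=500, seed=k)
            agree += (delta.p_value < 0.05) == (boot.p_value < 0.05)
        assert agree / n_sets >= 0.95


class TestFitAdditive:
    def test_missing_joint_group_is_error(self):
        ep = _episodes_from_counts(5, 100, 8, 120, 9, 60)
        ep = ep[ep["group"] != "joint"]
        with pytest.raises(ValueError, match="joint"):
            cypddi.fit_additive(ep)

    def test_closed_form_matches_regression(self):
        ep = _episodes_from_counts(20, 400, 10, 300, 30, 200)
        fast = cypddi.fit_additive(ep)
        # independent check: 2x2 Wald from the contingency table
        a, b, c, d = 30, 170, 20, 380
        assert fast.or_joint_vs_substrate == pytest.approx(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.log(a * d / (b * c)) / se
        assert fast.p_value == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_separation_flagged_with_fallback(self):
        ep = _episodes_from_counts(5, 100, 2, 50, 30, 30)  # joint all events
        ep["age_at_anchor"] = np.linspace(20, 60, len(ep))
        res = cypddi.fit_additive(ep, covariates=("age",))
        assert "separation_penalized_fallback" in res.flags or np.isfinite(res.p_value)

    def test_detects_injected_effect(self):
        df = cypddi.simulate_exposure_groups(
            4000, 100, 4000, risk1=0.05, risk2=0.0, theta=3.0, seed=5
        )
        res = cypddi.fit_additive(df)
        assert res.or_joint_vs_substrate > 1
        assert res.p_value < 1e-6


class TestEnrichment:
    def _results(self, spec):
        out = []
        for i, (p, rr) in enumerate(spec):
            out.append(
                cypddi.DDITestResult(
                    pair=(f"d{i}", f"e{i}"), model="synergistic",
                    rr=rr, p_value=p,
                )
            )
        return out

    def test_exact_test_matches_hypergeometric_oracle(self):
        # 3/10 significant inside the enzyme vs 2/90 outside
        spec = [(1e-6, 2.0)] * 3 + [(0.5, 1.0)] * 7 + [(1e-6, 2.0)] * 2 + [(0.5, 1.0)] * 88
        results = self._results(spec)
        enzyme_map = {r.pair: ["CYP2D6"] for r in results[:10]}
        enzyme_map.update({r.pair: ["CYP3A4/5"] for r in results[10:]})
        out = {e.enzyme: e for e in cypddi.enzyme_enrichment(results, enzyme_map, 0.05)}
        e = out["CYP2D6"]
        assert (e.n_sig_in, e.n_in, e.n_sig_out, e.n_out) == (3, 10, 2, 90)
        # oracle: hypergeometric tail P(X >= 3) with 5 significant among 100
        oracle = sps.hypergeom.sf(2, 100, 5, 10)
        assert e.p_value == pytest.approx(oracle, rel=1e-10)

    def test_extreme_concentration_minimizes_p(self):
        spec = [(1e-6, 2.0)] * 5 + [(0.5, 1.0)] * 45
        results = self._results(spec)
        enzyme_map = {r.pair: ["CYP2D6"] for r in results[:5]}
        enzyme_map.update({r.pair: ["CYP2C9"] for r in results[5:]})
        out = cypddi.enzyme_enrichment(results, enzyme_map, 0.05)
        best = min(out, key=lambda e: e.p_value)
        assert best.enzyme == "CYP2D6"

    def test_direction_requirement(self):
        # tiny p but protective direction: not counted as significant
        results = self._results([(1e-9, 0.5), (0.5, 1.0)])
        enzyme_map = {r.pair: ["CYP2D6"] for r in results}
        out = cypddi.enzyme_enrichment(results, enzyme_map, 0.05)
        assert out[0].n_sig_in == 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            cypddi.enzyme_enrichment([], {}, 1.5)


class TestPower:
    def test_null_power_equals_directional_size(self):
        # rejection = two-sided p < alpha AND RR > 1, so the null rejection
        # rate is alpha/2 (the upper tail only)
        pe = cypddi.power_simulation(
            2000, 2000, 2000, (0.05, 0.05), rr_alt=1.0, alpha=0.05,
            n_reps=2000, seed=1,
        )
        envelope = 1.96 * np.sqrt(0.025 * 0.975 / 2000)
        assert abs(pe.power - 0.025) < envelope + 0.005

    def test_monotone_in_joint_group_size(self):
        powers = [
            cypddi.power_simulation(
                5000, 5000, n12, (0.02, 0.02), rr_alt=2.0, alpha=0.05,
                n_reps=1500, seed=2,
            ).power
            for n12 in (50, 200, 800)
        ]
        assert powers[0] <= powers[1] <= powers[2]

    def test_small_reps_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cypddi.stats"):
            cypddi.power_simulation(100, 100, 100, (0.1, 0.1), 2.0, 0.05,
                                    n_reps=50, seed=3)
        assert any("noisy" in r.message for r in caplog.records)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            cypddi.power_simulation(0, 10, 10, (0.1, 0.1), 2.0, 0.05)

    def test_vectorized_test_matches_fit_synergistic(self):
        """The power loop's Wald test equals the covariate-free model fit."""
        m1, n1, m2, n2, m12, n12 = 37, 1000, 45, 1200, 21, 300
        rr, p = _wald_logrr_from_counts(m1, n1, m2, n2, m12, n12)
        res = cypddi.fit_synergistic(_episodes_from_counts(m1, n1, m2, n2, m12, n12))
        assert res.rr == pytest.approx(rr)
        assert res.p_value == pytest.approx(p)
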