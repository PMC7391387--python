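import math

import numpy as np
import pytest

from oracles import markov_probability, quadrature_probability
from osteorisk.frax import (
    RiskProfile,
    first_event_decomposition,
    fracture_probability,
    impute_mof_incidence,
    lifetime_probability,
    probability_table,
)
from osteorisk.lifetable import HazardSchedule, schedule_from_rate_table, zero_schedule
from osteorisk.synthetic import simulate_mortality
from osteorisk.tables import AgeSexBand, BandError, RateTable, RatioTable, five_year_bands

FEMALE_HIP_PER_100K = [13, 59, 60, 145, 176, 630, 670, 993, 1729, 2750, 3571]


def female_hip_rates():
    return RateTable(
        {b: r / 1e5 for b, r in zip(five_year_bands("female"), FEMALE_HIP_PER_100K)}
    )


def female_gompertz_mortality():
    return simulate_mortality("gompertz", {"a": 1e-4, "b": 0.09}, five_year_bands("female"))


def const(sex, h):
    return HazardSchedule(sex, [0.0, 110.0], [h])


class TestImputeMof:
    def test_band_product(self):
        hip = RateTable({AgeSexBand("female", 65, 70): 630 / 1e5})
        rho = RatioTable({AgeSexBand("female", 65, 70): 4.0})
        mof = impute_mof_incidence(hip, rho)
        assert mof[AgeSexBand("female", 65, 70)] == pytest.approx(2520 / 1e5, rel=1e-12)

    def test_unit_ratio_is_identity(self):
        hip = female_hip_rates()
        rho = RatioTable({b: 1.0 for b in hip})
        assert impute_mof_incidence(hip, rho) == hip

    def test_elementwise_against_numpy_oracle(self):
        hip = female_hip_rates()
        rng = np.random.default_rng(5)
        rhos = 1.0 + 4.0 * rng.random(len(FEMALE_HIP_PER_100K))
        rho = RatioTable({b: r for b, r in zip(five_year_bands("female"), rhos)})
        mof = impute_mof_incidence(hip, rho)
        expected = np.asarray([hip[b] for b in hip]) * np.asarray([rho[b] for b in hip])
        got = np.asarray([mof[b] for b in hip])
        np.testing.assert_allclose(got, expected, rtol=1e-14)

    def test_band_mismatch_lists_bands(self):
        hip = female_hip_rates()
        rho = RatioTable({AgeSexBand("female", 65, 70): 2.0})
        with pytest.raises(BandError, match="mismatched"):
            impute_mof_incidence(hip, rho)


class TestFractureProbability:
    def test_constant_hazard_closed_form(self):
        res = fracture_probability(const("female", 0.01), const("female", 0.05), 60, 10)
        expected = (0.01 / 0.06) * (1 - math.exp(-0.6))
        assert res.probability == pytest.approx(expected, rel=1e-14)
        assert round(res.probability, 5) == 0.07520

    def test_no_competing_risk_pure_exponential(self):
        res = fracture_probability(const("male", 0.01), zero_schedule("male"), 60, 10)
        assert res.probability == pytest.approx(1 - math.exp(-0.1), rel=1e-14)

    def test_rr_applies_to_fracture_hazard_exactly(self):
        rr = 1.85
        res = fracture_probability(
            const("male", 0.01), zero_schedule("male"), 60, 10, RiskProfile(rr)
        )
        assert res.probability == pytest.approx(1 - math.exp(-rr * 0.1), rel=1e-14)

    def test_rr_submultiplicative_under_competing_risk(self):
        f, d = const("female", 0.01), const("female", 0.05)
        p1 = fracture_probability(f, d, 60, 10, RiskProfile(1.0)).probability
        p2 = fracture_probability(f, d, 60, 10, RiskProfile(2.0)).probability
        assert p2 > p1
        assert p2 < 2 * p1

    def test_agreement_with_quadrature_oracle(self):
        sched_f = schedule_from_rate_table(female_hip_rates(), "female", 110)
        sched_d = schedule_from_rate_table(female_gompertz_mortality(), "female", 110)
        for age, horizon, rr in [(50, 10, 1.0), (62.5, 10, 2.0), (70, 25, 1.3), (40, 70, 1.0)]:
            ours = fracture_probability(
                sched_f, sched_d, age, horizon, RiskProfile(rr)
            ).probability
            oracle = quadrature_probability(sched_f, sched_d, age, horizon, rr)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_agreement_with_markov_chain_oracle(self):
        sched_f = schedule_from_rate_table(female_hip_rates(), "female", 110)
        sched_d = schedule_from_rate_table(female_gompertz_mortality(), "female", 110)
        ours = fracture_probability(sched_f, sched_d, 70, 10).probability
        oracle = markov_probability(sched_f, sched_d, 70, 10, dt=1e-4)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_conservation_to_1e12(self):
        sched_f = schedule_from_rate_table(female_hip_rates(), "female", 110)
        sched_d = schedule_from_rate_table(female_gompertz_mortality(), "female", 110)
        for age, horizon in [(50, 10), (40, 70), (90, 20)]:
            p_f, p_d, s, _ = first_event_decomposition(sched_f, sched_d, age, horizon)
            assert p_f + p_d + s == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_horizon(self):
        sched_f = schedule_from_rate_table(female_hip_rates(), "female", 110)
        sched_d = schedule_from_rate_table(female_gompertz_mortality(), "female", 110)
        probs = [
            fracture_probability(sched_f, sched_d, 50, h).probability for h in range(0, 61, 5)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[0] == 0.0

    def test_monotone_in_fracture_and_death_hazards(self):
        f, d = const("female", 0.01), const("female", 0.05)
        base = fracture_probability(f, d, 60, 10).probability
        more_f = fracture_probability(const("female", 0.012), d, 60, 10).probability
        more_d = fracture_probability(f, const("female", 0.08), 60, 10).probability
        assert more_f > base
        assert more_d < base

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            fracture_probability(const("male", 0.01), const("male", 0.05), 60, -1)

    def test_span_outside_schedules_rejected(self):
        with pytest.raises(ValueError, match="support"):
            fracture_probability(const("male", 0.01), const("male", 0.05), 105, 10)

    def test_mismatched_sexes_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            fracture_probability(const("male", 0.01), const("female", 0.05), 60, 10)


class TestLifetimeProbability:
    def test_constant_hazard_closed_form(self):
        res = lifetime_probability(const("male", 0.002), const("male", 0.02), 50)
        expected = (0.002 / 0.022) * (1 - math.exp(-0.022 * 60))
        assert res.probability == pytest.approx(expected, rel=1e-14)
        assert round(res.probability, 5) == 0.06662
        assert res.horizon == "lifetime"

    def test_zero_fracture_hazard_gives_zero(self):
        res = lifetime_probability(zero_schedule("male"), const("male", 0.02), 50)
        assert res.probability == 0.0

    def test_matches_quadrature_oracle(self):
        sched_f = schedule_from_rate_table(female_hip_rates(), "female", 110)
        sched_d = schedule_from_rate_table(female_gompertz_mortality(), "female", 110)
        ours = lifetime_probability(sched_f, sched_d, 50).probability
        oracle = quadrature_probability(sched_f, sched_d, 50, 60)
        assert ours == pytest.approx(oracle, abs=1e-10)
        assert 0 < ours < 1

    def test_start_at_terminal_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            lifetime_probability(const("male", 0.01), const("male", 0.02), 110)


class TestProbabilityTable:
    def _inputs(self):
        hip = {}
        rho = {}
        mort = {}
        for sex in ("male", "female"):
            scale = 1.0 if sex == "female" else 0.66
            for b, r in zip(five_year_bands(sex), FEMALE_HIP_PER_100K):
                hip[b] = scale * r / 1e5
                rho[b] = 3.0
            for b, m in simulate_mortality(
                "gompertz", {"a": 1e-4, "b": 0.09}, five_year_bands(sex)
            ).items():
                mort[b] = m
        return RateTable(hip), RatioTable(rho), RateTable(mort)

    def test_cardinality(self):
        hip, rho, mort = self._inputs()
        results = probability_table(hip, rho, mort, [50, 60, 70, 80], 10.0)
        assert len(results) == 16  # 2 outcomes x 2 sexes x 4 ages

    def test_mof_dominates_hip_for_random_ratio_tables(self):
        hip, _, mort = self._inputs()
        rng = np.random.default_rng(99)
        for _ in range(200):
            rho = RatioTable({b: 1.0 + 6.0 * rng.random() for b in hip})
            results = probability_table(hip, rho, mort, [55, 75], 10.0)
            by_key = {(r.sex, r.start_age, r.outcome): r.probability for r in results}
            for sex in ("male", "female"):
                for age in (55, 75):
                    assert by_key[(sex, age, "MOF")] >= by_key[(sex, age, "hip")]

    def test_raising_hip_rates_raises_every_hip_probability(self):
        hip, rho, mort = self._inputs()
        bumped = RateTable({b: 1.1 * v for b, v in hip.items()})
        base = probability_table(hip, rho, mort, [50, 60, 70, 80], 10.0)
        more = probability_table(bumped, rho, mort, [50, 60, 70, 80], 10.0)
        for r0, r1 in zip(base, more):
            if r0.outcome == "hip":
                assert r1.probability > r0.probability

    def test_lifetime_horizon_supported(self):
        hip, rho, mort = self._inputs()
        results = probability_table(hip, rho, mort, [50], "lifetime")
        assert all(r.horizon == "lifetime" for r in results)
        assert all(0 < r.probability < 1 for r in results)
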