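import math

import numpy as np
import pytest

from herdsim.animals import AnimalClass, AnimalState, CowState
from herdsim.config import HerdConfig, ProtocolConfig, ReproProtocolConfig
from herdsim.lifecycle import (
    breed,
    conceptus_growth,
    conceptus_weight_total,
    cull_update,
    lactation_bw_change,
    pregnancy_update,
    schedule_estrus,
    simulate_birth,
    target_adg,
    wood_milk,
)
from herdsim.rng import BoundedDistribution, RandomStreams


# ---------------------------------------------------------------------------
# Conceptus mass and growth
# ---------------------------------------------------------------------------


class TestConceptus:
    def test_total_weight_hand_value(self):
        # (0.0148*279 - 2.408) * 40 = 68.848
        assert conceptus_weight_total(279, 40) == pytest.approx(68.848, abs=0.01)

    def test_total_weight_zero_calf(self):
        assert conceptus_weight_total(279, 0) == 0.0

    def test_literal_grouping_goes_negative(self):
        assert conceptus_weight_total(279, 40, literal=True) == pytest.approx(-92.19, abs=0.01)

    def test_growth_zero_through_day_50(self):
        assert conceptus_growth(50, 279, 68.85) == 0.0
        assert conceptus_growth(10, 279, 68.85) == 0.0

    def test_growth_at_term_hand_value(self):
        # 3 * W / (GL - 50) at t = GL
        assert conceptus_growth(279, 279, 68.85) == pytest.approx(3 * 68.85 / 229, rel=1e-12)

    def test_daily_growth_integrates_to_total_weight(self):
        gl, w = 279, conceptus_weight_total(279, 42)
        total = sum(conceptus_growth(t, gl, w) for t in range(51, gl + 1))
        assert total == pytest.approx(w, rel=0.01)

    def test_short_gestation_rejected(self):
        with pytest.raises(ValueError):
            conceptus_growth(10, 50, 60.0)


# ---------------------------------------------------------------------------
# Lactation body-weight change and milk
# ---------------------------------------------------------------------------


class TestLactationBW:
    @pytest.mark.parametrize("dim, parity", [(65, 1), (70, 2)])
    def test_zero_crossing_at_curve_midpoint(self, dim, parity):
        assert lactation_bw_change(dim, parity) == pytest.approx(0.0, abs=1e-12)

    def test_day_zero_mobilisation(self):
        assert lactation_bw_change(0, 1) == pytest.approx(-(20 / 65) * math.e, rel=1e-12)

    def test_dry_cows_have_no_lactation_tissue_change(self):
        assert lactation_bw_change(100, 2, lactating=False) == 0.0

    def test_cumulative_change_over_full_lactation_is_near_zero(self):
        # The analytic integral over [0, inf) is exactly 0; the daily-step sum
        # carries a discretization residual bounded by ~|f(0)|/2 plus the tail
        # beyond day 500.  Total mobilised mass is s (20 or 40 kg), so require
        # the residual to be < 5% of it.
        for parity, mobilised in ((1, 20.0), (2, 40.0)):
            cum = sum(lactation_bw_change(t, parity) for t in range(0, 500))
            assert abs(cum) < 0.05 * mobilised


class TestWoodMilk:
    def test_flat_curve(self):
        assert wood_milk(100, 30.0, 0.0, 0.0) == 30.0

    def test_peak_at_b_over_c(self):
        a, b, c = 17.5, 0.22, 0.003
        days = np.arange(1, 500)
        yields = [wood_milk(d, a, b, c) for d in days]
        assert days[int(np.argmax(yields))] == pytest.approx(b / c, abs=1.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            wood_milk(10, -1.0, 0.2, 0.003)


# ---------------------------------------------------------------------------
# Growth targets
# ---------------------------------------------------------------------------


class TestTargetADG:
    def test_heifer_gain_toward_first_pregnancy_milestone(self):
        herd = HerdConfig()
        a = AnimalState(id=1, birth_day=-300, bw=100.0, mature_bw=625.0,
                        animal_class=AnimalClass.HEIFER_I, breeding_day=400)
        # milestone: 0.55 * mature full BW = 343.75 kg in 400 days
        assert target_adg(a, 0, herd) == pytest.approx((0.55 * 625 - 100) / 400)

    def test_at_milestone_day_gain_is_zero(self):
        herd = HerdConfig()
        a = AnimalState(id=1, birth_day=-400, bw=330.0, mature_bw=600.0,
                        animal_class=AnimalClass.HEIFER_II, breeding_day=0)
        assert target_adg(a, 0, herd) == 0.0

    def test_second_parity_cow_targets_full_mature_weight(self):
        herd = HerdConfig()
        a = AnimalState(id=1, birth_day=-1400, bw=0.92 * 680, mature_bw=680.0,
                        parity=2, animal_class=AnimalClass.COW,
                        cow_state=CowState.LACTATING, last_calving_day=0)
        adg = target_adg(a, 0, herd)
        assert adg == pytest.approx(0.08 * 680 / herd.estimated_lactation_length)

    def test_mature_cow_stops_growing(self):
        herd = HerdConfig()
        a = AnimalState(id=1, birth_day=-2000, bw=690.0, mature_bw=680.0,
                        parity=4, animal_class=AnimalClass.COW,
                        cow_state=CowState.LACTATING)
        assert target_adg(a, 0, herd) == 0.0


# ---------------------------------------------------------------------------
# Stochastic events
# ---------------------------------------------------------------------------


def _repro(**kw):
    return ReproProtocolConfig(**kw)


class TestBirth:
    def test_all_female_kept_when_rate_is_one(self):
        herd = HerdConfig(stillbirth_probability=0.0, female_calf_probability=1.0,
                          keep_female_calf_rate=1.0)
        streams = RandomStreams(0)
        dam = AnimalState(id=1, parity=2, animal_class=AnimalClass.COW)
        calf = simulate_birth(dam, herd, streams, sim_day=10, calf_id=99)
        assert calf is not None and calf.birth_day == 10 and calf.sex == "F"

    def test_certain_stillbirth_yields_no_calf(self):
        herd = HerdConfig(stillbirth_probability=1.0)
        streams = RandomStreams(0)
        dam = AnimalState(id=1, parity=2, animal_class=AnimalClass.COW)
        assert simulate_birth(dam, herd, streams, 0, 99) is None

    def test_sex_ratio_binomial(self):
        herd = HerdConfig(stillbirth_probability=0.0, female_calf_probability=0.5,
                          keep_female_calf_rate=1.0)
        streams = RandomStreams(5)
        dam = AnimalState(id=1, parity=2, animal_class=AnimalClass.COW)
        females = sum(
            simulate_birth(dam, herd, streams, 0, i) is not None
            for i in range(10_000)
        )
        assert abs(females - 5000) < 150  # 3 sigma of Binomial(1e4, .5)


class TestEstrusAndBreeding:
    def test_timed_ai_is_deterministic_and_consumes_no_draws(self):
        streams = RandomStreams(0)
        before = streams.lifecycle.bit_generator.state
        protocol = ProtocolConfig(protocol="timed_ai", tai_service_interval=42)
        a = AnimalState(id=1)
        day = schedule_estrus(a, protocol, _repro(), streams, 100)
        assert day == 142
        assert streams.lifecycle.bit_generator.state == before

    def test_degenerate_cycle_length(self):
        streams = RandomStreams(0)
        repro = _repro(estrous_cycle=BoundedDistribution(21.0, 0.0, 18.0, 25.0))
        protocol = ProtocolConfig(estrus_detection_probability=1.0)
        assert schedule_estrus(AnimalState(id=1), protocol, repro, streams, 50) == 71

    def test_synchronized_first_service_is_common_to_all_animals(self):
        repro = _repro()
        protocol = ProtocolConfig(protocol="synch_estrus_detection",
                                  synch_first_service_delay=10)
        days = set()
        for i in range(20):
            streams = RandomStreams(i)
            days.add(schedule_estrus(AnimalState(id=i), protocol, repro, streams,
                                     200, first_service=True))
        assert days == {210}

    def test_certain_conception(self):
        streams = RandomStreams(0)
        protocol = ProtocolConfig(conception_probability=1.0)
        a = AnimalState(id=1)
        assert breed(a, protocol, _repro(), BoundedDistribution(42, 0, 30, 55),
                     streams, 0)
        assert a.days_in_pregnancy == 1
        assert 266 <= a.gestation_length <= 294
        assert a.expected_calf_bw == 42.0

    def test_impossible_conception_reschedules(self):
        streams = RandomStreams(0)
        protocol = ProtocolConfig(conception_probability=0.0)
        a = AnimalState(id=1)
        assert not breed(a, protocol, _repro(), BoundedDistribution(42, 0, 30, 55),
                         streams, 100)
        assert a.days_in_pregnancy == 0 and a.breeding_day > 100

    def test_conception_rate_binomial(self):
        streams = RandomStreams(9)
        protocol = ProtocolConfig(conception_probability=0.4)
        dist = BoundedDistribution(42, 0, 30, 55)
        wins = 0
        for i in range(10_000):
            a = AnimalState(id=i)
            wins += breed(a, protocol, _repro(), dist, streams, 0)
        assert abs(wins - 4000) < 150


class TestPregnancy:
    def _pregnant(self, i=1):
        return AnimalState(id=i, days_in_pregnancy=1, gestation_length=279,
                           expected_calf_bw=42.0, parity=1,
                           animal_class=AnimalClass.COW, cow_state=CowState.LACTATING)

    def test_zero_loss_rate_reaches_term(self):
        repro = _repro(pregnancy_loss_rate=0.0)
        streams = RandomStreams(0)
        a = self._pregnant()
        outcomes = {pregnancy_update(a, repro.cow, repro, streams, d)
                    for d in range(2, 279)}
        assert outcomes == {"pregnant"}
        assert pregnancy_update(a, repro.cow, repro, streams, 279) == "term"

    def test_certain_loss_aborts_at_first_check(self):
        repro = _repro(pregnancy_loss_rate=1.0)
        streams = RandomStreams(0)
        a = self._pregnant()
        for d in range(2, 100):
            status = pregnancy_update(a, repro.cow, repro, streams, d)
            if status == "aborted":
                break
        assert status == "aborted"
        assert a.days_in_pregnancy == 0 and a.breeding_day > 0

    def test_total_loss_rate_matches_three_check_compounding(self):
        """Per-check q with (1-q)^3 = 1 - L gives ~27.1% losses for q=0.1."""
        repro = _repro(pregnancy_loss_rate=1 - 0.9 ** 3)
        assert repro.per_check_loss == pytest.approx(0.1)
        streams = RandomStreams(13)
        losses = 0
        for i in range(10_000):
            a = self._pregnant(i)
            for d in range(2, 280):
                status = pregnancy_update(a, repro.cow, repro, streams, d)
                if status != "pregnant":
                    break
            losses += status == "aborted"
        assert abs(losses - 2710) < 150


class TestCulling:
    def test_no_hazards_no_rules_no_culls(self):
        from herdsim.config import CullingConfig

        herd = HerdConfig(culling=CullingConfig(annual_probabilities={}))
        streams = RandomStreams(0)
        cow = AnimalState(id=1, parity=2, animal_class=AnimalClass.COW,
                          cow_state=CowState.LACTATING, dim=100)
        assert all(cull_update(cow, herd, streams, d) is None for d in range(365))

    def test_open_heifer_past_cull_age_removed_for_reproduction(self):
        herd = HerdConfig(heifer_repro_cull_age=700)
        streams = RandomStreams(0)
        heifer = AnimalState(id=1, birth_day=-701,
                             animal_class=AnimalClass.HEIFER_II)
        assert cull_update(heifer, herd, streams, 0) == "reproduction_failure"

    def test_annual_hazard_reproduces_expected_cull_count(self):
        """N cow-years at total annual hazard h -> ~N*h culls (binomial CI)."""
        herd = HerdConfig()
        h = sum(herd.culling.annual_probabilities.values())
        streams = RandomStreams(21)
        n = 1000
        culled = 0
        for i in range(n):
            cow = AnimalState(id=i, parity=2, animal_class=AnimalClass.COW,
                              cow_state=CowState.LACTATING, dim=100)
            for d in range(365):
                if cull_update(cow, herd, streams, d) is not None:
                    culled += 1
                    break
        expected = n * (1 - (1 - h / 365) ** 365)
        assert abs(culled - expected) < 3.5 * math.sqrt(expected)
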