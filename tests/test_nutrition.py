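import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herdsim.animals import AnimalClass, AnimalState, CowState
from herdsim.config import FeedLibraryEntry, HerdConfig, RationConfig, default_config
from herdsim.nutrition import (
    FAT_MAX_PCT,
    FORAGE_NDF_MIN_PCT,
    NDF_MAX_PCT,
    NDF_MIN_PCT,
    InfeasibleRationError,
    NutrientRequirements,
    calf_allowable_gain,
    calf_milk_intake,
    formulate_ration,
    pen_average,
    requirements,
    starter_intake,
)


# ---------------------------------------------------------------------------
# Calf feeding
# ---------------------------------------------------------------------------


class TestCalfFeeding:
    def test_pre_weaning_allowance_is_ten_percent_of_birth_weight(self):
        assert calf_milk_intake(40.0, age=10, weaning_day=56, weaning_period=14) == 4.0

    def test_allowance_zero_at_weaning_day(self):
        assert calf_milk_intake(40.0, age=56, weaning_day=56, weaning_period=14) == 0.0

    def test_linear_ramp_decrement(self):
        steps = [calf_milk_intake(40.0, a, 56, 14) for a in range(42, 57)]
        decrements = np.diff(steps)
        assert np.allclose(decrements, -4.0 / 14)

    def test_starter_continuity_at_breakpoint(self):
        low = starter_intake(69.365 - 1e-9)
        high = starter_intake(69.365 + 1e-9)
        assert low == pytest.approx(0.0960, abs=2e-4)
        assert high == pytest.approx(low, abs=2e-4)

    def test_starter_hand_value_above_breakpoint(self):
        assert starter_intake(100.0) == pytest.approx(2.8882, abs=1e-3)

    def test_starter_clamped_below_zero_crossing(self):
        assert starter_intake(40.0) == 0.0  # raw value would be -0.0495

    @given(st.floats(min_value=1.0, max_value=300.0))
    def test_starter_never_negative_and_monotone(self, bw):
        assert starter_intake(bw) >= 0.0
        assert starter_intake(bw + 1.0) >= starter_intake(bw)

    def test_allowable_gain_is_minimum_of_energy_and_protein(self):
        # generous milk energy but diluted protein: protein should govern
        g = calf_allowable_gain(milk_dm=0.8, starter_dm=0.0, bw=45.0)
        energy_only = calf_allowable_gain(milk_dm=0.8, starter_dm=2.0, bw=45.0)
        assert g <= energy_only

    def test_zero_intake_gives_negative_gain(self):
        assert calf_allowable_gain(0.0, 0.0, 45.0) < 0.0

    def test_doubling_intake_never_decreases_gain(self):
        for milk, starter, bw in itertools.product([0.3, 0.6], [0.0, 0.5], [45, 70]):
            g1 = calf_allowable_gain(milk, starter, bw)
            g2 = calf_allowable_gain(2 * milk, 2 * starter, bw)
            assert g2 >= g1


# ---------------------------------------------------------------------------
# Requirements
# ---------------------------------------------------------------------------


def _cow(bw=650.0, dim=120, parity=2, dip=0):
    return AnimalState(id=1, birth_day=-1500, bw=bw, mature_bw=680.0,
                       parity=parity, dim=dim, days_in_pregnancy=dip,
                       gestation_length=279 if dip else 0,
                       expected_calf_bw=42.0 if dip else 0.0,
                       animal_class=AnimalClass.COW,
                       cow_state=CowState.LACTATING if dim else CowState.DRY)


class TestRequirements:
    herd = HerdConfig()

    def test_dry_open_zero_gain_cow_has_maintenance_only(self):
        cow = _cow(dim=0)
        cow.cow_state = CowState.DRY
        req = requirements(cow, milk=0.0, herd_cfg=self.herd, adg=0.0)
        assert req.ne == pytest.approx(0.080 * 650 ** 0.75)
        assert req.mp == pytest.approx(3.8 * 650 ** 0.75)

    def test_requirements_increase_with_milk(self):
        cow = _cow()
        reqs = [requirements(cow, milk, self.herd, adg=0.0)
                for milk in (10.0, 20.0, 30.0, 40.0)]
        for lo, hi in zip(reqs, reqs[1:]):
            assert hi.ne > lo.ne and hi.mp > lo.mp
            assert hi.ca > lo.ca and hi.p > lo.p

    def test_maintenance_scales_with_metabolic_body_weight(self):
        r1 = requirements(_cow(bw=300.0, dim=0), 0.0, self.herd, 0.0)
        r2 = requirements(_cow(bw=600.0, dim=0), 0.0, self.herd, 0.0)
        assert r2.ne / r1.ne == pytest.approx(2 ** 0.75, rel=1e-9)


class TestPenAverage:
    def _req(self, ne):
        return NutrientRequirements(ne=ne, mp=1000.0, ca=80.0, p=50.0,
                                    expected_dmi=20.0, estimated_milk=30.0)

    def test_single_animal_is_identity(self):
        req = self._req(30.0)
        assert pen_average([req]).ne == req.ne

    def test_two_animal_mean(self):
        assert pen_average([self._req(30.0), self._req(40.0)]).ne == 35.0

    def test_lead_factor_scales_nutrients_not_intake(self):
        avg = pen_average([self._req(30.0)], lead_factor=1.1)
        assert avg.ne == pytest.approx(33.0)
        assert avg.expected_dmi == 20.0

    def test_empty_pen_rejected(self):
        with pytest.raises(ValueError):
            pen_average([])


# ---------------------------------------------------------------------------
# Least-cost formulation
# ---------------------------------------------------------------------------


def _feed(name, price, nel=1.5, mp=80, ndf=30.0, forage=True, fat=3.0,
          ca=0.5, p=0.35, max_inclusion=math.inf):
    return FeedLibraryEntry(name=name, price=price, dm=0.5, nel=nel, mp=mp,
                            cp=12.0, ndf=ndf, forage=forage, fat=fat, ca=ca,
                            p=p, starch=20.0, max_inclusion=max_inclusion)


TOY_FEEDS = [
    _feed("cheap_forage", 0.06, nel=1.40, mp=50, ndf=48.0, forage=True),
    _feed("dear_protein", 0.40, nel=2.00, mp=320, ndf=10.0, forage=False),
]


def _brute_force(req, feeds, step=0.01):
    """Exhaustive grid search over a 2-feed ration (total DM fixed)."""
    best = None
    dmi = req.expected_dmi
    x1 = np.arange(0.0, dmi + step, step)
    x2 = dmi - x1
    ok = x2 >= -1e-12
    x1, x2 = x1[ok], np.maximum(x2[ok], 0.0)
    f1, f2 = feeds
    ne = x1 * f1.nel + x2 * f2.nel
    mp = x1 * f1.mp + x2 * f2.mp
    ca = x1 * f1.ca * 10 + x2 * f2.ca * 10
    p = x1 * f1.p * 10 + x2 * f2.p * 10
    ndf = (x1 * f1.ndf + x2 * f2.ndf) / dmi
    fndf = (x1 * (f1.ndf if f1.forage else 0) + x2 * (f2.ndf if f2.forage else 0)) / dmi
    fat = (x1 * f1.fat + x2 * f2.fat) / dmi
    feasible = ((ne >= req.ne) & (mp >= req.mp) & (ca >= req.ca) & (p >= req.p)
                & (ndf >= NDF_MIN_PCT) & (ndf <= NDF_MAX_PCT)
                & (fndf >= FORAGE_NDF_MIN_PCT) & (fat <= FAT_MAX_PCT))
    cost = x1 * f1.price + x2 * f2.price
    cost[~feasible] = np.inf
    i = int(np.argmin(cost))
    return cost[i], x1[i], x2[i]


class TestFormulation:
    def test_single_feed_one_dimensional_feasibility(self):
        feed = _feed("complete", 0.10, nel=1.5, mp=100, ndf=30.0)
        req = NutrientRequirements(ne=30.0, mp=1800.0, ca=80.0, p=50.0,
                                   expected_dmi=20.0)
        ration = formulate_ration(req, [feed])
        assert ration.amounts[0] == pytest.approx(20.0, rel=1e-6)
        assert ration.cost == pytest.approx(2.0, rel=1e-6)

    def test_two_feed_toy_matches_brute_force_grid(self):
        req = NutrientRequirements(ne=28.0, mp=1500.0, ca=60.0, p=40.0,
                                   expected_dmi=20.0, estimated_milk=25.0)
        ration = formulate_ration(req, TOY_FEEDS)
        best_cost, x1, x2 = _brute_force(req, TOY_FEEDS)
        assert math.isfinite(best_cost)
        assert ration.cost <= best_cost * 1.001  # within 0.1% of the grid optimum

    def test_optimum_not_beaten_by_random_feasible_sampling(self):
        rng = np.random.default_rng(0)
        req = NutrientRequirements(ne=28.0, mp=1500.0, ca=60.0, p=40.0,
                                   expected_dmi=20.0, estimated_milk=25.0)
        ration = formulate_ration(req, TOY_FEEDS)
        f1, f2 = TOY_FEEDS
        beaten = 0
        for x1 in rng.uniform(0, 20.0, size=1000):
            x2 = 20.0 - x1
            ne = x1 * f1.nel + x2 * f2.nel
            mp = x1 * f1.mp + x2 * f2.mp
            ndf = (x1 * f1.ndf + x2 * f2.ndf) / 20.0
            fndf = x1 * f1.ndf / 20.0
            if (ne >= req.ne and mp >= req.mp and NDF_MIN_PCT <= ndf <= NDF_MAX_PCT
                    and fndf >= FORAGE_NDF_MIN_PCT):
                cost = x1 * f1.price + x2 * f2.price
                beaten += cost < ration.cost * (1 - 1e-9)
        assert beaten == 0

    def test_converged_ration_satisfies_all_constraints(self):
        cfg = default_config()
        feeds = [f for f in cfg.feeds if f.name not in ("milk_replacer", "calf_starter")]
        req = NutrientRequirements(ne=36.0, mp=2200.0, ca=132.0, p=84.0,
                                   expected_dmi=25.0, estimated_milk=35.0)
        r = formulate_ration(req, feeds)
        s = r.supplied
        tol = 1e-6 * 25.0
        assert abs(r.amounts.sum() - 25.0) < tol
        assert s["ne"] >= req.ne - tol and s["mp"] >= req.mp - tol
        assert NDF_MIN_PCT - 1e-6 <= s["ndf_pct"] <= NDF_MAX_PCT + 1e-6
        assert s["forage_ndf_pct"] >= FORAGE_NDF_MIN_PCT - 1e-6
        assert s["fat_pct"] <= FAT_MAX_PCT + 1e-6
        assert np.all(r.amounts >= -1e-12)
        for amount, feed in zip(r.amounts, feeds):
            assert amount <= feed.max_inclusion + 1e-9

    def test_impossible_milk_triggers_stepwise_reduction_then_converges(self):
        """An unmeetable energy demand steps milk down 0.5 kg at a time."""
        feeds = TOY_FEEDS
        # The fibre constraints cap achievable NE at ~35.25 Mcal for this
        # 20-kg toy, so a 45-Mcal demand is infeasible until enough milk
        # (0.715 Mcal/kg each) has been backed off.
        req = NutrientRequirements(ne=45.0, mp=500.0, ca=30.0, p=20.0,
                                   expected_dmi=20.0, estimated_milk=30.0)
        ration = formulate_ration(req, feeds, RationConfig(max_milk_reductions=40))
        assert ration.milk_reductions >= 1
        assert ration.supplied["ne"] >= req.ne - ration.milk_reductions * 0.5 * 0.715 - 1e-6

    def test_hard_infeasibility_names_binding_constraints(self):
        req = NutrientRequirements(ne=80.0, mp=500.0, ca=30.0, p=20.0,
                                   expected_dmi=20.0, estimated_milk=0.0)
        with pytest.raises(InfeasibleRationError, match="ne"):
            formulate_ration(req, TOY_FEEDS)

    def test_milk_reduction_is_monotone_in_requirements(self):
        req = NutrientRequirements(ne=36.0, mp=2200.0, ca=132.0, p=84.0,
                                   expected_dmi=25.0, estimated_milk=35.0)
        seq = [req]
        for _ in range(5):
            seq.append(seq[-1].with_milk_reduced(0.5))
        for lo, hi in zip(seq[1:], seq):
            assert lo.ne <= hi.ne and lo.mp <= hi.mp
            assert lo.ca <= hi.ca and lo.p <= hi.p
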