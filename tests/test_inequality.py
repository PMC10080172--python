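"""Age-at-event distributions and SD/CV/Gini statistics."""

import numpy as np
import pytest
from scipy import stats

import hli
from hli.inequality import (AgeAtEventDistribution, EmptyDistributionError,
                            condition_on_age, cv_age_at_event,
                            event_distribution, gini_age_at_event,
                            sd_age_at_event)
from hli.lifetable import build_life_table, recover_ax
from hli.morbidity import reconstruct_morbidity_curve, sullivan_hale
from hli.schedules import AbridgedSchedule

from conftest import make_random_life_table, make_random_lstar


def _two_point():
    """Half the population ceases to be healthy at 55, half at 75."""
    return AgeAtEventDistribution(
        x=np.array([55.0, 75.0]), mass=np.array([0.5, 0.5]),
        mean_age=np.array([55.0, 75.0]), kind="onset",
    )


class TestStatistics:
    def test_symmetric_two_point(self):
        res = sd_age_at_event(_two_point())
        assert res.mean == pytest.approx(65.0, abs=1e-14)
        assert res.sd == pytest.approx(10.0, abs=1e-14)
        assert res.cv == pytest.approx(10.0 / 65.0, abs=1e-14)
        # population Gini: mean absolute difference / (2 * mean)
        assert res.gini == pytest.approx(10.0 / 130.0, abs=1e-14)

    def test_degenerate_point_mass(self):
        d = AgeAtEventDistribution(np.array([65.0, 70.0]),
                                   np.array([1.0, 0.0]),
                                   np.array([65.0, 70.0]), "death")
        res = sd_age_at_event(d)
        assert res.sd == 0.0 and res.cv == 0.0 and res.gini == 0.0

    def test_moments_against_brute_force(self, rng):
        masses = rng.uniform(0.1, 1.0, 20)
        ages = np.sort(rng.uniform(0, 100, 20))
        wvar = rng.uniform(0, 4.0, 20)
        d = AgeAtEventDistribution(ages, masses, ages, "death", wvar)
        total = masses.sum()
        mu = sum(m * a for m, a in zip(masses, ages)) / total
        var = sum(m * ((a - mu) ** 2 + v)
                  for m, a, v in zip(masses, ages, wvar)) / total
        res = sd_age_at_event(d)
        assert res.mean == pytest.approx(mu, abs=1e-12)
        assert res.sd == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_gini_against_double_loop(self, rng):
        masses = rng.uniform(0.1, 1.0, 15)
        ages = np.sort(rng.uniform(10, 100, 15))
        d = AgeAtEventDistribution(ages, masses, ages, "death")
        w = masses / masses.sum()
        mu = float(w @ ages)
        brute = sum(w[i] * w[j] * abs(ages[i] - ages[j])
                    for i in range(15) for j in range(15)) / (2 * mu)
        assert gini_age_at_event(d) == pytest.approx(brute, abs=1e-12)

    def test_scale_properties(self, rng):
        masses = rng.uniform(0.1, 1.0, 10)
        ages = np.sort(rng.uniform(10, 100, 10))
        d = AgeAtEventDistribution(ages, masses, ages, "death")
        c = 3.7
        d_scaled = AgeAtEventDistribution(ages * c, masses, ages * c, "death")
        assert sd_age_at_event(d_scaled).sd == pytest.approx(
            c * sd_age_at_event(d).sd, rel=1e-12)
        assert cv_age_at_event(d_scaled) == pytest.approx(cv_age_at_event(d),
                                                          rel=1e-12)
        assert gini_age_at_event(d_scaled) == pytest.approx(
            gini_age_at_event(d), rel=1e-12)

    def test_mass_rescaling_invariance(self, rng):
        masses = rng.uniform(0.1, 1.0, 10)
        ages = np.sort(rng.uniform(10, 100, 10))
        a = AgeAtEventDistribution(ages, masses, ages, "death")
        b = AgeAtEventDistribution(ages, masses * 1e5, ages, "death")
        assert sd_age_at_event(a).sd == pytest.approx(sd_age_at_event(b).sd,
                                                      rel=1e-12)
        assert gini_age_at_event(a) == pytest.approx(gini_age_at_event(b),
                                                     rel=1e-12)


class TestEventDistribution:
    def test_first_differences(self):
        grid = np.array([0.0, 5.0, 10.0])
        lt = build_life_table(grid, np.array([0.2, 0.5, 1.0]),
                              np.array([2.5, 2.5, np.nan]), e_last=4.0)
        d = event_distribution(lt)
        assert np.allclose(d.mass, [0.2, 0.4, 0.4], atol=1e-15)
        assert d.kind == "death"

    def test_onset_equals_death_when_curves_match(self, rng):
        lt = make_random_life_table(rng)
        mc = reconstruct_morbidity_curve(
            lt, AbridgedSchedule(lt.x, lt.ex, "hale"), mode="strict")
        dd = event_distribution(lt)
        do = event_distribution(mc)
        assert do.kind == "onset"
        assert np.allclose(do.mass, dd.mass, atol=1e-10)
        assert np.allclose(do.mean_age, dd.mean_age, atol=1e-12)

    def test_total_mass_equals_curve_start(self, rng):
        for _ in range(5):
            lt = make_random_life_table(rng)
            lstar = make_random_lstar(rng, lt)
            mc = reconstruct_morbidity_curve(lt, sullivan_hale(lt, lstar),
                                             mode="strict")
            assert event_distribution(lt).total == pytest.approx(lt.lx[0],
                                                                 rel=1e-12)
            assert event_distribution(mc).total == pytest.approx(lstar[0],
                                                                 rel=1e-10)

    def test_all_zero_curve_is_empty(self, rng):
        lt = make_random_life_table(rng)
        mc = reconstruct_morbidity_curve(
            lt, AbridgedSchedule(lt.x, np.zeros(lt.n_groups), "hale"))
        with pytest.raises(EmptyDistributionError):
            event_distribution(mc)


class TestConditioning:
    def test_threshold_at_first_age_is_identity(self, rng):
        d = event_distribution(make_random_life_table(rng))
        c = condition_on_age(d, d.x[0])
        assert np.array_equal(c.mass, d.mass)

    def test_all_mass_below_threshold(self):
        grid = np.array([0.0, 5.0, 10.0, 65.0])
        lt = build_life_table(grid, np.array([0.5, 1.0, 1.0, 1.0]),
                              np.array([2.5, 2.5, 27.5, np.nan]), e_last=5.0)
        d = event_distribution(lt)
        with pytest.raises(EmptyDistributionError):
            condition_on_age(d, 65.0)

    def test_off_grid_threshold_raises(self, rng):
        d = event_distribution(make_random_life_table(rng))
        with pytest.raises(ValueError, match="not on the age grid"):
            condition_on_age(d, 63.0)

    def test_mass_above_65_equals_survivors_at_65(self, rng):
        lt = make_random_life_table(rng)
        d = condition_on_age(event_distribution(lt), 65.0)
        i65 = int(np.flatnonzero(lt.x == 65.0)[0])
        assert d.total == pytest.approx(lt.lx[i65], rel=1e-12)


class TestLifeTableIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_mean_age_at_death_equals_e0(self, seed):
        rng = np.random.default_rng(seed)
        lt = make_random_life_table(rng)
        res = sd_age_at_event(event_distribution(lt))
        assert abs(res.mean - lt.ex[0]) < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_conditioned_mean_equals_65_plus_e65(self, seed):
        rng = np.random.default_rng(seed)
        lt = make_random_life_table(rng)
        i65 = int(np.flatnonzero(lt.x == 65.0)[0])
        res = sd_age_at_event(condition_on_age(event_distribution(lt), 65.0))
        assert abs(res.mean - (65.0 + lt.ex[i65])) < 1e-10

    def test_onset_mean_identity(self, rng):
        """Mean onset age = healthy person-years / ever-healthy mass."""
        lt = make_random_life_table(rng)
        lstar = make_random_lstar(rng, lt)
        hale = sullivan_hale(lt, lstar)
        mc = reconstruct_morbidity_curve(lt, hale, mode="strict")
        res = sd_age_at_event(event_distribution(mc))
        assert res.mean == pytest.approx(hale.values[0] * lt.lx[0] / lstar[0],
                                         abs=1e-10)


def test_rank_agreement_across_measures(battery_populations):
    """SD, CV and Gini order random populations consistently."""
    sds, cvs, ginis = [], [], []
    for pop in battery_populations:
        lt = recover_ax(pop.qx, pop.ex)
        d = event_distribution(lt)
        res = sd_age_at_event(d)
        sds.append(res.sd)
        cvs.append(res.cv)
        ginis.append(res.gini)
    assert stats.spearmanr(sds, cvs).statistic > 0.8
    assert stats.spearmanr(sds, ginis).statistic > 0.8
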