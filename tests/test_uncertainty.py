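"""Split-normal sampling and Monte Carlo interval machinery."""

import numpy as np
import pytest

import hli
from hli.schedules import AbridgedSchedule
from hli.uncertainty import (IntervalSummary, UncertaintySpec,
                             UnstableDrawsError, monte_carlo_ui,
                             sample_inputs, sample_schedule)


@pytest.fixture()
def spec():
    return UncertaintySpec(n_draws=100, seed=4)


def _interval_schedule():
    grid = np.array([0.0, 5.0])
    vals = np.array([10.0, 4.0])
    return AbridgedSchedule(grid, vals, "life_expectancy",
                            lower=vals - 1.0, upper=vals + 2.0)


class TestSampleSchedule:
    def test_zero_width_is_identity(self, spec):
        grid = np.array([0.0, 5.0])
        s = AbridgedSchedule(grid, np.array([10.0, 4.0]), "life_expectancy",
                             lower=np.array([10.0, 4.0]),
                             upper=np.array([10.0, 4.0]))
        for z in (-3.0, 0.0, 2.5):
            assert np.array_equal(sample_schedule(s, z, spec).values,
                                  s.values)

    def test_quantile_anchoring(self, spec):
        """z at the input-level quantile lands exactly on the bounds."""
        s = _interval_schedule()
        q = spec.input_quantile
        assert np.allclose(sample_schedule(s, q, spec).values, s.upper,
                           atol=1e-12)
        assert np.allclose(sample_schedule(s, -q, spec).values, s.lower,
                           atol=1e-12)

    def test_large_sample_quantiles_recover_bounds(self):
        """Empirical 2.5/97.5 percentiles of draws sit on the published
        bounds to within Monte Carlo error."""
        spec = UncertaintySpec(seed=0, input_level=0.95)
        k = 1000
        grid = np.arange(k, dtype=float)
        vals = np.full(k, 10.0)
        s = AbridgedSchedule(grid, vals, "life_expectancy",
                             lower=vals - 2.0, upper=vals + 3.0)
        rng = np.random.default_rng(17)
        draws = np.concatenate(
            [sample_schedule(s, rng.standard_normal(k), spec).values
             for _ in range(120)]
        )
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(8.0, abs=0.5e-2 * 2.0 + 0.02)
        assert hi == pytest.approx(13.0, abs=0.5e-2 * 3.0 + 0.03)

    def test_death_probability_clipped(self, spec):
        grid = np.array([0.0, 5.0])
        vals = np.array([0.95, 0.5])
        s = AbridgedSchedule(grid, vals, "death_probability",
                             lower=vals * 0.9, upper=np.clip(vals * 1.2, 0, 1))
        out = sample_schedule(s, 10.0, spec)
        assert np.all(out.values <= 1.0)


class TestSampleInputs:
    def test_draws_are_life_table_coherent(self, demo_population, spec):
        """The drawn (qx, ex) pair recovers in-range nax without clamping."""
        pop = demo_population
        rng = np.random.default_rng(3)
        for _ in range(20):
            q, e, h = sample_inputs(pop.qx, pop.ex, pop.hale, rng, spec)
            lt = hli.recover_ax(q, e, mode="strict")  # no consistency error
            assert np.all(h.values <= lt.ex + 1e-12)

    def test_hale_clipped_to_draw_expectancy(self, demo_population, spec):
        pop = demo_population
        rng = np.random.default_rng(3)
        q, e, h = sample_inputs(pop.qx, pop.ex, pop.hale, rng, spec)
        assert np.all(h.values <= e.values + 1e-12)


class TestMonteCarloUI:
    def test_zero_width_inputs_give_zero_width_outputs(self, demo_population):
        pop = demo_population
        q = pop.qx.replace_values(pop.qx.values)
        e = pop.ex.replace_values(pop.ex.values)
        h = pop.hale.replace_values(pop.hale.values)
        ui = monte_carlo_ui(q, e, h, UncertaintySpec(n_draws=40, seed=1))
        for summary in ui.values():
            assert summary.lower == pytest.approx(summary.upper, abs=1e-10)
            assert summary.lower == pytest.approx(summary.point, abs=1e-10)

    def test_same_seed_reproduces_different_seed_varies(self, demo_population):
        pop = demo_population
        args = (pop.qx, pop.ex, pop.hale)
        a = monte_carlo_ui(*args, UncertaintySpec(n_draws=80, seed=11))
        b = monte_carlo_ui(*args, UncertaintySpec(n_draws=80, seed=11))
        c = monte_carlo_ui(*args, UncertaintySpec(n_draws=80, seed=12))
        assert all(a[k].lower == b[k].lower and a[k].upper == b[k].upper
                   for k in a)
        assert any(a[k].lower != c[k].lower for k in a)
        # 80% level means the 10th/90th draw percentiles by construction
        assert all(s.level == 0.80 for s in a.values())

    def test_widening_inputs_never_narrows_intervals(self, demo_population):
        pop = demo_population

        def scaled(s, f):
            return AbridgedSchedule(
                s.grid, s.values, s.measure,
                s.values - f * (s.values - s.lower),
                s.values + f * (s.upper - s.values))

        widths = []
        for f in (0.5, 1.0, 2.0):
            ui = monte_carlo_ui(scaled(pop.qx, f), scaled(pop.ex, f),
                                scaled(pop.hale, f),
                                UncertaintySpec(n_draws=150, seed=21))
            widths.append({k: v.width for k, v in ui.items()})
        for a, b in zip(widths, widths[1:]):
            for k in a:
                assert b[k] >= a[k] - 1e-9

    def test_unstable_draws_raise(self, demo_population):
        pop = demo_population
        calls = {"n": 0}

        def flaky(q, e, h):
            calls["n"] += 1
            if calls["n"] > 1 and calls["n"] % 3 == 0:
                raise ValueError("synthetic failure")
            return {"x": 1.0}

        with pytest.raises(UnstableDrawsError, match="failed"):
            monte_carlo_ui(pop.qx, pop.ex, pop.hale,
                           UncertaintySpec(n_draws=60, seed=2), flaky)

    def test_rare_failures_are_dropped(self, demo_population):
        pop = demo_population
        calls = {"n": 0}

        def rarely_flaky(q, e, h):
            calls["n"] += 1
            if calls["n"] in (5, 9):  # 2 of 100 draws
                raise ValueError("synthetic failure")
            return {"x": float(calls["n"])}

        ui = monte_carlo_ui(pop.qx, pop.ex, pop.hale,
                            UncertaintySpec(n_draws=100, seed=2),
                            rarely_flaky)
        assert ui["x"].lower <= ui["x"].upper


class TestSpecAndSummary:
    def test_interval_summary_rejects_crossed_bounds(self):
        with pytest.raises(ValueError):
            IntervalSummary(point=1.0, lower=2.0, upper=1.0, level=0.8)

    @pytest.mark.parametrize("kwargs", [
        {"level": 1.2}, {"n_draws": 1}, {"input_level": 0.0},
        {"correlation": "magic"},
    ])
    def test_spec_validation(self, kwargs):
        with pytest.raises(ValueError):
            UncertaintySpec(**kwargs)

    def test_input_quantile_matches_95(self):
        assert UncertaintySpec().input_quantile == pytest.approx(1.959964,
                                                                 abs=1e-6)
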