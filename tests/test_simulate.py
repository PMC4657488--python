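"""Simulator: reproducibility, torus symmetry, gas-model rate, bias scenario."""

import math
from datetime import datetime

import numpy as np
import pytest

from remcam.events import classify_night, collapse_to_independent_events
from remcam.simulate import (
    BiasConfig,
    SimConfig,
    follows_fixture,
    grid_deployments,
    prides_fixture,
    recover_density,
    simulate,
    simulate_bias_scenario,
    trials_fixture,
)
from remcam.types import ValidationError

SMALL = dict(arena=(4.0, 4.0), n_animals=40, n_cameras=4, duration_h=200.0)


class TestReproducibility:
    def test_same_seed_identical_outputs(self):
        b1 = simulate(SimConfig(seed=5, **SMALL))
        b2 = simulate(SimConfig(seed=5, **SMALL))
        assert b1.events == b2.events
        assert np.array_equal(b1.cameras, b2.cameras)

    def test_different_seed_differs(self):
        b1 = simulate(SimConfig(seed=5, **SMALL))
        b2 = simulate(SimConfig(seed=6, **SMALL))
        assert b1.events != b2.events


class TestGeometry:
    def test_translation_invariance_on_torus(self):
        base = simulate(SimConfig(seed=3, **SMALL))
        shifted = simulate(SimConfig(seed=3, shift=(1.37, 2.91), **SMALL))
        assert shifted.n_events == base.n_events

    def test_zero_animals_zero_events(self):
        cfg = SimConfig(seed=0, arena=(4.0, 4.0), n_animals=0, n_cameras=4, duration_h=10.0)
        assert simulate(cfg).n_events == 0

    def test_saturating_zones_detect_everyone_immediately(self):
        # four zones of radius ~2 on a 4x4 torus with near-full angle cover
        # the arena: every animal is inside a zone at t = 0
        cfg = SimConfig(seed=2, arena=(4.0, 4.0), n_animals=30, n_cameras=4,
                        duration_h=1.0, detect_r=1.99, detect_theta=2 * math.pi - 1e-9)
        b = simulate(cfg)
        at_start = sum(e.timestamp == cfg.start for e in b.events)
        assert at_start >= cfg.n_animals

    def test_zone_larger_than_arena_rejected(self):
        with pytest.raises(ValidationError, match="arena"):
            SimConfig(arena=(4.0, 4.0), detect_r=2.5)

    def test_event_timestamps_within_deployment(self):
        b = simulate(SimConfig(seed=1, **SMALL))
        dep = b.deployments[0]
        for e in b.events:
            assert dep.start <= e.timestamp <= dep.end


class TestGasModel:
    def test_event_rate_matches_analytic_over_replicates(self):
        """Mean per-camera event rate of straight movers matches
        rho = D V r (2 + theta) / pi within 3 SE (scaled-down run)."""
        rates = []
        cfg = None
        for seed in range(40):
            cfg = SimConfig(seed=seed, arena=(6.0, 6.0), n_animals=180,
                            n_cameras=9, duration_h=600.0)
            b = simulate(cfg)
            rates.append(b.n_events / (cfg.n_cameras * cfg.duration_h))
        rates = np.array(rates)
        se = rates.std(ddof=1) / math.sqrt(len(rates))
        assert abs(rates.mean() - cfg.analytic_rate) < 3 * se

    def test_dt_plays_no_role_for_straight_movement(self):
        b1 = simulate(SimConfig(seed=4, dt_min=1.0, **SMALL))
        b2 = simulate(SimConfig(seed=4, dt_min=0.5, **SMALL))
        assert b1.events == b2.events

    def test_crw_dt_halving_leaves_event_rate_unchanged(self):
        """Correlated-walk event rates converge as the heading step shrinks:
        halving dt leaves the mean rate unchanged within Monte-Carlo error
        (3 SE of the difference of means). The turning-angle sd scales with
        sqrt(dt), so both runs discretise the same underlying process."""
        rates = {}
        for dt in (2.0, 1.0):
            per_seed = []
            for seed in range(30):
                cfg = SimConfig(seed=seed, arena=(4.0, 4.0), n_animals=120,
                                n_cameras=9, duration_h=300.0, movement="crw",
                                turning_sd=0.8, dt_min=dt)
                per_seed.append(simulate(cfg).n_events)
            rates[dt] = np.array(per_seed, dtype=float)
        diff = rates[1.0].mean() - rates[2.0].mean()
        se = math.sqrt(rates[1.0].var(ddof=1) / 30 + rates[2.0].var(ddof=1) / 30)
        assert abs(diff) < 3 * se

    def test_pipeline_recovery_small(self):
        """End-to-end REM recovery on unbiased simulations is unbiased within
        5% (scaled-down version of the full recovery experiment)."""
        ds = [
            recover_density(simulate(SimConfig(seed=s, arena=(6.0, 6.0), n_animals=180,
                                               n_cameras=9, duration_h=600.0)))
            for s in range(40)
        ]
        assert abs(np.mean(ds) / 5.0 - 1.0) < 0.05


class TestBiasScenario:
    BIAS = dict(arena=(6.0, 6.0), n_animals=180, n_cameras=9, duration_h=240.0)

    def test_zero_hazard_reduces_to_unbiased(self):
        b0 = simulate(SimConfig(seed=7, **self.BIAS))
        b1 = simulate(SimConfig(seed=7, bias=BiasConfig(q=0.0), **self.BIAS))
        assert b0.events == b1.events

    def test_requires_bias_config(self):
        with pytest.raises(ValidationError):
            simulate_bias_scenario(SimConfig(**self.BIAS))

    def test_day_events_exceed_night_events(self):
        b = simulate_bias_scenario(
            SimConfig(seed=1, bias=BiasConfig(q=0.1, rest_h=2.0), **self.BIAS)
        )
        ind = collapse_to_independent_events(b.events)
        night = sum(classify_night(e.timestamp) for e in ind)
        assert len(ind) - night > night

    def test_all_events_inflated_night_unbiased(self):
        d_all, d_night = [], []
        for seed in range(15):
            b = simulate_bias_scenario(
                SimConfig(seed=seed, bias=BiasConfig(q=0.1, rest_h=2.0), **self.BIAS)
            )
            d_all.append(recover_density(b, window="all"))
            d_night.append(recover_density(b, window="night"))
        assert min(d_all) > 5.0
        assert abs(np.mean(d_night) / 5.0 - 1.0) < 0.25


class TestFixtures:
    def test_grid_spacing(self):
        deps = grid_deployments(20.0, 42.0)
        xs = sorted({d.x for d in deps})
        assert xs[1] - xs[0] == pytest.approx(math.sqrt(5.0))
        assert abs(len(deps) - 168) <= 8

    def test_trials_noiseless_recovery(self):
        from remcam.fieldparams import estimate_detection_zone

        z = estimate_detection_zone(trials_fixture(sd_r_m=0.0, sd_bearing_deg=0.0))
        assert z.r * 1000 == pytest.approx(14.42)
        assert math.degrees(z.theta) == pytest.approx(50.12)

    def test_follows_day_night_speeds(self):
        from remcam.fieldparams import follow_rate

        f = follows_fixture(["p"], day_speed=0.0, night_speed=0.4)[0]
        assert follow_rate(f, "all") == pytest.approx(0.2)
        assert follow_rate(f, "night") == pytest.approx(0.4)

    def test_prides_cloud_inside_habitat_gives_full_overlap(self):
        from shapely.geometry import box

        from remcam.reference import fit_ud, isopleth, overlap_proportion

        p = prides_fixture(n_prides=1, centers=np.array([[20.0, 20.0]]),
                           spread_km=1.0, seed=0)[0]
        hr = isopleth(fit_ud(p.points), 0.75, pride_id=p.pride_id)
        assert overlap_proportion(hr, box(0, 0, 40, 40)) == pytest.approx(1.0)

    def test_fixture_reproducibility(self):
        assert trials_fixture(seed=9) == trials_fixture(seed=9)
        assert prides_fixture(seed=9)[0] == prides_fixture(seed=9)[0]
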