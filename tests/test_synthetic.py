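"""Generator tests: determinism, cohort structure, regimes, censoring."""

import numpy as np
import pandas as pd
import pytest

from pape.synthetic import (STATIC_LABELS, FVC_COEFFS, ScenarioConfig,
                            generate_profile, generate_session, predict_fvc,
                            simulate_point_summaries)

from conftest import constant_scenario


class TestProfiles:
    def test_seeded_determinism(self):
        assert generate_profile(123) == generate_profile(123)

    def test_degenerate_sex_ratio(self):
        assert all(generate_profile(s, sex_ratio=1.0).sex_code == 1
                   for s in range(20))
        assert all(generate_profile(s, sex_ratio=0.0).sex_code == 2
                   for s in range(20))

    def test_sex_ratio_binomial(self):
        codes = [generate_profile(s, sex_ratio=0.7).sex_code for s in range(10_000)]
        male_frac = np.mean(np.array(codes) == 1)
        assert abs(male_frac - 0.7) < 0.02

    def test_eligibility_and_physiology(self):
        for s in range(200):
            p = generate_profile(s)
            assert 18 <= p.age <= 75
            assert p.height > 0 and p.weight > 0 and p.fvc > 0

    def test_invalid_sex_ratio(self):
        with pytest.raises(ValueError):
            generate_profile(0, sex_ratio=1.5)


class TestPredictFvc:
    def test_zeroed_coefficients(self):
        assert predict_fvc(1, 25, 100, coeffs={1: (0.05, 0.0, 0.0)}) == pytest.approx(5.0)

    def test_male_at_least_female(self):
        for h in (150, 165, 180, 195):
            for age in (18, 30, 50, 75):
                assert predict_fvc(1, age, h) >= predict_fvc(2, age, h)

    def test_matches_linear_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sex = int(rng.integers(1, 3))
            age = float(rng.uniform(18, 75))
            h = float(rng.uniform(150, 200))
            a, b, c = FVC_COEFFS[sex]
            assert predict_fvc(sex, age, h) == pytest.approx(a * h + b * age + c)

    def test_rejects_nonphysiological(self):
        with pytest.raises(ValueError):
            predict_fvc(1, 25, -10)
        with pytest.raises(ValueError):
            predict_fvc(3, 25, 170)


class TestSessions:
    def test_seeded_determinism(self, profile, small_config):
        a = generate_session(profile, small_config, seed=4)
        b = generate_session(profile, small_config, seed=4)
        pd.testing.assert_frame_equal(a.env_stream, b.env_stream)
        pd.testing.assert_frame_equal(a.physio_stream, b.physio_stream)
        assert a.segment_plan == b.segment_plan

    def test_pm_ordering_everywhere(self, session):
        pm = session.env_stream[["pm1", "pm2_5", "pm10"]].to_numpy()
        assert np.all(pm[:, 0] <= pm[:, 1]) and np.all(pm[:, 1] <= pm[:, 2])

    def test_cadences(self, session, small_config):
        env_dt = np.diff(session.env_stream["timestamp"])
        assert np.allclose(env_dt, small_config.env_period_s)
        phys_dt = np.diff(session.physio_stream["timestamp"])
        assert np.allclose(phys_dt, 1.0 / small_config.physio_rate_hz)

    def test_records_per_static_segment(self, session, small_config):
        t = session.env_stream["timestamp"].to_numpy()
        for label, arrive, leave in session.segment_plan:
            n = int(((t >= arrive) & (t < leave)).sum())
            # 300 s dwell sampled every 24 s: 12 or 13 depending on phase
            assert n in (12, 13), f"segment {label}: {n} records"

    def test_gas_channels_censored_at_lod(self, session, small_config):
        env = session.env_stream
        for gas in ("co", "no2"):
            assert (env[gas] >= small_config.lod_ppb - 1e-12).all()
            # sub-LOD regime medians (8 ppb) mean most records sit at the floor
            assert env[f"{gas}_censored"].mean() > 0.5
            at_floor = env.loc[env[f"{gas}_censored"], gas]
            assert np.allclose(at_floor, small_config.lod_ppb)

    def test_zero_variance_recovers_medians(self, profile):
        cfg = constant_scenario(level=25.0)
        s = generate_session(profile, cfg, seed=1)
        t = s.env_stream["timestamp"].to_numpy()
        for label, arrive, leave in s.segment_plan:
            sub = s.env_stream[(t >= arrive) & (t < leave)]
            assert np.allclose(sub["pm2_5"], 25.0)
            assert np.allclose(sub["pm1"], 24.0)
            assert np.allclose(sub["rh"], sub["rh"].iloc[0])

    def test_indoor_co2_exceeds_outdoor(self, profile, small_config):
        """Indoor point A (~1010 ppm) must dominate every outdoor point
        (~620 ppm) session by session, as in the emulated campaign."""
        wins = 0
        for seed in range(50):
            s = generate_session(profile, small_config, seed=seed)
            t = s.env_stream["timestamp"].to_numpy()
            med = {}
            for label, arrive, leave in s.segment_plan:
                med[label] = float(s.env_stream.loc[(t >= arrive) & (t < leave), "co2"].median())
            if all(med["A"] > med[l] for l in STATIC_LABELS if l != "A"):
                wins += 1
        assert wins >= 48  # ±5% stochastic allowance over 50 sessions

    def test_afternoon_shifts(self, profile):
        cfg_m = constant_scenario(level=500.0)
        cfg_a = constant_scenario(level=500.0, time_of_day="afternoon")
        sm = generate_session(profile, cfg_m, seed=2)
        sa = generate_session(profile, cfg_a, seed=2)
        assert sa.env_stream["pm2_5"].iloc[0] == pytest.approx(500.0 * cfg_a.tod_pm_factor)
        assert sa.env_stream["co2"].iloc[0] == pytest.approx(
            sm.env_stream["co2"].iloc[0] + cfg_a.tod_co2_offset)

    def test_missing_regime_rejected(self):
        with pytest.raises(ValueError, match="regime_params"):
            ScenarioConfig(regime_params={"A": {}})

    def test_gps_track_follows_waypoints(self, session, small_config):
        env = session.env_stream
        t = env["timestamp"].to_numpy()
        for label, arrive, leave in session.segment_plan:
            lat, lon = small_config.waypoints[label]
            sub = env[(t >= arrive) & (t < leave)]
            assert np.allclose(sub["lat"], lat) and np.allclose(sub["lon"], lon)


class TestPointSummaries:
    def test_shape_and_determinism(self):
        a = simulate_point_summaries(20, seed=9)
        b = simulate_point_summaries(20, seed=9)
        assert a.shape == (20, 7) and list(a.columns) == list(STATIC_LABELS)
        pd.testing.assert_frame_equal(a, b)

    def test_offset_injection(self):
        tab = simulate_point_summaries(200, seed=3, point_offsets={"A": 390.0})
        assert tab["A"].mean() - tab["B"].mean() > 300.0
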