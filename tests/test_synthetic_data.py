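import numpy as np
import pandas as pd
import pytest

from snapmech import ball_strike, track_processing, units
from snapmech.defence_assay import aggregate_trials, read_defence_csv
from snapmech.errors import ConfigError
from snapmech.morphometry import MandibleMorphometry, inertia_model, read_morphometry_csv
from snapmech.snap_kinematics import read_snap_events_csv
from snapmech.synthetic_data import (
    SimulationConfig,
    SpeciesRates,
    TRACK_CONFIG,
    cohort_mandible,
    gen_ball_strike_events,
    gen_defence_trials,
    gen_morphometry,
    gen_snap_events,
    gen_tracks,
    morphometry_si,
)


class TestConfigValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(body_mass_mg=(3.22, -0.1))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(l_a_mm=(0.0, 0.1))

    def test_partition_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(partition_weights=(0.5, 0.4, 0.3))

    def test_rates_bounded(self):
        with pytest.raises(ConfigError):
            SpeciesRates(attack=1.2, snap=0.5, hit=0.5, kill=0.5)


class TestGenMorphometry:
    def test_column_means_near_targets(self):
        cfg = SimulationConfig(seed=1, n_individuals=17)
        df = gen_morphometry(cfg)
        targets = {
            "m_t_mg": cfg.body_mass_mg, "l_t_mm": cfg.body_length_mm,
            "m_a1_ug": cfg.m_a1_ug, "m_a2_ug": cfg.m_a2_ug, "l_a_mm": cfg.l_a_mm,
        }
        for col, (mean, sd) in targets.items():
            sem = sd / np.sqrt(len(df))
            assert abs(df[col].mean() - mean) < 3 * sem + 1e-12, col

    def test_zero_sd_degenerates_to_means(self):
        cfg = SimulationConfig(seed=2, body_mass_mg=(3.22, 0.0))
        df = gen_morphometry(cfg)
        assert (df["m_t_mg"] == 3.22).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        pd.testing.assert_frame_equal(gen_morphometry(cfg), gen_morphometry(cfg))

    def test_rows_satisfy_invariants(self, cohort_config):
        df = morphometry_si(gen_morphometry(cohort_config))
        for r in df.itertuples(index=False):
            m = MandibleMorphometry(m_a1=r.m_a1, m_a2=r.m_a2, l_a=r.l_a)
            assert 0 < inertia_model(m).k < 1


class TestGenBallStrikeEvents:
    def test_noiseless_exact_inversion(self):
        cfg = SimulationConfig(seed=4, n_events=40, noise_cv=0.0)
        morph = gen_morphometry(cfg)
        events, truth = gen_ball_strike_events(cfg, morph)
        msi = morphometry_si(morph)
        mandible = cohort_mandible(msi)
        im = inertia_model(mandible)
        ev = events.rename(columns={
            "v_b_m_s": "v_b", "v_t_m_s": "v_t", "omega_t_rad_s": "omega_t"})
        ev["m_b"] = ev.pop("m_b_mg").map(units.mg_to_kg)
        analyzed = ball_strike.analyze_events(ev, msi, m_a=mandible.m_a, k=im.k)
        np.testing.assert_allclose(
            analyzed["v_mt"], truth["v_mt_m_s"], rtol=1e-9)
        np.testing.assert_allclose(
            analyzed["e_a"].map(units.j_to_uj), truth["e_a_uj"], rtol=1e-9)

    def test_partition_all_to_ball(self):
        cfg = SimulationConfig(seed=4, n_events=10, noise_cv=0.0,
                               partition_weights=(1.0, 0.0, 0.0))
        events, _ = gen_ball_strike_events(cfg, gen_morphometry(cfg))
        assert (events["v_t_m_s"] == 0.0).all()
        assert (events["omega_t_rad_s"] == 0.0).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=13, n_events=20)
        morph = gen_morphometry(cfg)
        e1, t1 = gen_ball_strike_events(cfg, morph)
        e2, t2 = gen_ball_strike_events(cfg, morph)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noisy_recovery_within_two_sem(self):
        cfg = SimulationConfig(seed=7, n_events=200, noise_cv=0.05)
        morph = gen_morphometry(cfg)
        events, truth = gen_ball_strike_events(cfg, morph)
        msi = morphometry_si(morph)
        mandible = cohort_mandible(msi)
        im = inertia_model(mandible)
        ev = events.rename(columns={
            "v_b_m_s": "v_b", "v_t_m_s": "v_t", "omega_t_rad_s": "omega_t"})
        ev["m_b"] = ev.pop("m_b_mg").map(units.mg_to_kg)
        analyzed = ball_strike.analyze_events(ev, msi, m_a=mandible.m_a, k=im.k)
        rec = analyzed["v_mt"].to_numpy()
        tru = truth["v_mt_m_s"].to_numpy()
        tol = 2 * rec.std(ddof=1) / np.sqrt(len(rec))
        assert abs(rec.mean() - tru.mean()) < tol


class TestGenTracks:
    def test_tracks_regenerate_velocities_and_angles(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_events=12)
        events, _ = gen_ball_strike_events(cfg, gen_morphometry(cfg))
        tracks = gen_tracks(cfg, events)
        csv = tmp_path / "tracks.csv"
        tracks.to_csv(csv, index=False)
        yml = tmp_path / "cfg.yaml"
        yml.write_text(
            "\n".join(f"{k}: {v}" for k, v in TRACK_CONFIG.items()) + "\n")
        loaded = track_processing.read_tracks_csv(csv, yml)
        for rec in events.itertuples(index=False):
            ball = loaded[(rec.event_id, "ball")]
            termite = loaded[(rec.event_id, "termite")]
            assert track_processing.first_interval_speed(ball) == pytest.approx(
                rec.v_b_m_s, rel=1e-9)
            assert track_processing.first_interval_speed(termite) == pytest.approx(
                rec.v_t_m_s, rel=1e-9)
            d = track_processing.direction_angle(
                track_processing.track_displacement_px(ball), ball.body_axis,
                y_down=True)
            assert d.angle_deg == pytest.approx(rec.angle_deg, abs=1e-6)
            assert d.signed_deg >= 0  # strikes aim left of the body axis


class TestGenDefenceTrials:
    def test_zero_rate_zero_attacks(self):
        cfg = SimulationConfig(seed=6, species={
            "sp": SpeciesRates(attack=0.0, snap=0.5, hit=0.5, kill=0.5)})
        df = gen_defence_trials(cfg)
        assert (df["attacks"] == 0).all()

    def test_observed_rate_in_binomial_interval(self):
        cfg = SimulationConfig(seed=3, species={
            "sp": SpeciesRates(attack=0.34, snap=0.5, hit=0.3, kill=0.0,
                               encounters_per_trial=50.0)})
        df = gen_defence_trials(cfg)
        rate = df["attacks"].sum() / df["encounters"].sum()
        assert 0.28 <= rate <= 0.40

    def test_determinism(self):
        cfg = SimulationConfig(seed=8)
        pd.testing.assert_frame_equal(gen_defence_trials(cfg), gen_defence_trials(cfg))

    def test_counts_satisfy_invariants(self, cohort_config):
        df = gen_defence_trials(cohort_config)
        counts = aggregate_trials(df)  # constructor enforces the invariants
        assert len(counts) == len(cohort_config.species)


class TestRoundTripThroughReaders:
    def test_all_tables_pass_input_validation(self, tmp_path, cohort_config):
        cfg = cohort_config
        morph = gen_morphometry(cfg)
        morph.to_csv(tmp_path / "morphometry.csv", index=False)
        gen_snap_events(cfg).to_csv(tmp_path / "snaps.csv", index=False)
        events, _ = gen_ball_strike_events(cfg, morph)
        events.to_csv(tmp_path / "strikes.csv", index=False)
        gen_defence_trials(cfg).to_csv(tmp_path / "defence.csv", index=False)

        msi = read_morphometry_csv(tmp_path / "morphometry.csv")
        assert len(msi) == cfg.n_individuals
        snaps = read_snap_events_csv(tmp_path / "snaps.csv")
        assert (snaps["omega_a"] > 0).all()
        strikes = ball_strike.read_ball_strike_csv(tmp_path / "strikes.csv")
        assert len(strikes) == cfg.n_events
        counts = aggregate_trials(read_defence_csv(tmp_path / "defence.csv"))
        assert all(c.encounters >= c.attacks for c in counts)
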