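"""Synthetic cohort generator: shape, determinism and planted effects."""

import numpy as np
import pytest

from vrphobia import (
    CohortConfig,
    SceneSpec,
    generate_cohort,
    sample_profile,
    synthesize_actions,
    synthesize_eeg,
    welch_band_power,
)
from vrphobia.montage import CHANNELS_21


def _small_eeg_config(**kw):
    defaults = dict(n_participants=2, n_abnormal=1, record_duration=4.0, seed=5)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestCohortShape:
    def test_single_participant_single_scene(self):
        cfg = CohortConfig(n_participants=1, n_abnormal=0,
                           scenes=(SceneSpec(1, "Puzzle", "norm"),),
                           record_duration=2.0)
        records = generate_cohort(cfg)
        assert len(records) == 1
        assert records[0].eeg.n_channels == 21

    def test_record_count_is_participants_times_scenes(self):
        cfg = _small_eeg_config(n_participants=3, n_abnormal=1)
        assert len(generate_cohort(cfg, include_eeg=False)) == 3 * 6

    def test_channel_labels_follow_the_montage(self):
        cfg = _small_eeg_config(n_participants=1, n_abnormal=0,
                                scenes=(SceneSpec(1, "Puzzle", "norm"),))
        rec = generate_cohort(cfg)[0]
        assert rec.eeg.channels == CHANNELS_21


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = _small_eeg_config()
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.eeg.data, rb.eeg.data)
            assert [e.timestamp for e in ra.actions.events] == \
                   [e.timestamp for e in rb.actions.events]

    def test_different_seeds_differ(self):
        a = generate_cohort(_small_eeg_config(seed=5))
        b = generate_cohort(_small_eeg_config(seed=6))
        assert not np.array_equal(a[0].eeg.data, b[0].eeg.data)

    def test_action_logs_independent_of_eeg_generation(self):
        cfg = _small_eeg_config()
        with_eeg = generate_cohort(cfg, include_eeg=True)
        without = generate_cohort(cfg, include_eeg=False)
        for ra, rb in zip(with_eeg, without):
            assert [e.timestamp for e in ra.actions.events] == \
                   [e.timestamp for e in rb.actions.events]


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_participants=0),
        dict(record_duration=-1.0),
        dict(n_abnormal=5, n_participants=4),
        dict(sampling_rate=40.0),
        dict(phobic_power_multiplier=0.0),
        dict(scenes=()),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortConfig(**kw)

    def test_scene_validation(self):
        with pytest.raises(ValueError):
            SceneSpec(7, "Puzzle", "norm")
        with pytest.raises(ValueError):
            SceneSpec(1, "Puzzle", "norm", n_actions=0)


class TestSignals:
    def test_one_minute_at_500hz_has_30000_samples(self):
        cfg = CohortConfig(n_participants=1, n_abnormal=0, record_duration=60.0,
                           scenes=(SceneSpec(1, "Puzzle", "norm"),), seed=2)
        rec = generate_cohort(cfg)[0].eeg
        assert rec.n_samples == 30000
        assert rec.sampling_rate == 500.0

    def test_signals_are_finite(self):
        for rec in generate_cohort(_small_eeg_config()):
            assert np.isfinite(rec.eeg.data).all()

    def test_zero_alpha_amplitude_leaves_only_noise_in_alpha_band(self):
        cfg = _small_eeg_config(n_participants=1, n_abnormal=0)
        scene = SceneSpec(1, "Puzzle", "norm")
        rng = np.random.default_rng(7)
        profile = sample_profile(rng, "P1", False, cfg)
        profile.band_amps["alpha"] = 0.0
        no_alpha = synthesize_eeg(profile, scene, cfg, np.random.default_rng(1))
        profile_noise = sample_profile(np.random.default_rng(7), "P1", False, cfg)
        for band in profile_noise.band_amps:
            profile_noise.band_amps[band] = 0.0
        profile_noise.coupling_uv = profile.coupling_uv
        noise_only = synthesize_eeg(profile_noise, scene, cfg, np.random.default_rng(2))
        full = synthesize_eeg(sample_profile(np.random.default_rng(7), "P1", False, cfg),
                              scene, cfg, np.random.default_rng(3))
        _, p_no_alpha = welch_band_power(no_alpha, "alpha")
        _, p_noise = welch_band_power(noise_only, "alpha")
        _, p_full = welch_band_power(full, "alpha")
        assert p_no_alpha < 0.1 * p_full          # alpha oscillation gone
        assert p_no_alpha < 3.0 * p_noise         # at the noise floor

    def test_right_alpha_depression_yields_negative_o2_o1_iha(self):
        """Monte-Carlo sign test: with the planted right-hemisphere alpha
        depression, the O2-O1 alpha asymmetry of abnormal phobic records is
        negative in significantly more than half of realizations."""
        from scipy.stats import binomtest

        from vrphobia import iha_profile

        cfg = _small_eeg_config(n_participants=1, n_abnormal=1, record_duration=3.0)
        scene = SceneSpec(2, "Puzzle", "arachnophobia")
        negative = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            profile = sample_profile(rng, "P1", True, cfg)
            rec = synthesize_eeg(profile, scene, cfg, rng)
            prof = iha_profile(rec)
            negative += prof.loc["O2-O1", "alpha"] < 0
        assert binomtest(negative, n_seeds, 0.5, alternative="greater").pvalue < 0.01

    def test_planted_alpha_power_elevation_recoverable_across_seeds(self):
        """Abnormal participants' arachnophobia records carry more alpha
        band power than their norm records in >90% of cohort seeds."""
        scenes = (SceneSpec(1, "Puzzle", "norm"), SceneSpec(2, "Puzzle", "arachnophobia"))
        elevated = 0
        n_seeds = 50
        for s in range(n_seeds):
            cfg = CohortConfig(n_participants=1, n_abnormal=1, scenes=scenes,
                               record_duration=3.0, seed=2000 + s)
            norm_rec, phob_rec = generate_cohort(cfg)
            _, p_norm = welch_band_power(norm_rec.eeg, "alpha")
            _, p_phob = welch_band_power(phob_rec.eeg, "alpha")
            elevated += p_phob > p_norm
        assert elevated > 0.9 * n_seeds


class TestActions:
    def test_zero_positional_noise_places_exactly_on_target(self):
        cfg = _small_eeg_config()
        profile = sample_profile(np.random.default_rng(0), "P1", False, cfg)
        profile.place_noise = 0.0
        log = synthesize_actions(profile, SceneSpec(1, "Puzzle", "norm"), cfg,
                                 np.random.default_rng(1))
        for ev in log.events:
            assert np.allclose(ev.placed, ev.target)

    def test_certain_hits_give_full_score(self):
        cfg = _small_eeg_config()
        profile = sample_profile(np.random.default_rng(0), "P1", False, cfg)
        profile.hit_prob = 1.0
        log = synthesize_actions(profile, SceneSpec(4, "Shooting", "norm"), cfg,
                                 np.random.default_rng(1))
        assert log.n_hits == log.n_actions == 10

    def test_timestamps_monotone_within_bounds(self):
        cfg = _small_eeg_config()
        profile = sample_profile(np.random.default_rng(3), "P1", True, cfg)
        for scene in cfg.scenes:
            log = synthesize_actions(profile, scene, cfg, np.random.default_rng(9))
            ts = [e.timestamp for e in log.events]
            assert all(a < b for a, b in zip(ts, ts[1:]))
            assert log.t_start < ts[0] or log.t_start == 0.0
            assert ts[-1] <= log.t_end

    def test_phobia_lowers_abnormal_shooting_accuracy_in_expectation(self):
        """500 replicates: mean hit rate of an abnormal profile drops in the
        arachnophobia scene relative to its norm scene."""
        cfg = _small_eeg_config()
        profile = sample_profile(np.random.default_rng(4), "P1", True, cfg)
        rng = np.random.default_rng(42)
        norm_scene = SceneSpec(4, "Shooting", "norm")
        phob_scene = SceneSpec(5, "Shooting", "arachnophobia")
        norm_hits = [synthesize_actions(profile, norm_scene, cfg, rng).n_hits
                     for _ in range(500)]
        phob_hits = [synthesize_actions(profile, phob_scene, cfg, rng).n_hits
                     for _ in range(500)]
        assert np.mean(phob_hits) < np.mean(norm_hits)
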