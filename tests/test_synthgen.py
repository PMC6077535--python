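"""Synthetic-session generator: ground truth, determinism, paradigm counts."""

import numpy as np
import pytest

from sodbci import preprocess, synthgen
from sodbci.synthgen import (
    NodeTimingModel,
    ParadigmConfig,
    SubjectProfile,
    generate_background_noise,
    generate_p300_epoch,
    generate_ssvep_block,
    simulate_operation_session,
    simulate_registration_session,
)
from sodbci.types import EpochSet


class TestBackgroundNoise:
    def test_zero_noise_gives_zero_matrix(self):
        out = generate_background_noise(100, 3, SubjectProfile(noise_sd=0.0))
        assert np.all(out == 0)

    def test_deterministic_under_seed(self):
        p = SubjectProfile(seed=42)
        a = generate_background_noise(500, 2, p)
        b = generate_background_noise(500, 2, p)
        np.testing.assert_array_equal(a, b)

    def test_sample_sd_matches_independent_resimulation(self):
        """The realized SD must agree with an independently coded pink+white
        mix at the same nominal scale."""
        p = SubjectProfile(noise_sd=1.0, seed=5)
        out = generate_background_noise(100_000, 1, p)

        # independent oracle: same model, separate implementation
        rng = np.random.default_rng(99)
        n = 100_000
        white = rng.standard_normal(n)
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, d=1.0)
        f[0] = f[1]
        pink = np.fft.irfft(spec / np.sqrt(f), n=n)
        pink /= pink.std()
        oracle = (pink + white) / np.sqrt(2.0)

        assert abs(out.std() - oracle.std()) / oracle.std() < 0.20

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            generate_background_noise(0, 3, SubjectProfile())


class TestSSVEPBlock:
    def test_zero_condition_zero_delay_peaks_at_quarter_period(
        self, cfg, quiet_profile
    ):
        node = NodeTimingModel(0, transmission_delay=0.0, flash_jitter_sd=0.0)
        seg, lag = generate_ssvep_block(0.0, node, cfg, quiet_profile)
        assert lag == 0.0
        # noiseless: locate the first positive peak of the occipital wave
        occ = seg[3]  # O1
        t_ms = np.arange(seg.shape[1]) / cfg.sampling_rate * 1000.0
        first_period = t_ms < 62.5
        peak_t = t_ms[first_period][np.argmax(occ[first_period])]
        assert abs(peak_t - 15.625) <= 1000.0 / cfg.sampling_rate

    @pytest.mark.parametrize(
        "condition, delay, expected_lag",
        [(90.0, 0.0, 90.0), (0.0, 10.0, 57.6), (270.0, 31.25, 90.0)],
    )
    def test_true_lag_arithmetic(self, cfg, quiet_profile, condition, delay, expected_lag):
        node = NodeTimingModel(0, transmission_delay=delay, flash_jitter_sd=0.0)
        _, lag = generate_ssvep_block(condition, node, cfg, quiet_profile)
        assert lag == pytest.approx(expected_lag, abs=1e-9)

    def test_unsupported_phase_rejected(self, cfg, quiet_profile):
        with pytest.raises(ValueError, match="phase condition"):
            generate_ssvep_block(45.0, NodeTimingModel(0), cfg, quiet_profile)


class TestP300Epoch:
    def test_nontarget_is_background_only(self, cfg, quiet_profile):
        node = NodeTimingModel(0, flash_jitter_sd=0.0)
        seg, lat = generate_p300_epoch(False, node, quiet_profile, cfg)
        assert np.all(seg == 0)  # zero noise, no template
        assert np.isnan(lat)

    def test_zero_amplitude_degenerate(self, cfg):
        profile = SubjectProfile(p300_amplitude=0.0, noise_sd=0.0, p300_latency_jitter_sd=0.0)
        node = NodeTimingModel(0, flash_jitter_sd=0.0)
        tgt, _ = generate_p300_epoch(True, node, profile, cfg)
        non, _ = generate_p300_epoch(False, node, profile, cfg)
        np.testing.assert_array_equal(tgt, non)

    def test_delay_shifts_true_latency(self, cfg, quiet_profile):
        node = NodeTimingModel(0, transmission_delay=46.875, flash_jitter_sd=0.0)
        _, lat = generate_p300_epoch(True, node, quiet_profile, cfg)
        assert lat == pytest.approx(quiet_profile.p300_base_latency + 46.875)

    def test_template_strongest_on_parietal(self, cfg, quiet_profile):
        node = NodeTimingModel(0, flash_jitter_sd=0.0)
        seg, _ = generate_p300_epoch(True, node, quiet_profile, cfg)
        parietal_peak = seg[:3].max()
        occipital_peak = seg[3:].max()
        assert parietal_peak == pytest.approx(quiet_profile.p300_amplitude)
        assert occipital_peak == pytest.approx(0.5 * quiet_profile.p300_amplitude)


class TestRegistrationSession:
    def test_paradigm_counts(self, cfg, still_nodes, quiet_profile):
        s = simulate_registration_session(still_nodes, cfg, quiet_profile)
        flashes = s.events[s.events.kind == "flash"]
        block0 = flashes[flashes.block == 0]
        assert len(block0) == 120
        assert int(block0.is_target.sum()) == 30
        assert int((~block0.is_target.astype(bool)).sum()) == 90
        flick = s.events[s.events.kind == "flicker_onset"]
        assert len(flick) == 4 * 4  # conditions x nodes

    def test_flicker_protocol_duration(self, cfg, still_nodes, quiet_profile):
        s = simulate_registration_session(still_nodes, cfg, quiet_profile)
        flick0 = s.events[(s.events.kind == "flicker_onset") & (s.events.block == 0)]
        onsets = flick0.onset_s.to_numpy()
        # 4 conditions spaced by 5 s flicker + 2 s gap
        np.testing.assert_allclose(np.diff(onsets), 7.0)

    def test_zero_delay_true_lags_match_condition(self, cfg, still_nodes, quiet_profile):
        s = simulate_registration_session(still_nodes, cfg, quiet_profile)
        tf = s.truth["flicker"]
        np.testing.assert_allclose(
            tf.true_lag_deg.to_numpy(), tf.phase_condition_deg.to_numpy()
        )

    def test_noiseless_peak_recovers_base_latency(self, cfg, still_nodes, quiet_profile):
        """With no delay, jitter, or noise the averaged target epoch peaks
        at the nominal latency to within one sample."""
        s = simulate_registration_session(still_nodes, cfg, quiet_profile)
        flashes = s.events[(s.events.kind == "flash") & (s.events.block == 0)]
        epochs = preprocess.extract_epochs(s.recording, flashes, 0.0, 600.0)
        targets = EpochSet([ep for ep in epochs if ep.meta["is_target"]])
        avg = preprocess.average_epochs(targets, ["node_id"])[0]
        pz = avg.samples[avg.channel_index(["Pz"])][0]
        peak_ms = np.argmax(pz) / avg.sfreq * 1000.0
        assert abs(peak_ms - quiet_profile.p300_base_latency) <= 1000.0 / cfg.sampling_rate

    def test_latency_minus_lag_constant_across_nodes(self, cfg, delayed_nodes, quiet_profile):
        """True P300 latency and true SSVEP lag share the transmission-delay
        term, so latency - lag*T/360 is constant over nodes without jitter."""
        s = simulate_registration_session(delayed_nodes, cfg, quiet_profile)
        lat = (
            s.truth["flashes"]
            .query("is_target")
            .groupby("node_id")
            .true_latency_ms.mean()
        )
        lag0 = (
            s.truth["flicker"]
            .query("phase_condition_deg == 0")
            .set_index("node_id")
            .true_lag_deg
        )
        diff = lat - lag0 * 62.5 / 360.0
        np.testing.assert_allclose(diff, diff.iloc[0], atol=1e-9)


class TestOperationSession:
    def test_trial_group_counts(self, cfg, still_nodes, quiet_profile):
        s = simulate_operation_session(still_nodes, cfg, quiet_profile, n_trials=100)
        flashes = s.events[s.events.kind == "flash"]
        groups = flashes.groupby(["trial", "node_id"]).is_target.first()
        assert int(groups.sum()) == 100
        assert int((~groups.astype(bool)).sum()) == 300

    def test_flashes_per_trial(self, cfg, still_nodes, quiet_profile):
        s = simulate_operation_session(still_nodes, cfg, quiet_profile, n_trials=3)
        per_trial = s.events[s.events.kind == "flash"].groupby("trial").size()
        assert (per_trial == cfg.repetitions * cfg.n_nodes).all()

    def test_deterministic_under_seed(self, cfg, still_nodes):
        p = SubjectProfile(seed=11)
        a = simulate_operation_session(still_nodes, cfg, p, n_trials=1)
        b = simulate_operation_session(still_nodes, cfg, p, n_trials=1)
        np.testing.assert_array_equal(a.recording.data, b.recording.data)
        assert a.events.equals(b.events)

    def test_requires_positive_trials(self, cfg, still_nodes, quiet_profile):
        with pytest.raises(ValueError):
            simulate_operation_session(still_nodes, cfg, quiet_profile, n_trials=0)
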