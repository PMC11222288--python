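"""Grand-average ERPs, method comparison, ERSP."""

import dataclasses
import itertools

import numpy as np
import pytest

from pursuitlock import (EpochSet, PipelineConfig, SimulationParams,
                         align_dataset, build_epoch_set, compare_alignments,
                         compute_ersp, ersp_frequency_grid, grand_average_erp,
                         make_trials, paired_signed_rank)


def epoch_set(data, fs=200.0, window=(0.0, None), labels=None):
    data = np.asarray(data, float)
    labels = labels if labels is not None else np.ones(data.shape[0], int)
    return EpochSet(data, labels, fs,
                    [f"ch{i}" for i in range(data.shape[1])],
                    window_s={"target": window})


class TestGrandAverage:
    def test_single_epoch_is_its_own_average(self, rng):
        data = rng.normal(size=(1, 2, 200))
        s = grand_average_erp(epoch_set(data))
        assert np.allclose(s.mean, data[0])
        assert np.allclose(s.sd, 0.0)

    def test_noiseless_simulator_peak_recovered(self):
        # epochs cut from the raw injected signal (no filtering): the
        # grand average must return the injected 3.4 μV peak at 0.300 s
        p = SimulationParams(n_trials=4, p_target=1.0, seed=19,
                             noise_amplitude_uV=0, alpha_amplitude_uV=0,
                             theta_amplitude_uV=0, delta_amplitude_uV=0,
                             gaze_jitter_px=0)
        cfg = PipelineConfig(artifact_strategy="identity")
        trials = make_trials(p)
        al = align_dataset(trials, "gaze", cfg)
        ep = build_epoch_set(trials, al, cfg, preprocess=False)
        tgt = ep.select(ep.labels == 1)
        # re-rate bookkeeping: epochs were cut from the raw 1 kHz data
        s = grand_average_erp(tgt, channels=["Pz"])
        assert s.peak_amplitude_uV[0] == pytest.approx(3.4, abs=0.01)
        # gaze alignment quantizes to the 60 Hz grid: one sample slack
        assert s.peak_latency_s[0] == pytest.approx(0.300, abs=1 / 60 + 1e-3)

    def test_sd_of_mean_shrinks_like_sqrt_n(self, rng):
        waves = rng.normal(size=(400, 1, 100))
        small = [grand_average_erp(epoch_set(waves[i:i + 25])).mean.std()
                 for i in range(0, 400, 25)]
        big = grand_average_erp(epoch_set(waves[:400])).mean.std()
        assert np.mean(small) / big == pytest.approx(4.0, rel=0.35)

    def test_linearity_under_constant_offset(self, rng):
        data = rng.normal(size=(6, 2, 150))
        a = grand_average_erp(epoch_set(data))
        b = grand_average_erp(epoch_set(data + 2.5))
        assert np.allclose(b.mean, a.mean + 2.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            grand_average_erp(epoch_set(np.zeros((0, 1, 10))))


def signed_rank_oracle(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.asarray(ws, float)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestCompareAlignments:
    def _summary(self, amps, lats):
        from pursuitlock import ErpSummary
        n = len(amps)
        return ErpSummary(["Pz"], np.arange(10) / 10, np.zeros((1, 10)),
                          np.zeros((1, 10)), np.asarray([amps[0]]),
                          np.asarray([lats[0]]), 1) if n == 1 else None

    def test_identical_inputs_give_zero_delta_and_p_one(self):
        from pursuitlock import ErpSummary
        mk = lambda: ErpSummary(["Pz"], np.arange(5) / 5, np.zeros((1, 5)),
                                np.zeros((1, 5)), np.array([2.0]),
                                np.array([0.3]), 4)
        subjects = [mk() for _ in range(6)]
        df = compare_alignments(subjects, subjects)
        assert df.loc["Pz", "d_amplitude_uV"] == 0.0
        assert df.loc["Pz", "p_latency"] == 1.0

    def test_signed_rank_matches_enumeration_oracle(self):
        x = np.array([0.31, 0.28, 0.33, 0.25, 0.36, 0.30, 0.27, 0.41])
        y = np.array([0.52, 0.44, 0.35, 0.61, 0.33, 0.58, 0.49, 0.40])
        p = paired_signed_rank(x, y)
        assert p == pytest.approx(signed_rank_oracle(x - y), abs=1e-12)

    def test_oracle_agreement_on_random_tables(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = x + rng.normal(size=8) * 0.5
            assert paired_signed_rank(x, y) == pytest.approx(
                signed_rank_oracle(x - y), abs=1e-12)

    def test_gaze_alignment_gives_sharper_peak_than_trigger(self):
        """Random search delays smear the trigger-aligned average; epochs
        are cut from the raw signal so the comparison isolates alignment."""
        p = SimulationParams(n_trials=40, p_target=1.0, seed=29,
                             channels=("Pz",))
        cfg = PipelineConfig(artifact_strategy="identity")
        trials = make_trials(p)
        peaks = {}
        for method in ("gaze", "trigger"):
            al = align_dataset(trials, method, cfg)
            ep = build_epoch_set(trials, al, cfg, preprocess=False)
            s = grand_average_erp(ep.select(ep.labels == 1), channels=["Pz"])
            peaks[method] = s.peak_amplitude_uV[0]
        assert peaks["gaze"] > peaks["trigger"]

    def test_mismatched_subjects_rejected(self):
        from pursuitlock import ErpSummary
        mk = lambda: ErpSummary(["Pz"], np.arange(5) / 5, np.zeros((1, 5)),
                                np.zeros((1, 5)), np.array([2.0]),
                                np.array([0.3]), 4)
        with pytest.raises(ValueError):
            compare_alignments([mk(), mk()], [mk()])


class TestErsp:
    def test_frequency_grid_has_189_bins(self):
        grid = ersp_frequency_grid((1.2, 20.0), 0.1)
        assert grid.size == 189
        assert grid[0] == pytest.approx(1.2) and grid[-1] == pytest.approx(20.0)

    def test_stationary_sinusoid_is_zero_db(self):
        fs, dur = 200.0, 6.0
        t = np.arange(int(fs * dur)) / fs
        sig = np.sin(2 * np.pi * 10 * t)
        ep = epoch_set(sig[None, None, :], fs=fs, window=(0.0, dur))
        m = compute_ersp(ep, baseline_window_s=(1.5, 2.5))
        interior = (m.times >= 1.5) & (m.times <= 4.5)
        f10 = np.argmin(np.abs(m.freqs_hz - 10.0))
        assert np.abs(m.values_db[0][f10, interior]).max() < 0.2

    def test_amplitude_doubling_steps_six_db(self):
        fs, dur = 200.0, 8.0
        t = np.arange(int(fs * dur)) / fs
        amp = np.where(t < 4.0, 1.0, 2.0)
        sig = amp * np.sin(2 * np.pi * 10 * t)
        ep = epoch_set(sig[None, None, :], fs=fs, window=(0.0, dur))
        m = compute_ersp(ep, baseline_window_s=(1.0, 3.0))
        f10 = np.argmin(np.abs(m.freqs_hz - 10.0))
        t6 = np.argmin(np.abs(m.times - 6.0))
        assert m.values_db[0, f10, t6] == pytest.approx(10 * np.log10(4),
                                                        abs=0.3)

    def test_white_noise_averages_to_zero_db(self, rng):
        """Whole-epoch baseline: deviations shrink with epoch count."""
        fs = 200.0
        data = rng.normal(size=(120, 1, int(3 * fs)))

        def max_abs_db(n):
            ep = epoch_set(data[:n], fs=fs, window=(0.0, 3.0))
            m = compute_ersp(ep, baseline_window_s=(0.0, 3.0),
                             freq_range_hz=(4.0, 20.0), step_hz=0.5)
            interior = (m.times >= 1.0) & (m.times <= 2.0)
            return np.abs(m.values_db[0][:, interior]).max()

        few, many = max_abs_db(12), max_abs_db(120)
        assert many < few  # estimator noise shrinks with epoch count
        # residual at 120 epochs: sampling noise plus the small positive
        # bias a whole-epoch baseline inherits from edge-deflated power
        assert many < 1.5

    def test_short_epoch_rejected(self):
        ep = epoch_set(np.zeros((1, 1, 200)), fs=200.0, window=(0.0, 1.0))
        with pytest.raises(ValueError, match="wavelet"):
            compute_ersp(ep)

    def test_baseline_outside_epoch_rejected(self):
        ep = epoch_set(np.random.default_rng(0).normal(size=(1, 1, 800)),
                       fs=200.0, window=(0.0, 4.0))
        with pytest.raises(ValueError, match="baseline"):
            compute_ersp(ep, baseline_window_s=(5.0, 6.0))

    def test_simulator_spectral_dynamics_recovered(self):
        """Alpha/theta suppression after +0.7 s and an early delta boost,
        relative to a pre-recognition baseline."""
        p = SimulationParams(n_trials=6, p_target=1.0, seed=23,
                             channels=("Cz", "Pz"))
        cfg = PipelineConfig(artifact_strategy="identity",
                             epoch_target_window_s=(-4.0, 2.0),
                             epoch_nontarget_window_s=(-12.0, -6.0))
        trials = make_trials(p)
        al = align_dataset(trials, "gaze", cfg)
        ep = build_epoch_set(trials, al, cfg)
        tgt = ep.select(ep.labels == 1)
        m = compute_ersp(tgt, baseline_window_s=(-3.5, -0.5),
                         freq_range_hz=(1.2, 20.0), step_hz=0.2)
        alpha = (m.freqs_hz >= 8) & (m.freqs_hz <= 13)
        delta = (m.freqs_hz >= 1.5) & (m.freqs_hz <= 4)
        late = (m.times >= 1.0) & (m.times <= 1.8)
        early = (m.times >= 0.1) & (m.times <= 1.0)
        assert m.values_db[0][np.ix_(alpha, late)].mean() < -1.0
        assert m.values_db[0][np.ix_(delta, early)].mean() > 1.0
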