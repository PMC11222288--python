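"""Pseudo-online detection: replaying recordings through the causal pipeline.

Trials are split 80/20 (stratified by target presence); a decoder is
trained on gaze-aligned epochs of the training split, then each test
recording is scanned with 1-s windows advanced in 100-ms steps (starting
2 s before the reference moment) and every window is classified. A target
command fires only after k consecutive target-class outputs (k = 1, 2, 3),
which trades hit rate against false alarms. Performance per threshold:

    HR  — fraction of target trials with a command within 1.5 s of onset,
    FAR — fraction of trials with a spurious command,
    SA  — system accuracy, SA = (1 − FAR + HR) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .decode import FeatureSet, FittedPipeline, cwt_band_power, fit_pipeline, zscore_epochs
from .gaze import align_dataset
from .io import EEGRecording, TargetAnnotation
from .preprocess import build_epoch_set, preprocess_recording

log = logging.getLogger(__name__)


def system_accuracy(far: float, hr: float) -> float:
    """System accuracy: SA = (1 − FAR + HR) / 2, rates as fractions."""
    return (1.0 - far + hr) / 2.0


# --------------------------------------------------------------------------
# splitting and windowing
# --------------------------------------------------------------------------

def split_train_test(trials: list, fraction: float = 0.8,
                     seed: int = 0) -> tuple[list, list]:
    """Disjoint, exhaustive split, stratified by target presence."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(trials) < 5:
        raise ValueError("need at least 5 trials to split")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(trials))
    train_idx: list[int] = []
    test_idx: list[int] = []
    flags = np.array([t.annotation.has_target for t in trials])
    for flag in (True, False):
        grp = idx[flags == flag]
        if grp.size == 0:
            continue
        perm = rng.permutation(grp)
        n_train = int(round(fraction * grp.size))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [trials[i] for i in train_idx], [trials[i] for i in test_idx]


def sliding_windows(rec: EEGRecording, reference_time: float | None,
                    start_s: float = -2.0, width_s: float = 1.0,
                    step_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Window grid and sliced data for one recording.

    Windows are ``[reference + start + j·step, +width)``. With a ``None``
    reference the grid spans the whole recording from t = 0 (the nontarget
    replay convention). Returns ``(start_times, windows)`` with windows
    shaped ``n × channels × samples``; a grid extending past the recording
    end is truncated with a warning.
    """
    fs = rec.sample_rate
    width_n = int(round(width_s * fs))
    step_n = int(round(step_s * fs))
    if step_n < 1 or width_n < 1:
        raise ValueError("window and step must be at least one sample")
    t0 = 0.0 if reference_time is None else reference_time + start_s
    raw_i0 = int(round(t0 * fs))
    if raw_i0 < 0:
        log.warning("window grid clipped at recording start")
    i0 = max(raw_i0, 0)
    starts = []
    slices = []
    i = i0
    while i + width_n <= rec.n_samples:
        starts.append(i / fs)
        slices.append(rec.data[:, i:i + width_n])
        i += step_n
    if not starts:
        raise ValueError("recording shorter than one window")
    return np.asarray(starts), np.stack(slices)


# --------------------------------------------------------------------------
# threshold rule and scoring
# --------------------------------------------------------------------------

def apply_threshold_rule(outputs, k: int) -> list[int]:
    """Indices where the k-th consecutive target output completes.

    After a command fires, the run counter re-arms (resets), so one long
    run of target outputs produces one command per k outputs, not one per
    sample.
    """
    if k < 1:
        raise ValueError("threshold k must be ≥ 1")
    commands = []
    run = 0
    for i, out in enumerate(outputs):
        run = run + 1 if out else 0
        if run >= k:
            commands.append(i)
            run = 0
    return commands


@dataclass
class DetectionRun:
    """Per-trial sliding-window outputs on the pseudo-online grid."""

    trial_id: str
    has_target: bool
    onset_time: float | None
    window_starts: np.ndarray
    window_width_s: float
    outputs: np.ndarray  # 1 = target-class output per window

    def command_times(self, k: int) -> np.ndarray:
        """A command is stamped at the end of its k-th consecutive window."""
        idx = apply_threshold_rule(self.outputs, k)
        return self.window_starts[idx] + self.window_width_s


@dataclass
class OnlineReport:
    """HR / FAR / SA for one consecutive-output threshold."""

    threshold: int
    hr: float
    far: float
    sa: float
    n_target: int
    n_nontarget: int
    outcomes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "hr": self.hr, "far": self.far,
                "sa": self.sa, "n_target": self.n_target,
                "n_nontarget": self.n_nontarget}


def score_run(runs: list[DetectionRun], k: int,
              hit_window_s: float = 1.5,
              strict_late_commands: bool = False) -> OnlineReport:
    """Score one threshold over a set of detection runs.

    A hit is a command within ``(onset, onset + hit_window]`` on a target
    trial. A false alarm is any command on a nontarget trial, or a command
    at or before onset on a target trial (commands later than the hit
    window count as false alarms only in strict mode; by default they are
    ignored and logged). FAR is the fraction of trials with ≥ 1 false
    alarm; the denominator includes every trial.
    """
    n_target = sum(r.has_target for r in runs)
    n_nontarget = len(runs) - n_target
    hits = 0
    fa_trials = 0
    late_ignored = 0
    outcomes = []
    for r in runs:
        cmds = r.command_times(k)
        if r.has_target:
            on = r.onset_time
            hit = bool(np.any((cmds > on) & (cmds <= on + hit_window_s)))
            early = np.any(cmds <= on)
            late = np.any(cmds > on + hit_window_s)
            fa = bool(early or (strict_late_commands and late))
            late_ignored += int(late and not strict_late_commands)
            hits += hit
            outcome = "hit" if hit else "miss"
        else:
            fa = cmds.size > 0
            outcome = "false_alarm" if fa else "correct_reject"
        fa_trials += fa
        outcomes.append({"trial_id": r.trial_id, "outcome": outcome,
                         "n_commands": int(cmds.size)})
    if late_ignored:
        log.info("threshold %d: late commands ignored on %d target trials",
                 k, late_ignored)
    hr = hits / n_target if n_target else float("nan")
    far = fa_trials / len(runs) if runs else float("nan")
    return OnlineReport(k, hr, far, system_accuracy(far, hr),
                        n_target, n_nontarget, outcomes)


# --------------------------------------------------------------------------
# end-to-end replay
# --------------------------------------------------------------------------

def _window_features(windows: np.ndarray, fs: float,
                     config: PipelineConfig) -> np.ndarray:
    z = zscore_epochs(windows)
    n = z.shape[0]
    X = np.empty((n, z.shape[1] * z.shape[2]))
    for i in range(n):
        X[i] = cwt_band_power(z[i], fs, config.cwt_band_hz,
                              config.cwt_freq_step_hz).ravel()
    return X


def detect_trial(rec: EEGRecording, annot: TargetAnnotation,
                 pipeline: FittedPipeline, config: PipelineConfig,
                 preprocessed: bool = False) -> DetectionRun:
    """Replay one recording through the causal detection pipeline."""
    if not preprocessed:
        rec = preprocess_recording(rec, config)
    reference = annot.onset_time if annot.has_target else None
    starts, windows = sliding_windows(rec, reference, config.online_start_s,
                                      config.online_window_s,
                                      config.online_step_s)
    X = _window_features(windows, rec.sample_rate, config)
    outputs = pipeline.predict(X)
    return DetectionRun(annot.trial_id, annot.has_target, annot.onset_time,
                        starts, config.online_window_s,
                        np.asarray(outputs, dtype=int))


def run_pseudo_online(trials: list, config: PipelineConfig | None = None,
                      classifier: str = "svm", seed: int = 0,
                      alignment_method: str = "gaze",
                      channel_selection: bool = False
                      ) -> tuple[list[OnlineReport], list[DetectionRun]]:
    """Full pseudo-online evaluation on a trial set.

    Splits trials 80/20, trains the decoder on aligned epochs of the
    training split, replays every test trial, and scores each configured
    consecutive-output threshold.
    """
    config = config or PipelineConfig()
    train, test = split_train_test(trials, config.train_fraction, seed)
    alignments = align_dataset(train, alignment_method, config)
    epochs = build_epoch_set(train, alignments, config)
    features = FeatureSet(
        _window_features(epochs.epochs, epochs.fs, config),
        epochs.labels, list(epochs.channel_labels), epochs.n_times, epochs.fs)
    pipeline = fit_pipeline(features, classifier, config, seed,
                            channel_selection=channel_selection)
    runs = [detect_trial(t.eeg, t.annotation, pipeline, config)
            for t in test]
    reports = [score_run(runs, k, config.hit_window_s,
                         config.strict_late_commands)
               for k in config.thresholds]
    for rep in reports:
        log.info("threshold %d: HR %.3f FAR %.3f SA %.3f",
                 rep.threshold, rep.hr, rep.far, rep.sa)
    return reports, runs
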