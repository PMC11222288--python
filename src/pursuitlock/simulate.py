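"""Synthetic EEG + gaze trial generator.

Emulates the statistical structure that gaze-aligned ERP extraction relies
on, with ground truth for parameter-recovery tests:

* a visual-search phase in which gaze saccades between fixation points,
  followed — once the observer "recognizes" the target, a random delay
  after its onset — by smooth pursuit locked to the drifting target region;
* a P300-like positive EEG deflection (parietal maximum, peak ~300 ms
  after recognition) injected at the recognition moment;
* 1/f background noise plus ongoing alpha/theta/delta oscillations, with
  the alpha/theta envelope attenuated from ~0.7 s after recognition and a
  transient delta power boost at recognition — the spectral dynamics the
  time-frequency stage is expected to recover;
* optional blink artifacts (frontal-dominant slow transients) to exercise
  the artifact-removal stage.

Everything is deterministic given ``(params, trial_seed)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (EEGRecording, GazeTrace, TargetAnnotation, TargetRegion,
                 ViewingGeometry, read_annotation, read_gaze_trace,
                 read_recording, write_annotation, write_gaze_trace,
                 write_recording)

log = logging.getLogger(__name__)

#: scalp gain of the recognition ERP per 10-20 site (parietal maximum,
#: falling off with distance on the cap); unlisted sites get the floor.
ERP_TOPOGRAPHY = {
    "Pz": 1.0, "P3": 0.85, "P4": 0.85, "POz": 0.9, "CPz": 0.8,
    "Cz": 0.7, "Oz": 0.55, "O1": 0.5, "O2": 0.5, "C3": 0.5, "C4": 0.5,
    "Fz": 0.35, "F3": 0.3, "F4": 0.3, "Fp1": 0.2, "Fp2": 0.2,
}
ERP_TOPOGRAPHY_FLOOR = 0.25

#: frontal weighting of blink artifacts.
BLINK_TOPOGRAPHY = {"Fp1": 1.0, "Fp2": 1.0, "Fz": 0.8, "F3": 0.6, "F4": 0.6,
                    "Cz": 0.3, "C3": 0.2, "C4": 0.2}
BLINK_TOPOGRAPHY_FLOOR = 0.05


@dataclass
class SimulationParams:
    """Generator settings; defaults describe the emulated study conditions.

    20-s videos, half containing one low-quality target appearing at a
    random time, recognition lagging onset by a uniform 0.3–3 s search
    delay, gaze at 60 Hz on a 1920×1080 screen, EEG at 1,000 Hz, and a
    ~3.4 μV parietal ERP peaking 300 ms after recognition.
    """

    n_trials: int = 240
    p_target: float = 0.5
    video_duration_s: float = 20.0
    onset_window_s: tuple = (5.0, 12.0)
    search_delay_s: tuple = (0.3, 3.0)

    channels: tuple = ("Fz", "Cz", "C3", "C4", "Pz", "P3", "P4", "Oz")
    eeg_fs: float = 1000.0
    gaze_fs: float = 60.0

    erp_peak_latency_s: float = 0.3
    erp_peak_amplitude_uV: float = 3.4
    erp_duration_s: float = 0.8

    noise_amplitude_uV: float = 4.0       # RMS of the 1/f background
    one_over_f_exponent: float = 1.0
    alpha_amplitude_uV: float = 4.0       # 10 Hz
    theta_amplitude_uV: float = 2.5       # 5.5 Hz
    delta_amplitude_uV: float = 2.0       # 2.5 Hz
    alpha_theta_attenuation: float = 0.4  # envelope factor after recognition
    attenuation_onset_s: float = 0.7      # relative to recognition
    delta_boost_factor: float = 2.0
    delta_boost_duration_s: float = 1.5

    target_half_extent_px: tuple = (48.0, 27.0)
    target_drift_px_s: float = 30.0
    fixation_dwell_s: tuple = (0.2, 0.4)
    min_saccade_px: float = 300.0
    gaze_jitter_px: float = 3.0
    pursuit_gain: float = 1.0
    blink_artifacts: bool = False
    blink_rate_hz: float = 0.2
    blink_amplitude_uV: float = 120.0

    seed: int = 0
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        if not 0 <= self.p_target <= 1:
            raise ValueError("p_target must be in [0, 1]")
        for name in ("video_duration_s", "eeg_fs", "gaze_fs", "erp_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.search_delay_s[0] < 0 or self.search_delay_s[0] > self.search_delay_s[1]:
            raise ValueError("search_delay_s must be an ordered non-negative interval")

    def erp_gain(self, label: str) -> float:
        return ERP_TOPOGRAPHY.get(label, ERP_TOPOGRAPHY_FLOOR)


@dataclass
class SimulationGroundTruth:
    """Per-trial latent variables the pipeline is supposed to recover."""

    trial_id: str
    recognition_time: float | None
    search_delay_s: float | None
    erp_peak_latency_s: float
    erp_peak_amplitude_uV: dict[str, float]


@dataclass
class TrialBundle:
    """One simulated (or loaded) trial: all streams plus optional truth."""

    trial_id: str
    eeg: EEGRecording
    gaze: GazeTrace
    annotation: TargetAnnotation
    truth: SimulationGroundTruth | None = None


# --------------------------------------------------------------------------
# ERP template
# --------------------------------------------------------------------------

def erp_template(latency_s: float, amplitude_uV: float, duration_s: float,
                 fs: float) -> np.ndarray:
    """Smooth unimodal positive waveform, zero at both ends.

    An asymmetric raised-cosine bump: it rises over ``[0, latency]`` and
    decays over ``[latency, duration]``, attaining exactly ``amplitude`` at
    ``latency``. A P300-like monophasic morphology without claiming any
    particular biophysical shape.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if not 0 <= latency_s <= duration_s:
        raise ValueError("latency must lie within [0, duration]")
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    w = np.zeros(n)
    if latency_s > 0:
        rise = t <= latency_s
        w[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / latency_s))
    fall = t > latency_s
    if duration_s > latency_s:
        w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - latency_s)
                                    / (duration_s - latency_s)))
    elif latency_s == duration_s:
        w[-1] = 1.0
    w[-1] = 0.0 if latency_s < duration_s else w[-1]
    return amplitude_uV * w


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise with the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _smoothstep(t: np.ndarray, t0: float, width: float = 0.1) -> np.ndarray:
    """0→1 cosine ramp starting at t0, of the given width (seconds)."""
    s = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * s))


# --------------------------------------------------------------------------
# gaze synthesis
# --------------------------------------------------------------------------

def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free trajectory into [lo, hi] by mirror reflection."""
    span = hi - lo
    if span <= 0:
        return np.full_like(p, lo)
    q = np.mod(p - lo, 2 * span)
    return lo + np.where(q > span, 2 * span - q, q)


def _make_region(params: SimulationParams, rng: np.random.Generator,
                 onset: float) -> TargetRegion:
    g = params.geometry
    hw, hh = params.target_half_extent_px
    margin = 60.0
    lo_x, hi_x = hw + margin, g.screen_width_px - hw - margin
    lo_y, hi_y = hh + margin, g.screen_height_px - hh - margin
    x0 = rng.uniform(lo_x, hi_x)
    y0 = rng.uniform(lo_y, hi_y)
    ang = rng.uniform(0, 2 * np.pi)
    vx = params.target_drift_px_s * np.cos(ang)
    vy = params.target_drift_px_s * np.sin(ang)
    ts = np.arange(onset, params.video_duration_s + 1e-9, 1.0 / 30.0)
    cx = _reflect(x0 + vx * (ts - onset), lo_x, hi_x)
    cy = _reflect(y0 + vy * (ts - onset), lo_y, hi_y)
    return TargetRegion(times=ts, cx=cx, cy=cy,
                        half_w=np.full(ts.size, hw),
                        half_h=np.full(ts.size, hh))


def _rect_distance(px, py, cx, cy, hw, hh) -> float:
    """Euclidean distance from a point to a rectangle (0 if inside)."""
    dx = max(abs(px - cx) - hw, 0.0)
    dy = max(abs(py - cy) - hh, 0.0)
    return float(np.hypot(dx, dy))


def _search_fixations(params: SimulationParams, rng: np.random.Generator,
                      until: float, annot: TargetAnnotation,
                      avoid_after: float | None) -> list[tuple[float, float, float, float]]:
    """Fixation schedule (t0, t1, x, y) covering [0, until).

    Consecutive points are ≥ ``min_saccade_px`` apart so inter-fixation
    jumps are supra-threshold saccades; points whose dwell overlaps the
    post-onset window keep clear of the (dilated) target region so the
    search phase cannot coincide with the target by construction.
    """
    g = params.geometry
    # keep-out margin: the 1° default coincidence tolerance plus headroom,
    # so a search fixation can never count as target coincidence
    keep_out = params.geometry.degrees_to_pixels(1.0) + 60.0
    fixations: list[tuple[float, float, float, float]] = []
    t = 0.0
    prev = None
    while t < until - 1e-9:
        dwell = rng.uniform(*params.fixation_dwell_s)
        t1 = min(t + dwell, until)
        for _ in range(60):
            x = rng.uniform(40.0, g.screen_width_px - 40.0)
            y = rng.uniform(40.0, g.screen_height_px - 40.0)
            if prev is not None and np.hypot(x - prev[0], y - prev[1]) < params.min_saccade_px:
                continue
            if annot.has_target and avoid_after is not None and t1 > avoid_after:
                tt = np.clip([t, 0.5 * (t + t1), t1],
                             annot.onset_time, annot.video_duration)
                ok = all(
                    _rect_distance(x, y, *[float(v) for v in annot.region.at(tc)])
                    > keep_out for tc in tt)
                if not ok:
                    continue
            break
        fixations.append((t, t1, x, y))
        prev = (x, y)
        t = t1
    return fixations


def _simulate_gaze(params: SimulationParams, rng: np.random.Generator,
                   annot: TargetAnnotation,
                   recognition: float | None) -> GazeTrace:
    n = int(round(params.video_duration_s * params.gaze_fs))
    t = np.arange(n) / params.gaze_fs
    x = np.empty(n)
    y = np.empty(n)
    search_until = recognition if recognition is not None else params.video_duration_s
    fixations = _search_fixations(params, rng, search_until, annot,
                                  annot.onset_time if annot.has_target else None)
    starts = np.array([f[0] for f in fixations])
    for i, ti in enumerate(t):
        if recognition is not None and ti >= recognition - 1e-9:
            cx, cy, _, _ = annot.region.at(ti)
            cx0, cy0, _, _ = annot.region.at(recognition)
            x[i] = cx0 + params.pursuit_gain * (cx - cx0)
            y[i] = cy0 + params.pursuit_gain * (cy - cy0)
        else:
            k = int(np.searchsorted(starts, ti, side="right") - 1)
            x[i] = fixations[k][2]
            y[i] = fixations[k][3]
    if params.gaze_jitter_px > 0:
        x += rng.normal(0, params.gaze_jitter_px, n)
        y += rng.normal(0, params.gaze_jitter_px, n)
    return GazeTrace(t, x, y, params.geometry, params.gaze_fs)


# --------------------------------------------------------------------------
# EEG synthesis
# --------------------------------------------------------------------------

def _simulate_eeg(params: SimulationParams, rng: np.random.Generator,
                  annot: TargetAnnotation,
                  recognition: float | None) -> EEGRecording:
    fs = params.eeg_fs
    n = int(round(params.video_duration_s * fs))
    t = np.arange(n) / fs
    data = np.zeros((len(params.channels), n))

    alpha_env = np.ones(n)
    delta_env = np.ones(n)
    if recognition is not None:
        att = _smoothstep(t, recognition + params.attenuation_onset_s)
        alpha_env -= (1 - params.alpha_theta_attenuation) * att
        boost = (_smoothstep(t, recognition)
                 - _smoothstep(t, recognition + params.delta_boost_duration_s))
        delta_env += (params.delta_boost_factor - 1) * boost

    template = None
    erp_start = None
    if recognition is not None and params.erp_peak_amplitude_uV != 0:
        template = erp_template(params.erp_peak_latency_s,
                                params.erp_peak_amplitude_uV,
                                params.erp_duration_s, fs)
        erp_start = int(round(recognition * fs))

    blinks: list[float] = []
    if params.blink_artifacts:
        n_blinks = rng.poisson(params.blink_rate_hz * params.video_duration_s)
        blinks = sorted(rng.uniform(0.2, params.video_duration_s - 0.5,
                                    size=n_blinks))
    blink_wave = erp_template(0.15, 1.0, 0.3, fs) if blinks else None

    for c, label in enumerate(params.channels):
        ch = _pink_noise(rng, n, fs, params.one_over_f_exponent,
                         params.noise_amplitude_uV)
        for amp, freq, env in (
                (params.alpha_amplitude_uV, 10.0, alpha_env),
                (params.theta_amplitude_uV, 5.5, alpha_env),
                (params.delta_amplitude_uV, 2.5, delta_env)):
            if amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                ch += amp * env * np.sin(2 * np.pi * freq * t + phase)
        if template is not None:
            gain = params.erp_gain(label)
            stop = min(erp_start + template.size, n)
            ch[erp_start:stop] += gain * template[:stop - erp_start]
        if blinks:
            bg = BLINK_TOPOGRAPHY.get(label, BLINK_TOPOGRAPHY_FLOOR)
            for tb in blinks:
                i0 = int(round(tb * fs))
                stop = min(i0 + blink_wave.size, n)
                ch[i0:stop] += params.blink_amplitude_uV * bg * blink_wave[:stop - i0]
        data[c] = ch

    events = [(annot.onset_time, "TGT")] if annot.has_target else []
    return EEGRecording(data=data, sample_rate=fs,
                        channel_labels=list(params.channels),
                        events=events, reference="CPz")


# --------------------------------------------------------------------------
# trials and datasets
# --------------------------------------------------------------------------

def _trial_rng(params: SimulationParams, trial_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(params.seed) & 0x7FFFFFFF, int(trial_seed) & 0x7FFFFFFF])


def simulate_trial(params: SimulationParams, trial_seed: int,
                   has_target: bool | None = None,
                   trial_id: str | None = None) -> TrialBundle:
    """Generate one trial: EEG + gaze + annotation + ground truth.

    Deterministic given ``(params, trial_seed)``. The recognition moment is
    snapped to the 60 Hz gaze grid (the finest clock the alignment stage
    can resolve); the ERP is injected at the nearest EEG sample.
    """
    rng = _trial_rng(params, trial_seed)
    trial_id = trial_id if trial_id is not None else f"trial_{trial_seed:010d}"
    if has_target is None:
        has_target = bool(rng.random() < params.p_target)

    if not has_target:
        annot = TargetAnnotation(trial_id=trial_id, has_target=False,
                                 video_duration=params.video_duration_s)
        gaze = _simulate_gaze(params, rng, annot, None)
        eeg = _simulate_eeg(params, rng, annot, None)
        truth = SimulationGroundTruth(trial_id, None, None,
                                      params.erp_peak_latency_s, {})
        return TrialBundle(trial_id, eeg, gaze, annot, truth)

    onset = rng.uniform(*params.onset_window_s)
    # recognition + the 1-s target window must fit inside the video
    max_delay = params.video_duration_s - onset - 1.05
    lo, hi = params.search_delay_s
    if max_delay < lo:
        raise ValueError("no admissible search delay: onset too close to "
                         "video end for the configured delay distribution")
    if max_delay < hi:
        log.warning("search delay truncated to [%.3f, %.3f] s", lo, max_delay)
        hi = max_delay
    delay = rng.uniform(lo, hi)
    recognition = onset + delay
    recognition = round(recognition * params.gaze_fs) / params.gaze_fs
    delay = recognition - onset

    region = _make_region(params, rng, onset)
    annot = TargetAnnotation(trial_id=trial_id, has_target=True,
                             video_duration=params.video_duration_s,
                             onset_time=onset, region=region)
    gaze = _simulate_gaze(params, rng, annot, recognition)
    eeg = _simulate_eeg(params, rng, annot, recognition)
    truth = SimulationGroundTruth(
        trial_id, recognition, delay, params.erp_peak_latency_s,
        {lab: params.erp_gain(lab) * params.erp_peak_amplitude_uV
         for lab in params.channels})
    return TrialBundle(trial_id, eeg, gaze, annot, truth)


def make_trials(params: SimulationParams) -> list[TrialBundle]:
    """Generate ``n_trials`` in memory with exactly round(n·p_target) targets."""
    if params.n_trials < 1:
        raise ValueError("n_trials must be ≥ 1")
    n_target = int(round(params.n_trials * params.p_target))
    flags = np.zeros(params.n_trials, dtype=bool)
    flags[:n_target] = True
    order_rng = np.random.default_rng([int(params.seed) & 0x7FFFFFFF, 0xD1CE])
    order_rng.shuffle(flags)
    seeds = np.random.SeedSequence(int(params.seed) & 0x7FFFFFFF)\
        .generate_state(params.n_trials) & 0x7FFFFFFF
    return [simulate_trial(params, int(seeds[i]), has_target=bool(flags[i]),
                           trial_id=f"trial_{i:04d}")
            for i in range(params.n_trials)]


def _truth_to_dict(truth: SimulationGroundTruth) -> dict:
    return {"trial_id": truth.trial_id,
            "recognition_time": truth.recognition_time,
            "search_delay_s": truth.search_delay_s,
            "erp_peak_latency_s": truth.erp_peak_latency_s,
            "erp_peak_amplitude_uV": truth.erp_peak_amplitude_uV}


def simulate_dataset(params: SimulationParams, out_dir) -> Path:
    """Write ``n_trials`` trial bundles plus a manifest to ``out_dir``.

    Each trial gets gaze (CSV), annotation (JSON), EEG (native bundle) and
    ground-truth (JSON) files; ``manifest.json`` records per-trial seeds so
    the dataset is exactly reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_target = int(round(params.n_trials * params.p_target))
    flags = np.zeros(params.n_trials, dtype=bool)
    flags[:n_target] = True
    order_rng = np.random.default_rng([int(params.seed) & 0x7FFFFFFF, 0xD1CE])
    order_rng.shuffle(flags)
    seeds = np.random.SeedSequence(int(params.seed) & 0x7FFFFFFF)\
        .generate_state(params.n_trials) & 0x7FFFFFFF

    manifest = {"seed": params.seed, "n_trials": params.n_trials,
                "p_target": params.p_target, "trials": []}
    for i in range(params.n_trials):
        tid = f"trial_{i:04d}"
        bundle = simulate_trial(params, int(seeds[i]),
                                has_target=bool(flags[i]), trial_id=tid)
        write_gaze_trace(bundle.gaze, out_dir / f"{tid}.gaze.csv")
        write_annotation(bundle.annotation, out_dir / f"{tid}.annot.json")
        write_recording(bundle.eeg, out_dir / f"{tid}.eeg.npz")
        (out_dir / f"{tid}.truth.json").write_text(
            json.dumps(_truth_to_dict(bundle.truth)))
        manifest["trials"].append({"trial_id": tid, "seed": int(seeds[i]),
                                   "has_target": bool(flags[i])})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("wrote %d trials (%d targets) to %s",
             params.n_trials, n_target, out_dir)
    return out_dir


def load_dataset(directory, geometry: ViewingGeometry | None = None
                 ) -> list[TrialBundle]:
    """Load a dataset written by :func:`simulate_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    geometry = geometry or ViewingGeometry()
    bundles = []
    for entry in manifest["trials"]:
        tid = entry["trial_id"]
        gaze = read_gaze_trace(directory / f"{tid}.gaze.csv", geometry)
        annot = read_annotation(directory / f"{tid}.annot.json")
        eeg = read_recording(directory / f"{tid}.eeg.npz")
        truth = None
        tf = directory / f"{tid}.truth.json"
        if tf.exists():
            d = json.loads(tf.read_text())
            truth = SimulationGroundTruth(
                d["trial_id"], d["recognition_time"], d["search_delay_s"],
                d["erp_peak_latency_s"], d["erp_peak_amplitude_uV"])
        bundles.append(TrialBundle(tid, eeg, gaze, annot, truth))
    return bundles
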