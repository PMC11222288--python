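"""EEG preprocessing chain and epoch construction.

Fixed chain order: baseline correction (subtract the mean of the first 10%
of samples) → amplitude rejection (> 200 μV dropped, applied at epoch
level) → downsampling to 200 Hz → zero-phase FIR band-pass 0.5–49 Hz →
pluggable artifact-component removal → common-average re-referencing.
Epochs are then cut relative to the alignment time: [0, 1) s as the target
sample and [−4, −3) s as the nontarget sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .gaze import AlignmentResult
from .io import EEGRecording

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# epoch container
# --------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Aligned fixed-width EEG windows with labels and provenance.

    ``epochs``: ``n × channels × samples`` (μV); ``labels``: 1 = target,
    0 = nontarget; ``provenance``: which alignment produced each epoch.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]
    trial_ids: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    window_s: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n × channels × samples")
        if self.epochs.shape[0] != self.labels.size:
            raise ValueError("labels must match epoch count")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match epoch channel count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return EpochSet(self.epochs[idx], self.labels[idx], self.fs,
                        list(self.channel_labels),
                        [self.trial_ids[i] for i in idx] if self.trial_ids else [],
                        [self.provenance[i] for i in idx] if self.provenance else [],
                        dict(self.window_s))

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return EpochSet(np.concatenate([p.epochs for p in parts]),
                        np.concatenate([p.labels for p in parts]),
                        first.fs, list(first.channel_labels),
                        sum((p.trial_ids for p in parts), []),
                        sum((p.provenance for p in parts), []),
                        dict(first.window_s))


# --------------------------------------------------------------------------
# per-recording stages
# --------------------------------------------------------------------------

def baseline_correct(rec: EEGRecording) -> EEGRecording:
    """Remove zero drift: subtract each channel's mean over the first 10%."""
    n = rec.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples for baseline correction")
    n10 = n // 10
    ref = rec.data[:, :n10].mean(axis=1, keepdims=True)
    return rec.copy_with(data=rec.data - ref)


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``target_fs`` (≤ current rate)."""
    if target_fs > rec.sample_rate:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == rec.sample_rate:
        return rec.copy_with()
    frac = Fraction(target_fs / rec.sample_rate).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=1, padtype="line")
    return rec.copy_with(data=data, sample_rate=target_fs)


def _bandpass_taps(low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    # windowed-sinc (Hamming); order targets a ≤0.5 Hz transition at the
    # low edge (≈3.3/Δf normalized for Hamming)
    width = min(0.5, low_hz)
    numtaps = int(np.ceil(3.3 * fs / width)) | 1
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs,
                         window="hamming")


def bandpass_fir(rec: EEGRecording, low_hz: float, high_hz: float
                 ) -> EEGRecording:
    """Zero-phase (forward–backward) FIR band-pass."""
    if not 0 < low_hz < high_hz < rec.sample_rate / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    taps = _bandpass_taps(low_hz, high_hz, rec.sample_rate)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen)
    return rec.copy_with(data=data)


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels (idempotent)."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs ≥ 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="common-average")


def remove_artifact_components(rec: EEGRecording, strategy: str = "heuristic",
                               ica_band_hz: tuple = (2.0, 49.0),
                               random_state: int = 0) -> EEGRecording:
    """Pluggable artifact-component removal stage.

    ``identity`` passes the data through unchanged. The default
    ``heuristic`` strategy estimates an ICA unmixing matrix on a copy
    band-passed to 2–49 Hz, then flags components whose time courses
    correlate strongly (|r| > 0.7) with a frontal-channel reference (the
    usual blink signature) or whose power is overwhelmingly below 3 Hz
    with frontal-dominant topography, and reconstructs the data without
    the flagged components. On decomposition failure the input is passed
    through with a warning.
    """
    if strategy == "identity":
        return rec.copy_with()
    if strategy != "heuristic":
        raise ValueError(f"unknown artifact strategy {strategy!r}")
    if rec.n_channels < 2:
        raise ValueError("ICA-based artifact removal needs ≥ 2 channels")

    from sklearn.decomposition import FastICA

    frontal = [i for i, lab in enumerate(rec.channel_labels)
               if lab.upper().startswith(("FP", "AF", "F"))]
    if not frontal:
        frontal = [0]
    try:
        train = bandpass_fir(rec, *ica_band_hz).data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(random_state=random_state, max_iter=500, tol=1e-3)
            ica.fit(train.T)
        sources = ica.transform(rec.data.T).T  # components × samples
        mixing = ica.mixing_  # channels × components
        frontal_ref = rec.data[frontal].mean(axis=0)
        flags = []
        freqs = np.fft.rfftfreq(sources.shape[1], d=1.0 / rec.sample_rate)
        for k in range(sources.shape[0]):
            s = sources[k]
            r = np.corrcoef(s, frontal_ref)[0, 1] if s.std() > 0 else 0.0
            w = np.abs(mixing[:, k])
            frontal_dom = w[frontal].max() >= 0.8 * w.max()
            ps = np.abs(np.fft.rfft(s)) ** 2
            low_frac = ps[freqs < 3.0].sum() / max(ps.sum(), 1e-30)
            flags.append((abs(r) > 0.7 and frontal_dom)
                         or (low_frac > 0.8 and frontal_dom))
        flags = np.asarray(flags)
        if not flags.any():
            return rec.copy_with()
        kept = sources.copy()
        kept[flags] = 0.0
        recon = (mixing @ kept) + ica.mean_[:, None]
        log.info("artifact removal: dropped %d/%d components",
                 int(flags.sum()), flags.size)
        return rec.copy_with(data=recon)
    except Exception as exc:  # noqa: BLE001 - degrade gracefully
        log.warning("ICA decomposition failed (%s); passing data through", exc)
        return rec.copy_with()


def preprocess_recording(rec: EEGRecording,
                         config: PipelineConfig | None = None) -> EEGRecording:
    """Run the continuous-signal part of the chain in its fixed order."""
    config = config or PipelineConfig()
    log.info("preprocess chain: baseline → downsample(%g Hz) → FIR %s Hz → "
             "artifact(%s) → common-average", config.target_fs_hz,
             config.bandpass_hz, config.artifact_strategy)
    rec = baseline_correct(rec)
    rec = downsample(rec, config.target_fs_hz)
    rec = bandpass_fir(rec, *config.bandpass_hz)
    rec = remove_artifact_components(rec, config.artifact_strategy,
                                     config.ica_band_hz,
                                     random_state=config.rng_seed)
    rec = rereference_common_average(rec)
    return rec


# --------------------------------------------------------------------------
# epoch-level stages
# --------------------------------------------------------------------------

def reject_epochs(epochs: EpochSet, limit_uV: float = 200.0) -> EpochSet:
    """Drop epochs whose max |amplitude| strictly exceeds ``limit_uV``."""
    if limit_uV <= 0:
        raise ValueError("limit must be positive")
    if epochs.n_epochs == 0:
        return epochs
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep = peak <= limit_uV
    dropped = int((~keep).sum())
    if dropped:
        log.info("amplitude rejection: dropped %d/%d epochs (> %g μV)",
                 dropped, epochs.n_epochs, limit_uV)
    if not keep.any():
        log.warning("amplitude rejection removed every epoch")
    return epochs.select(keep)


def extract_epochs(rec: EEGRecording, alignment: AlignmentResult,
                   config: PipelineConfig | None = None) -> EpochSet:
    """Cut the target and nontarget windows around the alignment time.

    Windows are half-open ``[t0, t1)`` in seconds relative to alignment;
    a nontarget window that starts before the recording yields only the
    target epoch (logged); a target window past the recording end raises.
    """
    config = config or PipelineConfig()
    if not alignment.found:
        raise ValueError("alignment_time absent; cannot epoch")
    fs = rec.sample_rate
    t0 = alignment.alignment_time
    parts, labels, prov = [], [], []
    for label, (w0, w1) in ((1, config.epoch_target_window_s),
                            (0, config.epoch_nontarget_window_s)):
        i0 = int(round((t0 + w0) * fs))
        n = int(round((w1 - w0) * fs))
        if i0 + n > rec.n_samples:
            if label == 1:
                raise ValueError(
                    f"trial {alignment.trial_id}: target window exceeds "
                    "recording end")
            log.info("trial %s: nontarget window past recording end; omitted",
                     alignment.trial_id)
            continue
        if i0 < 0:
            log.info("trial %s: %s window precedes recording start; omitted",
                     alignment.trial_id, "target" if label else "nontarget")
            continue
        parts.append(rec.data[:, i0:i0 + n])
        labels.append(label)
        prov.append(alignment.method)
    if not parts:
        raise ValueError(f"trial {alignment.trial_id}: no extractable window")
    return EpochSet(np.stack(parts), np.asarray(labels), fs,
                    list(rec.channel_labels),
                    [alignment.trial_id] * len(parts), prov,
                    {"target": tuple(config.epoch_target_window_s),
                     "nontarget": tuple(config.epoch_nontarget_window_s)})


def build_epoch_set(trials, alignments: list[AlignmentResult],
                    config: PipelineConfig | None = None,
                    preprocess: bool = True) -> EpochSet:
    """Preprocess, epoch and amplitude-reject a whole aligned dataset."""
    config = config or PipelineConfig()
    by_id = {t.trial_id: t for t in trials}
    parts = []
    for al in alignments:
        if not al.found:
            continue
        trial = by_id.get(al.trial_id)
        if trial is None:
            log.warning("trial %s: no data for alignment; skipped", al.trial_id)
            continue
        rec = preprocess_recording(trial.eeg, config) if preprocess else trial.eeg
        try:
            parts.append(extract_epochs(rec, al, config))
        except ValueError as exc:
            log.warning("%s", exc)
    if not parts:
        raise ValueError("no epochs could be extracted")
    return reject_epochs(EpochSet.concatenate(parts), config.amplitude_reject_uV)
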