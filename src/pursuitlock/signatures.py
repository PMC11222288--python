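"""Neural-signature analyses.

Grand-average ERPs with peak amplitude/latency, paired signed-rank
comparison of the two alignment methods, and event-related spectral
perturbation (ERSP) maps from a Morlet wavelet decomposition whose cycle
count grows with frequency (3 cycles at the lowest frequency, exponent 0.5
— the usual EEG time-frequency convention), expressed in dB relative to a
baseline window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve

from .preprocess import EpochSet

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# ERP
# --------------------------------------------------------------------------

@dataclass
class ErpSummary:
    """Grand-average waveforms and peak metrics for a set of channels."""

    channel_labels: list[str]
    times: np.ndarray              # seconds relative to alignment
    mean: np.ndarray               # channels × samples, μV
    sd: np.ndarray                 # across-epoch SD band
    peak_amplitude_uV: np.ndarray  # per channel
    peak_latency_s: np.ndarray
    n_epochs: int

    def channel(self, label: str) -> int:
        return self.channel_labels.index(label)


def grand_average_erp(epochs: EpochSet, channels: list[str] | None = None,
                      peak_window_s: tuple = (0.2, 0.6)) -> ErpSummary:
    """Pointwise mean ± SD across epochs, with positive-peak metrics.

    The peak is the maximum positive deflection inside ``peak_window_s``
    (seconds relative to the alignment moment). Pass target epochs only;
    an empty set is an error.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    if channels is None:
        channels = list(epochs.channel_labels)
    idx = [epochs.channel_labels.index(c) for c in channels]
    data = epochs.epochs[:, idx, :]
    t0 = epochs.window_s.get("target", (0.0, None))[0] or 0.0
    times = t0 + np.arange(epochs.n_times) / epochs.fs
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    w = (times >= peak_window_s[0]) & (times <= peak_window_s[1])
    if not w.any():
        w = np.ones_like(times, dtype=bool)
    peak_idx = np.argmax(mean[:, w], axis=1)
    wt = times[w]
    return ErpSummary(list(channels), times, mean, sd,
                      peak_amplitude_uV=mean[:, w].max(axis=1),
                      peak_latency_s=wt[peak_idx],
                      n_epochs=epochs.n_epochs)


def paired_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded; the exact null distribution is used for
    small samples. All-zero differences (identical inputs) return p = 1 —
    there is no evidence of any shift.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "auto"
    try:
        return float(stats.wilcoxon(d, method=method).pvalue)
    except ValueError:
        return float(stats.wilcoxon(d, method="auto").pvalue)


def compare_alignments(erp_gaze: list[ErpSummary],
                       erp_trigger: list[ErpSummary]) -> pd.DataFrame:
    """Per-channel comparison of the two epoch-extraction methods.

    Inputs are matched per-subject summaries (same order, same channels).
    Returns Δamplitude/Δlatency (gaze − trigger, averaged over subjects)
    and two-sided paired signed-rank p-values on the per-subject peak
    latency and amplitude.
    """
    if len(erp_gaze) != len(erp_trigger) or not erp_gaze:
        raise ValueError("need matched, non-empty per-subject summaries")
    chans = erp_gaze[0].channel_labels
    for s in (*erp_gaze, *erp_trigger):
        if s.channel_labels != chans:
            raise ValueError("mismatched channel sets between summaries")
    amp_g = np.array([s.peak_amplitude_uV for s in erp_gaze])
    amp_t = np.array([s.peak_amplitude_uV for s in erp_trigger])
    lat_g = np.array([s.peak_latency_s for s in erp_gaze])
    lat_t = np.array([s.peak_latency_s for s in erp_trigger])
    rows = []
    for j, ch in enumerate(chans):
        rows.append({
            "channel": ch,
            "d_amplitude_uV": float((amp_g[:, j] - amp_t[:, j]).mean()),
            "d_latency_s": float((lat_g[:, j] - lat_t[:, j]).mean()),
            "p_amplitude": paired_signed_rank(amp_g[:, j], amp_t[:, j]),
            "p_latency": paired_signed_rank(lat_g[:, j], lat_t[:, j]),
        })
    return pd.DataFrame(rows).set_index("channel")


# --------------------------------------------------------------------------
# ERSP
# --------------------------------------------------------------------------

@dataclass
class ErspMap:
    """channels × frequencies × time, in dB relative to baseline."""

    values_db: np.ndarray
    freqs_hz: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    baseline_window_s: tuple

    def channel(self, label: str) -> int:
        return self.channel_labels.index(label)


def _morlet_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return wav / np.sqrt((np.abs(wav) ** 2).sum())


def morlet_power(data: np.ndarray, fs: float, freqs: np.ndarray,
                 base_cycles: float = 3.0, expansion: float = 0.5
                 ) -> np.ndarray:
    """Time-frequency power of ``channels × samples`` data.

    Cycle count per frequency: ``base_cycles · (f / f_min)^expansion`` —
    constant cycles at ``expansion = 0``, constant window length at 1.
    Returns ``channels × len(freqs) × samples``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    out = np.empty((data.shape[0], freqs.size, data.shape[1]))
    f0 = freqs.min()
    for j, f in enumerate(freqs):
        cyc = base_cycles * (f / f0) ** expansion
        wav = _morlet_wavelet(f, cyc, fs)
        conv = fftconvolve(data, wav[None, :], mode="same", axes=1)
        out[:, j, :] = np.abs(conv) ** 2
    return out


def ersp_frequency_grid(freq_range_hz: tuple = (1.2, 20.0),
                        step_hz: float = 0.1) -> np.ndarray:
    lo, hi = freq_range_hz
    n = int(round((hi - lo) / step_hz)) + 1
    return np.linspace(lo, hi, n)


def compute_ersp(epochs: EpochSet, baseline_window_s: tuple | None = None,
                 freq_range_hz: tuple = (1.2, 20.0), step_hz: float = 0.1,
                 cycles: float = 3.0, expansion: float = 0.5) -> ErspMap:
    """Average Morlet power over epochs, in dB relative to baseline.

    ``baseline_window_s`` is given in seconds relative to the alignment
    moment (like the epoch windows); default is the first 20% of the
    epoch. The epoch must be at least one full wavelet long at the lowest
    analysis frequency, so ERSP wants wide epochs (e.g. [−4, 2) s) rather
    than the 1-s decoding windows.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot compute ERSP of an empty epoch set")
    freqs = ersp_frequency_grid(freq_range_hz, step_hz)
    duration = epochs.n_times / epochs.fs
    if duration < cycles / freqs.min():
        raise ValueError(
            f"epoch ({duration:g} s) shorter than one {cycles}-cycle wavelet "
            f"at {freqs.min():g} Hz ({cycles / freqs.min():g} s)")
    t0 = epochs.window_s.get("target", (0.0, None))[0] or 0.0
    times = t0 + np.arange(epochs.n_times) / epochs.fs
    if baseline_window_s is None:
        b0, b1 = times[0], times[0] + 0.2 * duration
    else:
        b0, b1 = baseline_window_s
    bmask = (times >= b0) & (times < b1)
    if not bmask.any() or b0 < times[0] - 1e-9 or b1 > times[-1] + 1.0 / epochs.fs + 1e-9:
        raise ValueError("baseline window lies outside the epoch")

    power = np.zeros((epochs.n_channels, freqs.size, epochs.n_times))
    for e in range(epochs.n_epochs):
        power += morlet_power(epochs.epochs[e], epochs.fs, freqs,
                              cycles, expansion)
    power /= epochs.n_epochs
    base = power[:, :, bmask].mean(axis=2, keepdims=True)
    values_db = 10.0 * np.log10(np.maximum(power, 1e-30)
                                / np.maximum(base, 1e-30))
    return ErspMap(values_db, freqs, times, list(epochs.channel_labels),
                   (float(b0), float(b1)))
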