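"""Pipeline configuration.

One flat, serializable record of every tunable the detection pipeline uses,
with the published operating points as defaults: 30°/s I-VT velocity
threshold, 200 μV amplitude rejection, 200 Hz working rate, 0.5–49 Hz FIR
band, [0,1) s / [−4,−3) s epoch windows, 1–13 Hz CWT feature band,
1.2–20 Hz (step 0.1) ERSP grid, 90% PCA variance, and the pseudo-online
grid (−2 s start, 1 s window, 0.1 s step, 1.5 s hit window, thresholds
1–3). Any subset of keys may be given in a YAML file; absent keys take
these defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .io import ViewingGeometry

log = logging.getLogger(__name__)


def _tuple(x) -> tuple:
    return tuple(x) if isinstance(x, (list, tuple)) else (x,)


@dataclass
class PipelineConfig:
    # gaze alignment
    velocity_threshold_deg_s: float = 30.0
    coincidence_tolerance_deg: float = 1.0
    min_dwell_samples: int = 3
    velocity_median_filter: bool = False

    # preprocessing
    amplitude_reject_uV: float = 200.0
    target_fs_hz: float = 200.0
    bandpass_hz: tuple = (0.5, 49.0)
    ica_band_hz: tuple = (2.0, 49.0)
    artifact_strategy: str = "heuristic"  # or "identity"

    # epoching (seconds relative to alignment, half-open)
    epoch_target_window_s: tuple = (0.0, 1.0)
    epoch_nontarget_window_s: tuple = (-4.0, -3.0)

    # features / ERSP
    cwt_band_hz: tuple = (1.0, 13.0)
    cwt_freq_step_hz: float = 0.5
    ersp_freq_range_hz: tuple = (1.2, 20.0)
    ersp_freq_step_hz: float = 0.1
    ersp_cycles: float = 3.0
    ersp_expansion: float = 0.5

    # decoding
    pca_variance: float = 0.90
    svm_gamma: float = 0.05
    svm_C: float = 1.0
    rlda_lambda: float = 0.9
    xgb_n_estimators: int = 20
    xgb_learning_rate: float = 0.1
    xgb_booster: str = "dart"
    xgb_max_depth: int = 10
    cv_folds: int = 6
    channel_fisher_reduce: str = "mean"  # or "max"

    # pseudo-online
    online_start_s: float = -2.0
    online_window_s: float = 1.0
    online_step_s: float = 0.1
    hit_window_s: float = 1.5
    thresholds: tuple = (1, 2, 3)
    train_fraction: float = 0.8
    strict_late_commands: bool = False

    rng_seed: int = 0
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        for key in ("bandpass_hz", "ica_band_hz", "epoch_target_window_s",
                    "epoch_nontarget_window_s", "cwt_band_hz",
                    "ersp_freq_range_hz", "thresholds"):
            setattr(self, key, _tuple(getattr(self, key)))
        if isinstance(self.geometry, dict):
            self.geometry = ViewingGeometry(**self.geometry)
        self._validate()

    def _validate(self) -> None:
        def check(cond: bool, key: str, msg: str) -> None:
            if not cond:
                raise ValueError(f"config key {key!r}: {msg}")

        check(self.velocity_threshold_deg_s > 0, "velocity_threshold_deg_s",
              "must be positive")
        check(self.coincidence_tolerance_deg >= 0, "coincidence_tolerance_deg",
              "must be non-negative")
        check(self.min_dwell_samples >= 1, "min_dwell_samples", "must be ≥ 1")
        check(self.amplitude_reject_uV > 0, "amplitude_reject_uV",
              "must be positive")
        check(self.target_fs_hz > 0, "target_fs_hz", "must be positive")
        for key in ("bandpass_hz", "ica_band_hz", "cwt_band_hz",
                    "ersp_freq_range_hz"):
            lo, hi = getattr(self, key)
            check(0 < lo < hi, key, "must satisfy 0 < low < high")
        for key in ("epoch_target_window_s", "epoch_nontarget_window_s"):
            lo, hi = getattr(self, key)
            check(lo < hi, key, "window start must precede end")
        t0, t1 = self.epoch_target_window_s
        n0, n1 = self.epoch_nontarget_window_s
        check(abs((t1 - t0) - (n1 - n0)) < 1e-9, "epoch_nontarget_window_s",
              "target and nontarget windows must be equally long")
        check(0 < self.pca_variance <= 1, "pca_variance", "must be in (0, 1]")
        check(0 <= self.rlda_lambda <= 1, "rlda_lambda", "must be in [0, 1]")
        check(self.svm_gamma > 0, "svm_gamma", "must be positive")
        check(self.svm_C > 0, "svm_C", "must be positive")
        check(self.cv_folds >= 2, "cv_folds", "must be ≥ 2")
        check(self.online_window_s > 0, "online_window_s", "must be positive")
        check(self.online_step_s > 0, "online_step_s", "must be positive")
        check(self.hit_window_s > 0, "hit_window_s", "must be positive")
        check(all(int(k) >= 1 for k in self.thresholds), "thresholds",
              "must all be ≥ 1")
        check(0 < self.train_fraction < 1, "train_fraction", "must be in (0,1)")
        check(self.channel_fisher_reduce in ("mean", "max"),
              "channel_fisher_reduce", "must be 'mean' or 'max'")
        check(self.artifact_strategy in ("heuristic", "identity"),
              "artifact_strategy", "must be 'heuristic' or 'identity'")

    # ---- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config; absent file or keys take the documented defaults."""
    if path is None:
        cfg = PipelineConfig()
    else:
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = PipelineConfig.from_dict(d)
    log.info("effective config: %s", cfg.to_dict())
    return cfg
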