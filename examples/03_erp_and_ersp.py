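"""Neural signatures: grand-average ERP peak and time-frequency dynamics.

Shows the injected parietal positivity in the gaze-aligned grand average
and the post-recognition spectral changes (alpha/theta suppression from
~0.7 s, early delta increase) in the ERSP map.
"""

import numpy as np

from pursuitlock import (PipelineConfig, SimulationParams, align_dataset,
                         build_epoch_set, compute_ersp, grand_average_erp,
                         make_trials)

trials = make_trials(SimulationParams(n_trials=24, p_target=1.0, seed=23))

# ERP: 1-s target epochs through the full preprocessing chain
cfg = PipelineConfig(artifact_strategy="identity")
al = align_dataset(trials, "gaze", cfg)
ep = build_epoch_set(trials, al, cfg)
s = grand_average_erp(ep.select(ep.labels == 1), channels=["Pz", "Fz"])
for ch, amp, lat in zip(s.channel_labels, s.peak_amplitude_uV,
                        s.peak_latency_s):
    print(f"{ch}: grand-average peak {amp:4.2f} μV at {lat * 1e3:.0f} ms "
          "after the recognition moment")
print("(the common-average reference on this sparse 8-channel montage "
      "attenuates the focal parietal ERP relative to its injected 3.4 μV)")

# ERSP: wide epochs around the recognition moment, pre-recognition baseline
wide = PipelineConfig(artifact_strategy="identity",
                      epoch_target_window_s=(-4.0, 2.0),
                      epoch_nontarget_window_s=(-12.0, -6.0))
epw = build_epoch_set(trials, al, wide)
m = compute_ersp(epw.select(epw.labels == 1), baseline_window_s=(-3.5, -0.5),
                 step_hz=0.2)
cz = m.channel("Pz") if "Pz" in m.channel_labels else 0
alpha = (m.freqs_hz >= 8) & (m.freqs_hz <= 13)
delta = (m.freqs_hz >= 1.5) & (m.freqs_hz <= 4)
late = (m.times >= 1.0) & (m.times <= 1.8)
early = (m.times >= 0.1) & (m.times <= 1.0)
print(f"alpha power 1.0–1.8 s after recognition: "
      f"{m.values_db[cz][np.ix_(alpha, late)].mean():+.2f} dB (suppression)")
print(f"delta power 0.1–1.0 s after recognition: "
      f"{m.values_db[cz][np.ix_(delta, early)].mean():+.2f} dB (increase)")
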