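"""Pseudo-online detection: sliding-window replay with threshold rule.

Splits trials 80/20, trains on gaze-aligned epochs, then scans each test
recording with 1-s windows in 100-ms steps; a detection command fires
after k consecutive target-class outputs. Reports HR/FAR/SA per k.
"""

from pursuitlock import (PipelineConfig, SimulationParams, make_trials,
                         run_pseudo_online)

cfg = PipelineConfig(artifact_strategy="identity")
# a favourable operating point: clean EEG and fast target discovery
params = SimulationParams(n_trials=40, p_target=0.5, seed=55,
                          search_delay_s=(0.3, 0.8),
                          noise_amplitude_uV=2.0,
                          alpha_theta_attenuation=0.25,
                          delta_boost_factor=2.5)
trials = make_trials(params)
reports, runs = run_pseudo_online(trials, cfg, classifier="rlda", seed=0)

for r in reports:
    print(f"threshold k={r.threshold}: HR {100 * r.hr:5.1f}%  "
          f"FAR {100 * r.far:5.1f}%  SA {100 * r.sa:5.1f}%")
print("raising k trades hits for false alarms; SA = (1 − FAR + HR)/2 "
      "summarizes the trade-off")
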