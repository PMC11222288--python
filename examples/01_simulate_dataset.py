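"""Generate a small synthetic EEG + gaze dataset and inspect its ground truth.

Each trial is a 20-s "video": half contain a drifting low-visibility
target; the observer's gaze saccades during search, then smoothly pursues
the target from the recognition moment, where a ~3.4 μV parietal ERP is
injected into the EEG.
"""

import numpy as np

from pursuitlock import SimulationParams, simulate_dataset, load_dataset

params = SimulationParams(n_trials=8, p_target=0.5, seed=7)
out = simulate_dataset(params, "scratch/example_dataset")
trials = load_dataset(out)

print(f"wrote {len(trials)} trials to {out}")
for t in trials:
    if t.annotation.has_target:
        print(f"  {t.trial_id}: target onset {t.annotation.onset_time:6.2f} s, "
              f"recognized at {t.truth.recognition_time:6.2f} s "
              f"(search delay {t.truth.search_delay_s:.2f} s)")
    else:
        print(f"  {t.trial_id}: no target")

delays = [t.truth.search_delay_s for t in trials if t.annotation.has_target]
print(f"mean search delay: {np.mean(delays):.2f} s — the random lag between "
      "target onset and recognition that breaks stimulus-locked epoching")
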