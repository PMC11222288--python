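"""Locate recognition moments from gaze and compare with ground truth.

The I-VT rule labels each 60 Hz gaze sample saccade (≥ 30°/s) or
sub-threshold; the first sustained sub-threshold sample inside the known
target region is the recognition moment the ERP is aligned to.
"""

import numpy as np

from pursuitlock import (PipelineConfig, SimulationParams, align_dataset,
                         make_trials)

cfg = PipelineConfig()
trials = make_trials(SimulationParams(n_trials=12, p_target=1.0, seed=11))

for method in ("gaze", "trigger"):
    results = align_dataset(trials, method, cfg)
    truth = {t.trial_id: t.truth.recognition_time for t in trials}
    errs = [abs(r.alignment_time - truth[r.trial_id])
            for r in results if r.found]
    print(f"{method:8s}: {sum(r.found for r in results)}/{len(results)} "
          f"aligned, median |error vs true recognition| = "
          f"{1e3 * np.median(errs):6.1f} ms")

print("gaze alignment lands within ~one 60 Hz gaze sample of the true "
      "recognition moment; trigger alignment is off by the whole search delay")
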