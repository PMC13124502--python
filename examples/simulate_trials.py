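"""Generate a small synthetic experiment and inspect its ground truth.

Each trial carries 2 minutes of 6-channel prefrontal EEG (512 Hz),
single-lead ECG and skin conductance (500 Hz), a condition label, SAM
self-ratings, and the injected ground truth (R-peak positions, SCR onset
times, per-pair alpha-asymmetry offsets).
"""

import numpy as np

from emofuse.synth import SynthConfig, generate_experiment

config = SynthConfig(n_participants=2, seed=1)
trials = generate_experiment(config)

print(f"{len(trials)} trials from {config.n_participants} participants")
labels = [t.label for t in trials]
for c in ("positive", "neutral", "negative"):
    print(f"  {c}: {labels.count(c)} trials")

t = trials[0]
print(f"\nfirst trial {t.trial_id} ({t.label}):")
print(f"  EEG {t.eeg.shape} at {t.eeg_fs:.0f} Hz, range ±{np.abs(t.eeg).max():.0f} uV")
print(f"  {t.ground_truth['r_peak_indices'].size} heartbeats, "
      f"{t.ground_truth['scr_onsets_s'].size} skin-conductance responses")
print(f"  SAM valence {t.sam_valence:.1f}, arousal {t.sam_arousal:.1f} (1-9 scale)")
# The injected asymmetry offsets are what the EEG features should recover:
# positive trials carry right-shifted alpha power (higher AI).
print(f"  true AI offsets (FP2/FP1, F4/F3, F8/F7): "
      f"{np.round(t.ground_truth['ai_offsets'], 2)}")
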