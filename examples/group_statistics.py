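"""Group-level repeated-measures ANOVA across the three conditions.

Trials are averaged to participant x condition cells; each measure gets a
one-way repeated-measures ANOVA with Greenhouse-Geisser correction and
Tukey HSD post-hoc tests. On synthetic data with injected effects, the
dorsolateral asymmetry indices and the autonomic features come out
significant while the frontopolar index (near-zero injected shift) and
raw LF/HF band powers may not.
"""

from emofuse.pipeline import group_level_stats, simulate_and_extract
from emofuse.synth import SynthConfig

trial_table, _, _ = simulate_and_extract(SynthConfig(n_participants=8, seed=9))
stats = group_level_stats(trial_table)

cols = ["measure", "F", "df1", "df2", "p_gg", "partial_eta_sq", "significant"]
print(stats[cols].round(4).to_string(index=False))
print(
    "\np_gg is the sphericity-corrected p-value; 'significant' applies the"
    "\nalpha = 0.05 screening rule used for fold-wise feature selection."
)
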