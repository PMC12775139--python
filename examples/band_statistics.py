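"""Band-wise spectral statistics between frustration conditions.

Simulates trials under low and medium frustration and runs the per-band
power analysis: Welch PSD per window, integrated band power, and a
two-sample t-test per canonical EEG band.  The induced beta/gamma power
increase in the medium condition shows up as negative t values (sign
convention: t = (low - mid) / se).
"""

import numpy as np

from frustmi import SyntheticConfig, band_psd_ttest, simulate_trial

cfg = SyntheticConfig(seed=0)
rng = np.random.default_rng(0)

low = np.stack([simulate_trial("low", "left", cfg, rng) for _ in range(20)])
mid = np.stack([simulate_trial("mid", "left", cfg, rng) for _ in range(20)])

stats = band_psd_ttest(low, mid, rate=cfg.rate)
print("Low vs Mid frustration, 20 trials per condition")
print(stats.table[["t", "p"]].round(4))
print()
print("Beta and Gamma show strong negative t values: the medium condition")
print("carries more power there, as the frustration induction intends.")
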