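"""Classify free-running rhythmicity in constant darkness and estimate period.

Simulates a cohort entrained for 3 LD days then released into DD for 12 days
with a 23.5-h free-running period; analyses DD days 3-11 with the 30-min
binned periodogram and the 0.01 rhythmicity threshold.
"""

import warnings

from flysleep import cohort_rhythm_table, fft_rhythm
from flysleep.simulate import ActivitySimConfig, simulate_cohort

warnings.simplefilter("ignore")

cfg = ActivitySimConfig(n_ld_days=3, n_dd_days=12, period_h=23.5)
traces = simulate_cohort(cfg, n_flies=16, seed=2)

results = [fft_rhythm(t, dd_day_range=(3, 11), threshold=0.01) for t in traces]
cohort = cohort_rhythm_table(results)

print(f"rhythmicity: {cohort.format_rhythmicity()}")
print(f"period: {cohort.mean_period_h:.2f} ± {cohort.sem_period_h:.2f} h")
print(f"FFT value: {cohort.mean_fft:.3f} ± {cohort.sem_fft:.3f}")
print(
    "\nEach fly's 'FFT value' is the share of non-DC spectral power at the "
    "circadian-band peak; flies above 0.01 are rhythmic, and the cohort "
    "period estimate recovers the simulated 23.5 h free-running period."
)
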