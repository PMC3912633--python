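"""Call candidate mutants in a simulated 2,000-line mutagenesis screen.

Line mean sleep is approximately normal across an EMS screen; candidate
sleep mutants are the lines beyond mean ± 3 SD.  Two severe short-sleepers
are planted at −5 SD and recovered.
"""

from flysleep import call_screen_outliers
from flysleep.simulate import simulate_screen_line_means

table, truth = simulate_screen_line_means(
    n_lines=2000, flies_per_line=6, seed=11,
    planted={"L0042": -5.0, "L1337": -5.0},
)
res = call_screen_outliers(table, bin_min=25, k_sd=3.0)

print(f"screen of {len(table)} lines, 6 flies each")
print(f"grand mean sleep {res.grand_mean:.0f} min, SD {res.grand_sd:.0f} min")
print(f"-3 SD cutoff at {res.low_cutoff:.0f} min")
print(f"low (short-sleep) outliers: {res.low_outliers}")
print(f"high outliers: {res.high_outliers}")
print(
    "\nBoth planted mutants fall below the cutoff; any extra calls are the "
    "expected ~0.27% two-sided tail of a normal screen distribution."
)
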