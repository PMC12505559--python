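"""Quantify bile-canalicular secretion kinetics and compare conditions.

Simulates fluorescence traces of dye secretion into canalicular lumina for
three conditions over a 60-minute window (the knockout secretes twice as fast
as wild type), then extracts per-trace amplitude and half-time and compares
the groups nonparametrically.
"""

import numpy as np

import dipackit as dk

ln2 = np.log(2)
params = {
    "WT-HLC": (100.0, ln2 / 12.0, 10.0),  # (amplitude, rate, baseline)
    "KO-HLC": (100.0, ln2 / 6.0, 10.0),   # doubled secretion rate
    "PHH": (100.0, ln2 / 6.0, 10.0),
}
traces, truth = dk.generate_traces(
    40, params, noise_sd=5.0, t_max=60.0, dt=1.0, seed=3, param_cv=0.15, t_lag=5.0
)

summary = dk.summarize_kinetics(traces, baseline_points=5, smooth_window=9)
print("per-group medians (amplitude in fluorescence units, half-time in min):")
print(summary.groupby("group")[["amplitude", "half_time"]].median().round(2))

for metric in ("amplitude", "half_time"):
    comp = dk.compare_groups(summary, metric)
    print(f"\n{metric}: Kruskal-Wallis p = {comp.kruskal_p:.3g}")
    print(comp.pairwise[["group_a", "group_b", "u", "pvalue", "padj"]].to_string(index=False))

# a faster rate halves the onset-referenced half-time; amplitudes stay similar,
# so the half-time comparison should be the significant one
wt = summary.loc[summary["group"] == "WT-HLC", "half_time"].median()
ko = summary.loc[summary["group"] == "KO-HLC", "half_time"].median()
print(f"\nmedian half-time WT {wt:.1f} min vs KO {ko:.1f} min (onset lag 5 min)")
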