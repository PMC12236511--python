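"""Time-resolved particle fractions: is the filament fraction rising with
reaction time?

Generates a five-dataset particle-count table (quench times 57-517 s) with
a known linear filament-fraction trend plus binomial noise, computes
per-dataset fractions (unassigned picks excluded), and tests the trend
with a permutation p-value and a bootstrap confidence interval for the
slope.
"""

from loopstate import time_resolved as T
from loopstate.synthetic import CountsConfig, gen_particle_counts

config = CountsConfig(seed=31)  # truth: slope 8.7e-4 /s, intercept 0.05
table, truth = gen_particle_counts(config)
fractions = T.compute_fractions(table)

for i in range(len(fractions.time_s)):
    print(f"  t = {fractions.time_s[i]:5.0f} s : filament fraction "
          f"{fractions.filament_fraction[i]:.3f} "
          f"+- {fractions.se[i]:.3f} (n = {fractions.assigned_total[i]:.0f})")

result = T.linear_trend(fractions, n_perm=10000, n_boot=10000, seed=31)
print(f"slope     : {result.slope:.3e} per s "
      f"(truth {truth['slope']:.3e}; 95% CI "
      f"[{result.ci_low:.3e}, {result.ci_high:.3e}])")
print(f"Pearson r : {result.pearson_r:.4f}")
print(f"permutation p (two-sided): {result.p_permutation:.4f}")
print()
print("A small permutation p with a positive slope indicates the filament")
print("fraction grows with reaction time, i.e. with accumulating product.")
print("With five datasets the p-value cannot go below ~1/120 (the number")
print("of distinct time-label permutations).")
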