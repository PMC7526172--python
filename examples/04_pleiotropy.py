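"""Rank correlations: positive pleiotropy across ages, and deleteriousness
versus induced aging rate.

Computes Kendall's tau between per-line median relative fecundities at each
pair of assay ages, between the change over an interval and the level at its
start, and between day-5 fecundity and day-33 survival.
"""

import agefec

ds = agefec.simulate_experiment(agefec.paper_like_config(seed=37))

print("positive pleiotropy (tau between ages):")
for pair in [(5, 19), (5, 33), (19, 33)]:
    r = agefec.age_pleiotropy(ds, None, pair)
    print(f"  day {pair[0]:>2} vs day {pair[1]:>2}: tau = {r.tau:5.2f}, "
          f"two-tailed p = {r.p_two_tailed:.2g} ({r.method}, n = {r.n})")

print("\naging rate vs deleteriousness (change vs level; conservative test):")
for pair in [(5, 19), (5, 33), (19, 33)]:
    r = agefec.aging_vs_deleteriousness(ds, None, pair)
    print(f"  days {pair[0]}-{pair[1]}: tau = {r.tau:5.2f}, p = {r.p_two_tailed:.2g}")

r = agefec.survival_pleiotropy(ds)
print(f"\nday-5 fecundity vs day-33 survival: tau = {r.tau:.2f}, p = {r.p_two_tailed:.2g}")
print("\nPositive tau throughout: lines that are worse young are also worse old,")
print("and more-deleterious lines age faster.")
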