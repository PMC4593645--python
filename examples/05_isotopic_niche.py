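"""Isotopic niche width and phase comparison from whole-blood signatures.

Simulates (d13C, d15N) samples for two breeding phases — a narrow
incubation niche and a much wider chick-rearing niche — and computes
the standard ellipse area (SEA, SEAc), its Bayesian posterior (SEA_B),
the probability that one phase's niche is smaller than the other's,
ellipse overlap, and Layman range/hull metrics.
"""

import numpy as np

from foragescape import (compare_groups, ellipse_overlap, layman_metrics,
                         sea_bayes, standard_ellipse)
from foragescape.simulate import simulate_isotopes

df, truth = simulate_isotopes(n_per_group=22, seed=9)
groups = {g: sub[["d13C", "d15N"]].to_numpy() for g, sub in df.groupby("group")}

ellipses, posts = {}, {}
for i, (g, xy) in enumerate(sorted(groups.items())):
    e = standard_ellipse(xy)
    ellipses[g], posts[g] = e, sea_bayes(xy, n_draws=10_000, seed=10 + i)
    lay = layman_metrics(xy)
    print(f"{g}: n={e.n}, SEAc={e.seac:.1f} per-mil^2 "
          f"(SEA_B median {np.median(posts[g].areas):.1f}), "
          f"d15N range {lay['d15N_range']:.1f}, hull {lay['hull_area']:.1f}")

p = compare_groups(posts["incubation"], posts["chick_rearing"])
ov = ellipse_overlap(ellipses["incubation"], ellipses["chick_rearing"], seed=4)
print(f"\nP(incubation niche smaller than chick-rearing) = {p:.3f}")
print(f"ellipse overlap: {ov['pct_of_union']:.1f}% of the combined niche")
print("\nA p near 1 with small overlap reproduces the classic pattern of a "
      "niche expansion between breeding phases.")
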