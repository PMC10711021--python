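"""Radiation-damage ranking: does the sieve remove damaged particles first?

Four equal groups of particles carry increasing accumulated electron dose
(emulating extraction from successively later movie-frame windows); damage
is a dose-proportional B-factor envelope that erodes high-frequency
amplitude. The full 9-iteration sieve runs twice — once with the
highpass band-energy score and once with plain normalized
cross-correlation — and the per-group retained fractions are read at the
iteration with 26.2% cumulative retention.
"""

from particlesieve import DEFAULT_DOSE_GROUPS
from particlesieve.experiments import damage_ranking_experiment

result = damage_ranking_experiment(seed=7, n_particles=400)

print(f"dose groups (e-/A^2): "
      + ", ".join(f"{d:.1f}" for d in DEFAULT_DOSE_GROUPS))
print(f"read at iteration {result.iteration} "
      f"({result.cumulative_pct}% cumulative retention)\n")
for scorer, fractions in result.retained_fraction.items():
    frs = ", ".join(f"{f:.2f}" for f in fractions)
    print(f"{scorer:<10} retained fraction per group: [{frs}]  "
          f"separation {result.separation(scorer):+.2f}")

print("\nA fraction profile decreasing left to right means low-dose "
      "(least damaged) particles\nsurvive preferentially; the separation "
      "is the retained-fraction gap between the\nleast and most damaged "
      "groups. The band-energy score separates dose groups more\nstrongly "
      "than NCC because damage erodes exactly the highpass band it "
      "inspects.")
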