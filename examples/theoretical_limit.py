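"""Theoretical particle-number limits and fold-of-limit for published stacks.

For each dataset the Rosenthal-Henderson limit is evaluated at the standard
defaults (S/N = 1/sqrt(3), N_e = 5 e-/A^2, sigma_e = 0.004 A^2, B = 50 A^2
for a standard Titan Krios) at the dataset's reported resolution and
symmetry, and the final-stack size is expressed as a multiple of that
limit. A fold near 1 means the stack is already close to the minimum
particle count theory allows at that resolution.
"""

from particlesieve import (
    LimitParams,
    fold_of_limit,
    round_half_up,
    symmetry_order,
    theoretical_particle_limit,
)

DATASETS = [
    # name, resolution (A), point group, final-stack particle count
    ("TRPA1", 3.90, "C4", 43585),
    ("hemagglutinin", 3.62, "C3", 130000),
    ("LAT1", 3.11, "C1", 250712),
    ("TRPM8", 2.98, "C4", 42040),
    ("streptavidin", 2.99, "D2", 23991),
]

print(f"{'dataset':<15}{'d (A)':>7}{'sym':>5}{'limit':>8}{'stack':>9}{'fold':>8}")
for name, d, sym, n_stack in DATASETS:
    params = LimitParams(n_asym=symmetry_order(sym), resolution_A=d)
    limit = round_half_up(theoretical_particle_limit(params))
    fold = fold_of_limit(n_stack, params)
    print(f"{name:<15}{d:>7.2f}{sym:>5}{limit:>8d}{n_stack:>9d}{fold:>7.1f}x")

print("\nEach 'limit' is the minimum particle count needed to reach the "
      "listed resolution\non an ideal instrument; 'fold' is how many times "
      "the deposited final stack exceeds it.")
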