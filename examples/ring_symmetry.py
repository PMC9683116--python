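"""Ring-closure symmetry: trajectory fitting, scoring and classification.

Simulates closing-ring trajectories with different degrees of one-sided
drift, fits circles to their outlines, normalizes to the first frame and
scores each closure, then summarizes a cohort the way per-category
percentages are reported.
"""

import numpy as np

from ringmetrics import (
    RingOutline,
    SymmetryResult,
    classify_symmetry,
    fit_circle,
    normalize_trajectory,
    simulate_ring_trajectory,
    summarize_symmetry_classes,
    symmetry_value,
)

def score(asymmetry, seed):
    traj = simulate_ring_trajectory(12, 25.0, asymmetry, seed=seed, jitter=0.3)
    fits = []
    for t, (center, radius) in enumerate(traj):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([center[0] + radius * np.cos(theta),
                               center[1] + radius * np.sin(theta)])
        fits.append(fit_circle(RingOutline(t, points=pts)))
    return symmetry_value(normalize_trajectory(fits))

for asym in (0.0, 0.3, 0.8):
    v = score(asym, seed=7)
    print(f"generative asymmetry {asym:.1f} -> symmetry value {v:.3f} "
          f"({classify_symmetry(v)})")

# A 21-cell cohort split 1 / 13 / 7 across the categories:
cohort = [0.05] + [0.4] * 13 + [0.8] * 7
results = []
for i, asym in enumerate(cohort):
    v = score(asym, seed=100 + i)
    results.append(SymmetryResult(v, classify_symmetry(v)))
print()
print(summarize_symmetry_classes(results).to_string(index=False))
# The symmetry value is the distance between the first-frame ring centre
# and the last-frame ring centre after setting the first ring to centre
# (0,0), radius 1; <0.2 symmetric, 0.2-0.6 asymmetric, >0.6 highly so.
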