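"""Critical radius and uncertainty envelope of the m(R) relation.

Generates noisy per-cell (radius, moment) measurements obeying the size
law m = b1 (R - r_c) with r_c = 0.57 µm, recovers r_c with the
error-weighted linear model, and wraps the scatter in a q = 0.95
directional-quantile envelope (250 directions, polyline-simplified).
"""

import numpy as np

from magnetokinetics.populations import critical_radius, quantile_envelope

rng = np.random.default_rng(3)
R = rng.uniform(0.3, 1.2, 400)
sigma_m = rng.uniform(1e-16, 3e-16, 400)
m = np.clip(5e-15 * (R - 0.57), 0, None) + rng.normal(0, sigma_m)

mask = R > 0.57  # the linear law only holds above the cut-on
fit = critical_radius(R[mask], m[mask], sigma_m[mask])
print(f"critical radius r_c = {fit.r_c:.3f} ± {fit.r_c_se:.3f} µm "
      f"(generating value 0.57 µm)")
print(f"slope b1 = {fit.slope:.2e} A·m² per µm")

env = quantile_envelope(np.column_stack([R, m * 1e15]), q=0.95,
                        n_directions=250)
inside = env.contains(np.column_stack([R, m * 1e15])).mean()
print(f"envelope: {len(env.vertices)} vertices after simplification, "
      f"{inside:.1%} of points inside")
# q bounds each 1D projection at its 95% quantile; the joint mass inside
# the intersection is necessarily lower (~74% for an isotropic Gaussian).
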