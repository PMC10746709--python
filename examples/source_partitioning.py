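"""Bayesian partitioning of sediment organic matter between sources.

Draws sediment delta13C/delta15N mixtures with a known 80:20 POM:plants
split, fits the two-tracer mixing model by MCMC, and cross-checks the
posterior mean against the deterministic grid oracle.
"""

import numpy as np

from marshcarbon import isomix, synthdata
from marshcarbon.datamodel import IsotopeSource

sources = [
    IsotopeSource("plants", -14.0, 0.5, 8.0, 0.5),
    IsotopeSource("POM", -24.0, 0.5, 6.0, 0.5),
]
table, truth = synthdata.gen_isotope_data(
    seed=11, true_proportions=(0.2, 0.8), sources=sources, n_mixtures=10
)

post = isomix.fit_mixing(table.mixtures, sources, n_samples=20000, seed=12)
grid = isomix.grid_posterior(table.mixtures, sources, resolution=0.01)

print(f"true contributions: plants 20%, POM 80%")
for k, name in enumerate(post.source_names):
    print(f"{name:>7}: posterior mean {100 * post.mean[k]:.1f}% "
          f"(95% CI {100 * post.ci_low[k]:.1f}-{100 * post.ci_high[k]:.1f}%), "
          f"grid oracle {100 * grid[k]:.1f}%")
print(f"acceptance rate {post.acceptance_rate:.2f}, min ESS {min(post.ess):.0f}")
print("-> MCMC and exhaustive integration agree to "
      f"{np.max(np.abs(np.array(post.mean) - grid)):.3f} in proportion units")
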