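"""Piecewise path analysis of belowground OC stock drivers.

Simulates plot data from a 5-node metamodel (grain size, accretion rate,
burrow surface, aboveground biomass -> belowground OC stock) with known
path coefficients and site-level intercepts, then refits it.
"""

from marshcarbon import pathsem, synthdata

dag = synthdata.DEFAULT_METAMODEL
coefs = synthdata.DEFAULT_PATH_COEFFICIENTS
data, truth = synthdata.gen_sem_dataset(
    seed=2024, dag=dag, path_coefficients=coefs, n_sites=10, plots_per_site=30
)

result = pathsem.simplify_and_fit_sem(dag, data)

print(f"Fisher's C = {result.fisher_c:.3f}, df = {result.df}, "
      f"P = {result.p_value:.3f} (model fits when P > 0.05)")
for (cause, effect), b in sorted(result.std_coefficients.items()):
    print(f"  {cause} -> {effect}: beta_std = {b:+.3f} "
          f"(generating beta = {coefs[(cause, effect)]:+.2f})")
r2m, r2c = result.r2["belowground_oc_stock"]
print(f"belowground OC stock R^2: marginal {r2m:.2f}, conditional {r2c:.2f}")
print("-> standardized paths recover the sign and rank of the generating "
      "coefficients; conditional R^2 adds the between-site variance")
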