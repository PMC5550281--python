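"""The Poisson wiring null model and its goodness-of-fit classification.

First evaluates the model on its printed worked inputs (151 synapses over 78
candidate cells), then fits the null across a synthetic lobe and prints the
colour-classified grid.
"""

import numpy as np

from alphalobe import (
    GeneratorConfig,
    chi2_gof,
    fit_grid,
    generate,
    poisson_expected_counts,
)

# --- worked example -------------------------------------------------------
M, N = 78, 151
expected = poisson_expected_counts(N, M, k_max=6)
print(f"model: c_k = M (N/M)^k e^(-N/M) / k!, with M={M} cells, N={N} synapses")
for k in (1, 2, 3):
    print(f"  expected cells with {k} synapse(s): {expected[k]:.1f} +/- {np.sqrt(expected[k]):.1f}")
observed = [10, 23, 24, 12, 3, 4, 2]
chi2, df, p = chi2_gof(observed, expected)
print(f"observed {observed}: chi2 = {chi2:.1f} with {df} bins retained, p = {p:.2f}")
print("p > 0.05: the observed wiring is indistinguishable from random assignment.\n")

# --- fit grid on a synthetic lobe -----------------------------------------
config = GeneratorConfig(
    n_kc_per_subtype={"KC-ab-s": 120, "KC-ab-p": 20},
    cells_per_compartment={"a3": [("MBON-a3", 2), ("PPL1-a3", 2)]},
    wiring_rate={
        ("KC-ab-s", "MBON-a3", "a3"): 12.0,
        ("KC-ab-p", "MBON-a3", "a3"): 6.0,
        ("KC-ab-s", "PPL1-a3", "a3"): 2.5,
    },
    seed=3,
)
connectome, _ = generate(config)
grid = fit_grid(connectome)
print(grid[["kc_type", "partner", "m_cells", "n_synapses", "p_value", "fit_class"]].to_string(index=False))
print(
    "\ngreen = consistent with Poisson wiring (p > 0.05); truly-Poisson "
    "synthetic wiring is green in ~95% of fits by construction."
)
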