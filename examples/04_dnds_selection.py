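"""Per-gene dN/dS selection inference with trinucleotide context.

Simulates mutation counts on a 20-gene panel with strong positive
selection on truncating changes in three genes, fits the 96-class neutral
model on synonymous counts and prints the per-gene omega estimates with
Benjamini-Hochberg q-values.
"""

import numpy as np

from chclone.dnds import (
    N_CLASSES, enumerate_site_opportunities, estimate_dnds_table,
    fit_neutral_context_model, global_dnds, simulate_counts,
)
from chclone.simulate import simulate_cds_panel

rng = np.random.default_rng(11)
panel = simulate_cds_panel(n_genes=20, length_codons=300, seed=11)
opps = {g.gene: enumerate_site_opportunities(g) for g in panel}
rates = rng.gamma(2.0, 0.2, N_CLASSES)  # heterogeneous context rates

selected = {"PPM1D": (1.0, 5.0), "TP53": (1.0, 5.0)}  # omega_mis, omega_tru
observed, syn_by_class = simulate_counts(opps, rates, omega=selected, rng=rng)

fitted = fit_neutral_context_model(syn_by_class, opps.values())
estimates = estimate_dnds_table(observed, opps, fitted)

print(f"{'gene':>8} {'omega_mis':>9} {'omega_tru':>9} {'q_tru':>10}")
for e in sorted(estimates, key=lambda e: e.q_tru):
    flag = " *" if e.q_tru < 0.10 else ""
    print(f"{e.gene:>8} {e.omega_mis:9.2f} {e.omega_tru:9.2f} "
          f"{e.q_tru:10.2e}{flag}")
print(f"\nglobal dN/dS: {global_dnds(estimates):.3f}")
# Starred genes reach q < 0.10 for the truncating class; under neutrality
# omega ~ 1 and the global dN/dS sits near 1.
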