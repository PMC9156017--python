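"""Per-site substitution rates: epistasis spreads rates across sites.

The per-site rate is the acceptance probability per test (equivalently,
mean spacing between tests over mean spacing between accepted
substitutions).  Under UE every site sits at 20/21; couplings and fields
push individual sites toward 0 (conserved) or leave them fast.
"""

import numpy as np

from epistasim import (
    EvolutionMode,
    SimulationConfig,
    SyntheticModelSpec,
    generate_potts_model,
    per_site_rates,
    run_matched_replicates,
)

model = generate_potts_model(SyntheticModelSpec(n_sites=60, seed=0))
config = SimulationConfig(total_generations=10_000, burn_in=2_000,
                          n_replicates=20, master_seed=42)
matched = run_matched_replicates(model, model.native_sequence, config)

print(f"{'regime':>6} {'mean rate':>10} {'min':>6} {'max':>6} {'SD across sites':>16}")
for m in (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE):
    prof = per_site_rates([rep[m] for rep in matched])
    print(f"{m.value:>6} {np.nanmean(prof.rate):>10.3f} {np.nanmin(prof.rate):>6.3f} "
          f"{np.nanmax(prof.rate):>6.3f} {np.nanstd(prof.rate):>16.4f}")
print("-> rate heterogeneity across sites (the SD column) is an emergent")
print("   property of the constraints; UE is flat at 20/21 by construction.")
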