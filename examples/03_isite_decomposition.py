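"""Decompose the excess of invariant sites into local and epistatic parts.

I_all(g) counts sites never substituted in tracked generations 1..g;
I_adj additionally requires the site to have been tested at least once.
Subtracting the neutral UE curve isolates selection: combined (CE-UE),
local (IE-UE) and their difference, the contribution of pairwise
epistasis alone — evaluated both at matched time and matched divergence.
"""

import numpy as np

from epistasim import (
    EvolutionMode,
    SimulationConfig,
    SyntheticModelSpec,
    divergence_matched_excess,
    generate_potts_model,
    isite_curve,
    run_matched_replicates,
    time_matched_excess,
)

model = generate_potts_model(SyntheticModelSpec(n_sites=60, seed=0))
config = SimulationConfig(total_generations=10_000, burn_in=2_000,
                          n_replicates=20, master_seed=42)
matched = run_matched_replicates(model, model.native_sequence, config)

for m in (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE):
    curve = isite_curve([rep[m] for rep in matched])
    g = 2 * model.n_sites - 1
    print(f"{m.value}: mean I_all at 2 generations/site = {curve.mean_all[g]:5.1f} "
          f"(I_adj {curve.mean_adj[g]:5.1f}) of N={model.n_sites}")

grid = np.array([1.0, 2.0, 3.0, 4.0])
tm = time_matched_excess(matched, grid)
print("\nexcess I-sites over UE at matched time (generations/site):")
print("  t    combined  local  epistatic  epistatic share")
for k, t in enumerate(grid):
    print(f"  {t:.1f}  {tm.eps_combined_adj[k]:8.2f} {tm.ell_local_adj[k]:6.2f}"
          f" {tm.eps_pairwise_adj[k]:9.2f}  {tm.ratio_adj[k]:14.2f}")

dm = divergence_matched_excess(matched, np.array([1.0, 2.0]))
print("\nat matched divergence (substitutions/site), which controls for the")
print("slower CE clock, epistasis still creates excess invariant sites:")
for k, d in enumerate(dm.grid):
    print(f"  d={d:.1f}: combined {dm.eps_combined_adj[k]:6.2f}, "
          f"epistatic share {dm.ratio_adj[k]:.2f}")
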