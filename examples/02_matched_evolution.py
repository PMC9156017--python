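"""Run matched CE/IE/UE evolution and compare substitution rates.

Each generation picks one random site (the same site in all three regimes,
via a shared random stream) and redraws its residue from the regime's
Gibbs conditional.  The uniform null (UE) accepts 20/21 of proposals;
local fields (IE) and epistatic couplings (CE) purge progressively more.
"""

from epistasim import (
    SimulationConfig,
    SyntheticModelSpec,
    generate_potts_model,
    run_matched_replicates,
    summarize_rates,
)

model = generate_potts_model(SyntheticModelSpec(n_sites=60, seed=0))
config = SimulationConfig(total_generations=10_000, burn_in=2_000,
                          n_replicates=20, master_seed=42)
matched = run_matched_replicates(model, model.native_sequence, config)
summary = summarize_rates(matched)

print(f"{'regime':>6} {'rate (subs/gen)':>16} {'allowed divergence':>19}")
for mode, est in summary.rates.items():
    print(f"{mode.value:>6} {est.mean:>10.3f} ± {est.sd:.3f} {summary.allowed[mode]:>17.1f}%")
print(f"\npurifying selection: combined {summary.purged_combined:.1f}% "
      f"= local {summary.purged_local:.1f}% + epistatic {summary.purged_epistasis:.1f}%")
print(f"share of selection due solely to pairwise epistasis: "
      f"{100 * summary.epistatic_share:.1f}%")
print("-> UE sits at 0.952 (=20/21) by construction; the gap below it is")
print("   replacement mutations rejected by the sequence constraints.")
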