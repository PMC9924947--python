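"""Generate a synthetic worm-panel cohort with planted ground truth.

Builds the default in-silico study (9 long-lived mutants + matched
wild-type controls, one lifespan assay + six stress assays, bulk RNA-seq
counts with planted gene modules) and prints its dimensions and the latent
per-strain traits that every downstream stage should recover.
"""

from stresslink import SimConfig, generate_cohort

config = SimConfig(seed=1, n_genes=1000, n_shared_driver=60,
                   n_lifespan_only=30, n_stress_specific=15)
survival, counts, metadata, gene_sets, truth = generate_cohort(config)

print(f"survival records : {len(survival)} "
      f"({survival['strain'].nunique()} strains x "
      f"{survival['assay'].nunique()} assays)")
print(f"count matrix     : {counts.shape[0]} genes x "
      f"{counts.shape[1]} samples")
print(f"planted modules  : "
      f"{ {name: len(s) for name, s in gene_sets.items()} }")
print("\nlatent traits (lifespan effect and bacterial stress trait):")
print(truth.strain_traits[["lifespan", "T_bacterial"]].round(3))
# The lifespan column is the configured fractional extension; T_bacterial
# mixes the shared robustness factor with a bacterial-specific factor.
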