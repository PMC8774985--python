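"""Generate a synthetic twin cohort and look at its structure.

The generator draws additive-genetic components with cross-twin correlation
1 (MZ) / 0.5 (DZ), a heritable dietary moderator, and a phenotypic liability
whose genetic and environmental paths depend linearly on each twin's own
moderator score.
"""

from acemod import generate_dataset, paper_like_config

dataset, manifest = generate_dataset(paper_like_config(seed=7))

print(f"pairs: {dataset.n_pairs}  individuals: {dataset.n_individuals}")
print(f"zygosity: {dataset.zygosity_counts()}")
print(dataset.df[["pair_id", "twin_order", "zygosity", "sex", "age",
                  "inattention_raw", "unhealthy_servings"]].head(4).to_string())
gen = manifest["config"]["params"]
print(f"\ngenerating paths: a={gen['a']:.3f} e={gen['e']:.3f} "
      f"beta_a={gen['beta_a']:.3f} beta_e={gen['beta_e']:.3f} "
      f"beta_m={gen['beta_m']:.2f}")
print("-> heritability rises from 0.30 to 0.51 across the moderator range;")
print("   the manifest records every generating value for later checks.")
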