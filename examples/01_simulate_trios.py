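"""Simulate an ascertained case-parent trio dataset.

Builds the default two-subpopulation (25%/75% admixed) haplotype pool —
12 gene regions with a handful of common sites and a rare-site spectrum
each — places causal effects (two common variants at +/-0.9, rare
effects 0.4 |log10 MAF|), and rejection-samples trios through an
affected child under the logistic disease model with intercept -2.2.
Writes a phased VCF, PED trio map, region map, and truth table.
"""

from trioemvs import CausalModel, PoolConfig, assign_effects, build_pool, simulate_dataset
from trioemvs.io import write_dataset

pool = build_pool(PoolConfig(), seed=0)
truth = assign_effects(pool, CausalModel(), seed=1)
dataset = simulate_dataset(pool, truth, n_families=350, seed=2)

paths = write_dataset(dataset, "scratch/example_dataset")
causal = truth.table[truth.table.causal]
print(f"pool: {pool.n_sites} sites in 12 regions; {len(causal)} causal variants")
print(causal[["variant_id", "region_id", "weighted_maf", "effect"]].to_string(index=False))
print(f"\n{len(dataset.trios)} trios written to: " + ", ".join(str(p) for p in paths.values()))
print(
    f"{int(dataset.polymorphic.sum())}/{pool.n_sites} sites are polymorphic in-sample "
    "(the rarest sites drop out at this sample size)"
)
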