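"""Generate a synthetic pseudo-haploid dataset with known ground truth.

Six weakly differentiated populations are simulated under the
Balding-Nichols model, single random alleles are sampled per site
(pseudo-haploid calls), heavy per-individual missingness is applied, and
one technical duplicate plus two mislabelled migrants are planted.
"""
import haplopop as hp

config = hp.SimConfig(
    n_snps=10_000,
    duplicate_pairs=1,
    migrants=[("P3", "P6", 2)],   # two P6-origin individuals captured at site P3
    seed=7,
)
dataset, truth = hp.build_dataset(config)

print(f"dataset: {dataset.n_individuals} individuals x {dataset.n_snps} SNPs")
print(f"groups: {dataset.groups}")
print(f"mean missingness: {1 - dataset.samples['n_calls'].mean() / dataset.n_snps:.2f}")
print(f"planted duplicate pair: {truth.duplicate_pairs[0]}")
print("planted migrants:")
print(truth.migrants(dataset.samples).to_string(index=False))

# The duplicate shares a diploid genome with its source individual; the
# migrants carry the P3 capture label but their genotypes were drawn from
# population P6 -- exactly the structure the analysis modules must recover.
hp.write_eigenstrat(dataset, "scratch/example_sim")
print("written to scratch/example_sim.{geno,snp,ind}")
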