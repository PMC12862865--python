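"""The whole chain on the six-population replica.

Simulates six weakly differentiated populations (sizes 8, 7, 26, 25, 22,
26) with four planted duplicate pairs and nine mislabelled migrants, then
runs: site filters -> PMR dedupe -> individual/count filters -> PCA ->
migrant screen (PC position + f4 confirmation) -> F_ST with permutations
-> f4 enumeration -> report.
"""
import haplopop as hp

config = hp.replica_config(seed=3, n_snps=20_000, n_perm=199,
                           outdir="scratch/pipeline_demo")
result = hp.run_pipeline(config)

print("stage survivor counts:")
for stage, n_ind, n_snp in result.stage_counts:
    print(f"  {stage}: {n_ind} individuals x {n_snp} SNPs")

print(f"\nduplicates dropped: {result.dropped}")

confirmed = result.migrants[result.migrants["confirmed"]]
truth = result.truth.migrants(result.dataset.samples)
print(f"migrants confirmed: {len(confirmed)} (planted: {len(truth)})")
print(confirmed[["sample_id", "capture_label", "nearest_group", "z"]]
      .to_string(index=False))

print("\nF_ST table (15 pairs + multi-group):")
print(result.fst.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
# Pairwise theta values land in the weak-differentiation range the
# generator was calibrated to (~0.03-0.09); permutation p-values at the
# floor 1/(n_perm+1) flag pairs whose differentiation no label shuffle
# reproduces.  The full report (PCA, f4 table, counts) is in
# scratch/pipeline_demo/report.txt.
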