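# Demo run: simulated closed breeding population with a planted recessive
# risk locus on chromosome 1 (SNP index 500 -> variant 1:10020000),
# 200 genotyped dogs x 10,000 SNPs. All thresholds at their study defaults.
seed: 11
n_genotyped: 200
outdir: results/demo
simulation:
  n_founders: 100
  n_generations: 6
  sire_fraction: 0.25
  mean_litter_size: 2.2
  n_chromosomes: 10
  snps_per_chromosome: 1000
  risk_locus: ["1", 500, 0.3]
  penetrance_aa: 0.6
  sporadic_rate: 0.005
  seed: 11
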