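# Demo cohort: 6 populations in 3 continental groups, 50 samples each,
# human-continental-scale drift (FST = 0.1), population-partitioned mtDNA
# haplogroup frequencies, ~2 private mtDNA mutations per lineage, and a 10%
# cross-continental maternal-lineage rate planting nuclear-mito mismatches.
simulate:
  pops: [AFR1, AFR2, EUR1, EUR2, EAS1, EAS2]
  group_of_pop:
    AFR1: Africa
    AFR2: Africa
    EUR1: Europe
    EUR2: Europe
    EAS1: EastAsia
    EAS2: EastAsia
  samples_per_pop: 50
  n_nuclear_sites: 1000
  fst: 0.1
  admix_dirichlet: {}
  mt_freqs:
    AFR1: {L0: 0.6, L1: 0.4}
    AFR2: {L2: 0.6, L3: 0.4}
    EUR1: {H: 0.6, U: 0.4}
    EUR2: {T: 0.6, K: 0.4}
    EAS1: {D: 0.6, F: 0.4}
    EAS2: {M: 0.6, G: 0.4}
  private_mut_rate: 2.0
  cross_mt_rate: 0.1
  panel_mode: full
  retained_sites: null
  seed: 0
mds_k: 2
z_threshold: 3.0
min_hg_distance: 4
permutations: 0
seed: 0
outdir: demo_out
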