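"""Allele-sharing distances and classical MDS projection.

Computes pairwise allele-sharing distances (mismatched alleles over alleles
compared) for nuclear and mtDNA matrices of a simulated cohort, embeds both
in two dimensions by classical (Torgerson) MDS, and reports how cleanly the
continental groups separate.
"""

import numpy as np

from mitonuc import (
    SimConfig,
    canonicalize_signs,
    classical_mds,
    load_default_haplogroup_tree,
    pairwise_distance_matrix,
    simulate_cohort,
)

cfg = SimConfig(
    pops=["AFR", "EUR", "EAS"],
    group_of_pop={"AFR": "Africa", "EUR": "Europe", "EAS": "EastAsia"},
    samples_per_pop=30,
    n_nuclear_sites=800,
    fst=0.1,
    mt_freqs={"AFR": {"L0": 1.0}, "EUR": {"H": 1.0}, "EAS": {"D": 1.0}},
    private_mut_rate=2.0,
    seed=2,
)
tree = load_default_haplogroup_tree()
Gn, Gm, truth, panel = simulate_cohort(cfg, tree)

for name, G in (("nuclear", Gn), ("mtDNA", Gm)):
    D = pairwise_distance_matrix(G)
    groups = np.array([panel.group_of[s] for s in D.labels])
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices(D.n, 1)
    within = D.values[iu][same[iu]].mean()
    between = D.values[iu][~same[iu]].mean()
    emb = classical_mds(D, k=2)
    emb.coords = canonicalize_signs(emb.coords)
    print(f"{name}: mean within-group distance {within:.4f}, between {between:.4f}")
    print(
        f"  MDS captures {emb.positive_mass_captured:.1%} of positive spectral mass"
        f" in 2 components; group centroids on C1:"
    )
    for g in sorted(set(groups)):
        c1 = emb.coords[groups == g, 0].mean()
        print(f"    {g:10s} {c1:+.4f}")
# Between-group distances exceed within-group ones for both genomes, and the
# first MDS component orders the continental groups — the co-divergence
# structure the concordance analysis quantifies.
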