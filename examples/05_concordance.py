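"""Nuclear-vs-mtDNA distance concordance: rho, rank differences, outliers.

Simulates one cohort without cross-continental maternal lineages and one
with 10% of them, and shows how the Spearman correlation between the two
distance-pair vectors drops while extreme rank-difference pairs appear.
"""

import copy

from mitonuc import (
    SimConfig,
    concordance,
    load_default_haplogroup_tree,
    pairwise_distance_matrix,
    simulate_cohort,
)

tree = load_default_haplogroup_tree()
base = SimConfig(
    pops=["AFR1", "AFR2", "EUR1", "EUR2", "EAS1", "EAS2"],
    group_of_pop={
        "AFR1": "Africa", "AFR2": "Africa",
        "EUR1": "Europe", "EUR2": "Europe",
        "EAS1": "EastAsia", "EAS2": "EastAsia",
    },
    samples_per_pop=50,
    n_nuclear_sites=1000,
    fst=0.1,
    mt_freqs={
        "AFR1": {"L0": 1.0}, "AFR2": {"L2": 1.0},
        "EUR1": {"H": 1.0}, "EUR2": {"T": 1.0},
        "EAS1": {"D": 1.0}, "EAS2": {"F": 1.0},
    },
    private_mut_rate=2.0,
    seed=5,
)

for cross in (0.0, 0.1):
    cfg = copy.deepcopy(base)
    cfg.cross_mt_rate = cross
    Gn, Gm, truth, panel = simulate_cohort(cfg, tree)
    conc = concordance(
        pairwise_distance_matrix(Gn), pairwise_distance_matrix(Gm), z_threshold=2.5
    )
    n_mism = int(truth.table["mismatch"].sum())
    mism = set(truth.table.loc[truth.table["mismatch"], "sample"])
    n_out_mism = sum(
        r.sample_i in mism or r.sample_j in mism for r in conc.outliers.itertuples()
    )
    print(
        f"cross_mt_rate={cross}: rho = {conc.rho:.3f} over {conc.n_pairs} pairs, "
        f"{len(conc.outliers)} outlier pairs (|z| > 2.5), "
        f"{n_out_mism} involving the {n_mism} mismatch-flagged samples"
    )
# Under pure co-divergence nuclear and mtDNA distances rank pairs similarly
# (rho ≈ 0.4 in this scaled-down cohort). Planting 10% foreign maternal
# lineages drags rho down and the flagged rank-difference outliers almost
# all involve the planted mismatch carriers.
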