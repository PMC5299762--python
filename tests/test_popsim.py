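import copy

import numpy as np
import pytest
from scipy.stats import binom

from mitonuc.popsim import (
    SimConfig,
    balding_nichols_frequencies,
    default_retained_sites,
    simulate_cohort,
    simulate_mtdna,
    simulate_nuclear,
    write_cohort,
)
from mitonuc.variant_io import read_panel, read_vcf


def _unadmixed(seed=0, **kw):
    base = dict(
        pops=["P1", "P2"],
        group_of_pop={"P1": "Africa", "P2": "Europe"},
        samples_per_pop=25,
        n_nuclear_sites=300,
        fst=0.1,
        mt_freqs={"P1": {"L0": 1.0}, "P2": {"H": 1.0}},
        seed=seed,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(fst=1.0),
            dict(samples_per_pop=0),
            dict(cross_mt_rate=1.5),
            dict(mt_freqs={"P1": {"L0": 0.7}, "P2": {"H": 1.0}}),  # not summing to 1
            dict(panel_mode="sparse"),
            dict(admix_dirichlet={"P1": [1.0]}),  # wrong length
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _unadmixed(**kw)


class TestNuclear:
    def test_balding_nichols_moments(self):
        """Var(p_pop) ≈ F p (1-p): the closed-form Beta variance."""
        rng = np.random.default_rng(0)
        p = np.full(100_000, 0.3)
        F = 0.1
        draws = balding_nichols_frequencies(p, F, rng)
        assert draws.mean() == pytest.approx(0.3, abs=0.005)
        assert draws.var() == pytest.approx(F * 0.3 * 0.7, rel=0.03)

    def test_fst_zero_bypasses_beta(self):
        rng = np.random.default_rng(0)
        p = np.linspace(0.1, 0.9, 50)
        np.testing.assert_array_equal(balding_nichols_frequencies(p, 0.0, rng), p)

    def test_fst_zero_populations_share_frequencies(self):
        cfg = _unadmixed(fst=0.0, samples_per_pop=100, n_nuclear_sites=400)
        G, _ = simulate_nuclear(cfg)
        f1 = G.dosage[:100].mean(axis=0) / 2
        f2 = G.dosage[100:].mean(axis=0) / 2
        # both estimate the same p per site: mean difference ~ 0, spread binomial
        assert abs((f1 - f2).mean()) < 0.01
        se2 = (f1 * (1 - f1) + f2 * (1 - f2)).mean() / 200
        assert (f1 - f2).var() == pytest.approx(se2, rel=0.35)

    def test_degenerate_dirichlet_gives_pure_ancestry(self):
        cfg = _unadmixed(
            pops=["P1", "P2", "P3"],
            group_of_pop={"P1": "Africa", "P2": "Europe", "P3": "Europe"},
            mt_freqs={
                "P1": {"L0": 1.0},
                "P2": {"H": 1.0},
                "P3": {"U": 1.0},
            },
            admix_dirichlet={"P3": [1.0, 0.0, 0.0]},
        )
        _, truth = simulate_nuclear(cfg)
        t3 = truth.table[truth.table["pop"] == "P3"]
        np.testing.assert_array_equal(t3["ancestry_P1"], 1.0)
        np.testing.assert_array_equal(t3[["ancestry_P2", "ancestry_P3"]], 0.0)

    def test_ancestry_rows_sum_to_one(self):
        cfg = _unadmixed(
            pops=["P1", "P2", "P3"],
            group_of_pop={"P1": "Africa", "P2": "Europe", "P3": "America"},
            mt_freqs={"P1": {"L0": 1.0}, "P2": {"H": 1.0}, "P3": {"A": 1.0}},
            admix_dirichlet={"P3": [2.0, 5.0, 1.0]},
        )
        _, truth = simulate_nuclear(cfg)
        anc = truth.table[truth.ancestry_columns()].to_numpy()
        np.testing.assert_allclose(anc.sum(axis=1), 1.0, atol=1e-9)


class TestMtdna:
    def test_no_crossing_no_admixture_all_matched(self, hg_tree):
        _, truth = simulate_mtdna(_unadmixed(), hg_tree)
        assert not truth.table["mismatch"].any()

    def test_haplotype_is_exact_path_union(self, hg_tree):
        cfg = _unadmixed(private_mut_rate=0.0)
        G, truth = simulate_mtdna(cfg, hg_tree)
        pos_of = {j: s.pos for j, s in enumerate(G.sites)}
        for i, hg in enumerate(truth.table["haplogroup"]):
            carried = {pos_of[j] for j in np.nonzero(G.dosage[i] == 1)[0]}
            expected = {p for p, _ in hg_tree.cumulative_variants(hg)}
            assert carried == expected

    def test_planted_mismatch_count_in_binomial_interval(self, hg_tree):
        cfg = _unadmixed(samples_per_pop=250, cross_mt_rate=0.1, seed=5)
        _, truth = simulate_mtdna(cfg, hg_tree)
        lo, hi = binom.interval(0.99, 500, 0.1)
        assert lo <= truth.table["mismatch"].sum() <= hi

    def test_mismatch_flag_recomputable(self, hg_tree, demo_sim_config):
        cfg = copy.deepcopy(demo_sim_config)
        cfg.cross_mt_rate = 0.15
        cfg.samples_per_pop = 20
        Gn, Gm, truth, panel = simulate_cohort(cfg, hg_tree)
        recomputed = truth.table["maternal_origin_group"] != truth.majority_group(
            cfg.group_of_pop
        )
        np.testing.assert_array_equal(truth.table["mismatch"], recomputed)

    def test_composition_matches_frequencies(self, hg_tree):
        cfg = _unadmixed(
            samples_per_pop=300,
            mt_freqs={"P1": {"L0": 0.7, "L1": 0.3}, "P2": {"H": 0.5, "U": 0.5}},
            seed=9,
        )
        _, truth = simulate_mtdna(cfg, hg_tree)
        t = truth.table
        for pop, freqs in cfg.mt_freqs.items():
            sub = t[t["pop"] == pop]["haplogroup"].value_counts(normalize=True)
            for hg, f in freqs.items():
                se = np.sqrt(f * (1 - f) / 300)
                assert abs(sub.get(hg, 0.0) - f) < 4 * se

    def test_unknown_haplogroup_label_rejected(self, hg_tree):
        cfg = _unadmixed(mt_freqs={"P1": {"ZZ9": 1.0}, "P2": {"H": 1.0}})
        with pytest.raises(KeyError, match="ZZ9"):
            simulate_mtdna(cfg, hg_tree)

    def test_reduced_panel_masks_to_retained_sites(self, hg_tree):
        retained = default_retained_sites(hg_tree)
        cfg = _unadmixed(panel_mode="reduced", private_mut_rate=2.0)
        G, _ = simulate_mtdna(cfg, hg_tree)
        assert [s.pos for s in G.sites] == sorted(
            p for p in retained if p in {s.pos for s in G.sites}
        )
        assert {s.pos for s in G.sites} <= set(retained)
        cfg2 = _unadmixed(panel_mode="reduced", retained_sites=retained[:5])
        G2, _ = simulate_mtdna(cfg2, hg_tree)
        assert {s.pos for s in G2.sites} <= set(retained[:5])


class TestDeterminismAndIo:
    def test_bit_identical_outputs_for_same_seed(self, hg_tree):
        cfg = _unadmixed(private_mut_rate=1.0, cross_mt_rate=0.1)
        a = simulate_cohort(cfg, hg_tree)
        b = simulate_cohort(cfg, hg_tree)
        np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
        np.testing.assert_array_equal(a[1].dosage, b[1].dosage)
        assert a[2].table.equals(b[2].table)

    def test_write_cohort_round_trips(self, tmp_path, hg_tree):
        cfg = _unadmixed(private_mut_rate=1.0)
        Gn, Gm, truth, panel = simulate_cohort(cfg, hg_tree)
        paths = write_cohort(Gn, Gm, truth, panel, tmp_path, cfg)
        Gn2 = read_vcf(paths["nuclear_vcf"], ploidy=2)
        Gm2 = read_vcf(paths["mtdna_vcf"], ploidy=1)
        np.testing.assert_array_equal(Gn2.dosage, Gn.dosage)
        np.testing.assert_array_equal(Gm2.dosage, Gm.dosage)
        assert read_panel(paths["panel"]).pop_of == panel.pop_of
        assert sum(1 for _ in open(paths["truth"])) == Gn.n_samples + 1
        cfg2 = SimConfig.from_yaml(paths["config"])
        assert cfg2 == cfg

    def test_inconsistent_labels_rejected(self, tmp_path, hg_tree):
        cfg = _unadmixed()
        Gn, Gm, truth, panel = simulate_cohort(cfg, hg_tree)
        other = simulate_cohort(_unadmixed(samples_per_pop=5), hg_tree)
        with pytest.raises(ValueError, match="different samples|do not match"):
            write_cohort(Gn, other[1], truth, panel, tmp_path)
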