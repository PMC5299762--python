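import numpy as np
import pandas as pd
import pytest

from mitonuc.gendist import DistanceMatrix
from mitonuc.haplocall import HaplotypeCall
from mitonuc.njtree import neighbor_joining
from mitonuc.pipeline import calls_from_matrix
from mitonuc.survey import (
    CountMatrix,
    classify_matches,
    cluster_counts,
    discordant_sisters,
    haplogroup_counts,
)
from mitonuc.variant_io import PopulationPanel


def _call(sample, hg):
    return HaplotypeCall(sample=sample, haplogroup=hg, score=1.0)


def _panel(assignments):
    return PopulationPanel(
        pop_of={s: p for s, (p, _) in assignments.items()},
        group_of={s: g for s, (_, g) in assignments.items()},
    )


class TestCounts:
    def test_single_sample(self):
        panel = _panel({"S1": ("CEU", "Europe")})
        M = haplogroup_counts([_call("S1", "H")], panel)
        assert M.table.shape == (1, 1) and M.table.loc["CEU", "H"] == 1

    def test_count_conservation(self, small_cohort, hg_tree):
        Gn, Gm, truth, panel = small_cohort
        calls = calls_from_matrix(Gm, hg_tree)
        M = haplogroup_counts(calls, panel)
        assert M.table.to_numpy().sum() == len(calls)
        assert (M.table.sum(axis=1) == panel.population_sizes()).all()

    def test_composition_tracks_generator_frequencies(self, small_cohort, small_config):
        _, Gm, truth, panel = small_cohort
        M = haplogroup_counts(
            [_call(s, h) for s, h in zip(truth.table["sample"], truth.table["haplogroup"])],
            panel,
        )
        prop = M.proportions()
        for pop, freqs in small_config.mt_freqs.items():
            for hg, f in freqs.items():
                se = np.sqrt(f * (1 - f) / small_config.samples_per_pop)
                assert abs(prop.loc[pop].get(hg, 0.0) - f) <= 4 * se + 1e-9

    def test_sample_missing_from_panel(self):
        panel = _panel({"S1": ("CEU", "Europe")})
        with pytest.raises(KeyError, match="S2"):
            haplogroup_counts([_call("S2", "H")], panel)


class TestCluster:
    def _cm(self, rows, index, cols, groups=None):
        table = pd.DataFrame(rows, index=index, columns=cols)
        return CountMatrix(table, groups or {p: "G" for p in index})

    def test_identical_rows_merge_first_and_sit_adjacent(self):
        M = self._cm(
            [[10, 0, 0], [10, 0, 0], [0, 5, 5], [1, 1, 8]],
            ["A", "B", "C", "D"],
            ["h1", "h2", "h3"],
        )
        res = cluster_counts(M)
        Z = res["row_linkage"]
        assert set(Z[0, :2].astype(int)) == {0, 1} and Z[0, 2] == 0.0
        order = res["row_order"]
        assert abs(order.index("A") - order.index("B")) == 1

    def test_proportions_not_raw_counts_drive_clustering(self):
        # D is A's profile scaled 10x: proportion-identical, merged at distance 0
        M = self._cm(
            [[10, 0], [0, 10], [5, 5], [100, 0]],
            ["A", "B", "C", "D"],
            ["h1", "h2"],
        )
        Z = cluster_counts(M)["row_linkage"]
        assert set(Z[0, :2].astype(int)) == {0, 3} and Z[0, 2] == 0.0

    def test_two_planted_pairs_merge_first(self):
        M = self._cm(
            [[9, 1, 0, 0], [8, 2, 0, 0], [0, 0, 1, 9], [0, 0, 2, 8]],
            ["A1", "A2", "B1", "B2"],
            list("wxyz"),
        )
        Z = cluster_counts(M)["row_linkage"]
        first_two = [set(Z[0, :2].astype(int)), set(Z[1, :2].astype(int))]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_single_row_warns_identity(self):
        M = self._cm([[1, 2]], ["A"], ["h1", "h2"])
        with pytest.warns(UserWarning, match="single-row"):
            res = cluster_counts(M)
        assert res["row_order"] == ["A"]


class TestClassify:
    def _counts(self, cells, groups):
        pops = sorted({p for p, _ in cells})
        hgs = sorted({h for _, h in cells})
        table = pd.DataFrame(0, index=pops, columns=hgs)
        for (p, h), c in cells.items():
            table.loc[p, h] = c
        return CountMatrix(table, groups)

    def test_continental_anchor_cells(self, hg_tree):
        M = self._counts(
            {("CEU", "H"): 5, ("IBS", "L2"): 1, ("YRI", "L0"): 9},
            {"CEU": "Europe", "IBS": "Europe", "YRI": "Africa"},
        )
        mt = classify_matches(M, hg_tree)
        cells = mt.cells.set_index(["pop", "haplogroup"])["status"]
        assert cells[("CEU", "H")] == "matched"
        assert cells[("IBS", "L2")] == "mismatched"
        assert cells[("YRI", "L0")] == "matched"

    def test_admixed_group_sources_count_as_matched(self, hg_tree):
        M = self._counts(
            {("PUR", "H"): 3, ("PUR", "A"): 4, ("PUR", "D"): 1},
            {"PUR": "America"},
        )
        mt = classify_matches(
            M, hg_tree, admixed_sources={"America": {"Europe", "Africa", "NativeAmerica"}}
        )
        cells = mt.cells.set_index("haplogroup")["status"]
        assert cells["H"] == "matched" and cells["A"] == "matched"
        assert cells["D"] == "mismatched"  # East Asia not a declared source

    def test_undeclared_group_outside_origin_universe(self, hg_tree):
        M = self._counts({("GIH", "H"): 1}, {"GIH": "India"})
        with pytest.raises(ValueError, match="India"):
            classify_matches(M, hg_tree)

    def test_per_sample_records_match_truth_flags(self, small_cohort, hg_tree):
        Gn, Gm, truth, panel = small_cohort
        calls = calls_from_matrix(Gm, hg_tree)
        M = haplogroup_counts(calls, panel)
        mt = classify_matches(M, hg_tree, calls=calls, panel=panel)
        rec = mt.per_sample.set_index("sample")["status"] == "mismatched"
        planted = truth.table.set_index("sample")["mismatch"]
        assert rec.reindex(planted.index).equals(planted)

    def test_idempotent_and_order_free(self, hg_tree):
        M = self._counts(
            {("CEU", "H"): 5, ("YRI", "L0"): 9},
            {"CEU": "Europe", "YRI": "Africa"},
        )
        a = classify_matches(M, hg_tree).cells
        M2 = CountMatrix(
            M.table.iloc[::-1, ::-1], dict(M.group_of_pop)
        )
        b = classify_matches(M2, hg_tree).cells
        key = ["pop", "haplogroup"]
        assert a.set_index(key)["status"].sort_index().equals(
            b.set_index(key)["status"].sort_index()
        )


class TestDiscordantSisters:
    def _tree(self):
        # two clean cherries: (s1,s2) and (s3,s4)
        d = np.array(
            [
                [0.00, 0.02, 0.50, 0.52],
                [0.02, 0.00, 0.52, 0.50],
                [0.50, 0.52, 0.00, 0.02],
                [0.52, 0.50, 0.02, 0.00],
            ]
        )
        labels = ["s1", "s2", "s3", "s4"]
        return neighbor_joining(
            DistanceMatrix(labels, d, np.ones((4, 4)))
        )

    def test_divergent_cherry_reported(self, hg_tree):
        calls = [_call("s1", "L1"), _call("s2", "H"), _call("s3", "H"), _call("s4", "H")]
        out = discordant_sisters(self._tree(), calls, hg_tree, min_hg_distance=4)
        assert len(out) == 1
        row = out.iloc[0]
        assert {row["sample_i"], row["sample_j"]} == {"s1", "s2"}
        assert row["hg_distance"] == 8

    def test_uniform_haplogroups_empty(self, hg_tree):
        calls = [_call(s, "H") for s in ("s1", "s2", "s3", "s4")]
        assert discordant_sisters(self._tree(), calls, hg_tree).empty

    def test_zero_threshold_reports_every_cherry(self, hg_tree):
        calls = [_call(s, "H") for s in ("s1", "s2", "s3", "s4")]
        out = discordant_sisters(self._tree(), calls, hg_tree, min_hg_distance=0)
        assert len(out) == 2

    def test_uncalled_leaf_rejected(self, hg_tree):
        calls = [_call(s, "H") for s in ("s1", "s2", "s3")]
        with pytest.raises(KeyError, match="s4"):
            discordant_sisters(self._tree(), calls, hg_tree)
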