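import math

import numpy as np
import pandas as pd
import pytest

from mitonuc.gendist import DistanceMatrix
from mitonuc.njtree import PhyloTree, neighbor_joining
from mitonuc.variant_io import (
    GenotypeMatrix,
    Site,
    load_kgp_population_sizes,
    read_haplogroup_table,
    read_panel,
    read_vcf,
    write_newick,
    write_vcf,
)

VCF_BODY = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0|1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t1|1
"""


def _matrix(ploidy=2, dosage=None, missing=False):
    dosage = np.array(dosage if dosage is not None else [[0, 1, 2], [2, 0, 1]], float)
    if missing:
        dosage[0, 1] = np.nan
    sites = [Site("1", 10 * (j + 1), "A", "G") for j in range(dosage.shape[1])]
    return GenotypeMatrix(["A", "B"], sites, dosage, ploidy)


class TestReadVcf:
    def test_diploid_dosages_and_missing(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(VCF_BODY)
        G = read_vcf(p, ploidy=2)
        assert G.samples == ["A", "B"]
        # phased and unphased GT treated identically as dosage
        np.testing.assert_array_equal(G.dosage[:, [0, 2]], [[0, 2], [1, 2]])
        assert G.dosage[0, 1] == 1 and math.isnan(G.dosage[1, 1])

    def test_multiallelic_rejected_naming_site(self, tmp_path):
        body = VCF_BODY.replace("1\t200\t.\tC\tT", "1\t200\t.\tC\tT,G")
        p = tmp_path / "m.vcf"
        p.write_text(body)
        with pytest.raises(ValueError, match="1:200"):
            read_vcf(p, ploidy=2)

    def test_ploidy_mismatch_rejected(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(VCF_BODY)
        with pytest.raises(ValueError, match="ploidy"):
            read_vcf(p, ploidy=1)

    @pytest.mark.parametrize("ploidy,missing", [(2, False), (2, True), (1, False), (1, True)])
    def test_round_trip_identity(self, tmp_path, ploidy, missing):
        dos = [[0, 1, 2], [2, 0, 1]] if ploidy == 2 else [[0, 1, 1], [1, 0, 0]]
        G = _matrix(ploidy=ploidy, dosage=dos, missing=missing)
        p = tmp_path / "rt.vcf"
        write_vcf(G, p)
        G2 = read_vcf(p, ploidy=ploidy)
        assert G2.samples == G.samples
        assert G2.sites == G.sites
        np.testing.assert_array_equal(G2.dosage, G.dosage)

    def test_write_deterministic_bytes(self, tmp_path):
        G = _matrix()
        write_vcf(G, tmp_path / "a.vcf")
        write_vcf(G, tmp_path / "b.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_empty_sample_matrix_header_only_body(self, tmp_path):
        G = GenotypeMatrix([], [Site("1", 5, "A", "G")], np.empty((0, 1)), 2)
        p = tmp_path / "e.vcf"
        write_vcf(G, p)
        data_lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert data_lines == ["1\t5\t.\tA\tG\t.\tPASS\t.\tGT"]


class TestGenotypeMatrixInvariants:
    def test_positions_must_increase(self):
        sites = [Site("1", 20, "A", "G"), Site("1", 10, "A", "G")]
        with pytest.raises(ValueError, match="increasing"):
            GenotypeMatrix(["A"], sites, np.zeros((1, 2)), 2)

    def test_dosage_range_enforced(self):
        with pytest.raises(ValueError, match="dosages"):
            _matrix(ploidy=1, dosage=[[0, 2, 1], [0, 0, 0]])


class TestPanel:
    def test_single_line(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("sample pop group\nS1 YRI Africa\n")
        panel = read_panel(p)
        assert panel.pop_of == {"S1": "YRI"} and panel.group_of == {"S1": "Africa"}

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("sample pop group\nS1 YRI Africa\nS1 CEU Europe\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(p)

    def test_kgp_sized_panel_group_totals(self, tmp_path):
        """A panel with 1KGP population sizes gives the known group totals."""
        df = load_kgp_population_sizes()
        rows = ["sample pop group"]
        for r in df.itertuples():
            rows += [f"{r.pop}_{i} {r.pop} {r.group}" for i in range(r.n)]
        p = tmp_path / "kgp_panel.tsv"
        p.write_text("\n".join(rows) + "\n")
        panel = read_panel(p)
        by_group = pd.Series(panel.group_of).value_counts()
        assert by_group["Africa"] == 504
        assert by_group.sum() == 2504
        assert len(panel.population_sizes()) == 26


class TestHaplogroupTable:
    def test_bundled_fixture_macro_split(self, hg_tree):
        # ancient L clades sit apart from the L3-derived M/N/R lineages
        for anc in ("L0", "L1", "L5"):
            assert hg_tree.parent[anc] == "reference"
        assert hg_tree.parent["L3"] == "L3'4" and hg_tree.parent["L4"] == "L3'4"
        for derived in ("M", "N"):
            assert hg_tree.parent[derived] == "L3"

    def test_order_independent(self, tmp_path, hg_tree):
        from importlib import resources

        ref = resources.files("mitonuc.data").joinpath("haplogroup_tree.tsv")
        with resources.as_file(ref) as fp:
            src = pd.read_csv(fp, sep="\t", keep_default_na=False)
        shuffled = src.sample(frac=1, random_state=3)
        p = tmp_path / "shuf.tsv"
        shuffled.to_csv(p, sep="\t", index=False)
        t2 = read_haplogroup_table(p)
        assert t2.parent == hg_tree.parent
        assert t2.edge_variants == hg_tree.edge_variants

    def test_two_node_tree(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "parent\tchild\tvariants\torigin\tmacro\n"
            "-\troot\t\tEurope\tH\n"
            "root\tH\t100:T\tEurope\tH\n"
        )
        t = read_haplogroup_table(p)
        assert t.cumulative_variants("H") == frozenset({(100, "T")})

    @pytest.mark.parametrize(
        "rows,err",
        [
            ("-\tr\t\tE\tH\nr\ta\t1:T\tE\tH\nr\ta\t2:T\tE\tH\n", "duplicate"),
            ("-\tr\t\tE\tH\nx\ta\t1:T\tE\tH\n", "orphan"),
            ("a\tb\t1:T\tE\tH\nb\ta\t2:T\tE\tH\n", "root"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, rows, err):
        p = tmp_path / "bad.tsv"
        p.write_text("parent\tchild\tvariants\torigin\tmacro\n" + rows)
        with pytest.raises(ValueError, match=err):
            read_haplogroup_table(p)


class TestNewick:
    def test_three_taxon_closed_form(self, tmp_path):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]]) / 10.0,
            np.full((3, 3), 10),
        )
        tree = neighbor_joining(D)
        # vA=(dAB+dAC-dBC)/2 etc., on the /10 scale
        assert write_newick(tree) == "(A:0.2,B:0.3,C:0.7);"

    def test_single_leaf(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node(0)
        t = PhyloTree(graph=g, leaf_labels={0: "A"})
        assert write_newick(t) == "A:0;"

    def test_unlabeled_leaf_rejected(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge(0, 1, length=1.0)
        g.add_edge(0, 2, length=1.0)
        with pytest.raises(ValueError, match="unlabeled|no label"):
            PhyloTree(graph=g, leaf_labels={1: "A"})

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(5)
        n = 7
        pts = rng.random((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = d / (d.max() * 1.01)
        np.fill_diagonal(d, 0.0)
        labels = [f"s{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(labels, (d + d.T) / 2, np.ones((n, n))))
        t2 = PhyloTree.from_newick(write_newick(tree))
        assert t2.leaf_set() == tree.leaf_set()
        for i in range(n):
            for j in range(i + 1, n):
                assert tree.path_length(labels[i], labels[j]) == pytest.approx(
                    t2.path_length(labels[i], labels[j]), abs=1e-9
                )
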