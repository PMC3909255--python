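"""Network data model, the TSV dialect, merging, degree filtering and export."""

import numpy as np
import pytest

import lncnet as ln
from _helpers import net_from_edges, random_network

TOY_TABLE = (
    "gene_id\tgene_type\tdisease_id\n"
    "g1\tlncRNA\td1\n"
    "g2\tcoding\td1\n"
    "g1\tlncRNA\td2\n"
)


def write(tmp_path, text, name="assoc.tsv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestLoad:
    def test_three_row_table(self, tmp_path):
        net = ln.load_associations(write(tmp_path, TOY_TABLE))
        assert net.n_genes == 2 and net.n_diseases == 2 and net.n_edges == 3
        assert net.gene("g1").gene_type == "lncRNA"
        assert net.parse_report.rows_read == 3
        assert net.parse_report.duplicates_dropped == 0

    def test_duplicate_edge_dropped_and_counted(self, tmp_path):
        table = "gene_id\tgene_type\tdisease_id\ng1\tlncRNA\td1\ng1\tlncRNA\td1\n"
        net = ln.load_associations(write(tmp_path, table))
        assert net.n_edges == 1
        assert net.parse_report.duplicates_dropped == 1

    def test_unknown_gene_type_names_line(self, tmp_path):
        table = (
            "# curated associations\n"
            "gene_id\tgene_type\tdisease_id\n"
            "g1\tlncRNA\td1\n"
            "g2\tmRNA\td1\n"
        )
        with pytest.raises(ln.NetworkValidationError, match="line 4"):
            ln.load_associations(write(tmp_path, table))

    def test_missing_required_column(self, tmp_path):
        with pytest.raises(ln.NetworkFormatError, match="gene_type"):
            ln.load_associations(write(tmp_path, "gene_id\tdisease_id\ng1\td1\n"))

    def test_metadata_and_comments(self, tmp_path):
        table = (
            "gene_id\tgene_type\tdisease_id\tdisease_class\tmim\n"
            "# a comment between rows\n"
            "g1\tlncRNA\td1\tCancer\t114480\n"
        )
        net = ln.load_associations(write(tmp_path, table))
        d = net.disease("d1")
        assert d.disease_class == "Cancer" and d.mim == "114480"


class TestModelInvariants:
    def test_degree_sums_equal_edge_count(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_network(rng)
            assert sum(net.gene_degrees.values()) == net.n_edges
            assert sum(net.disease_degrees.values()) == net.n_edges

    def test_shared_id_namespace_rejected(self):
        with pytest.raises(ln.NetworkValidationError, match="both sides"):
            ln.BipartiteAssociationNetwork(
                [ln.GeneNode("x", "coding")], [ln.DiseaseNode("x")], []
            )

    def test_edge_requires_registered_endpoints(self):
        with pytest.raises(ln.NetworkValidationError):
            ln.BipartiteAssociationNetwork(
                [ln.GeneNode("g1", "coding")], [ln.DiseaseNode("d1")], [("g1", "d9")]
            )


class TestMerge:
    def test_disjoint_union(self):
        a = net_from_edges({("g1", "d1"), ("g2", "d1")})
        b = net_from_edges({("g3", "d2")})
        merged = ln.merge_networks(a, b)
        assert merged.n_genes == 3 and merged.n_diseases == 2 and merged.n_edges == 3

    def test_shared_edge_counted_once(self):
        a = net_from_edges({("g1", "d1"), ("g2", "d1")})
        b = net_from_edges({("g1", "d1")})
        assert ln.merge_networks(a, b).n_edges == 2

    def test_conflicting_gene_type_raises(self):
        a = net_from_edges({("g1", "d1")}, gene_types={"g1": "lncRNA"})
        b = net_from_edges({("g1", "d2")}, gene_types={"g1": "coding"})
        with pytest.raises(ln.MergeConflictError):
            ln.merge_networks(a, b)

    def test_full_scale_integration(self, full_scale_paired_fixture):
        """578 lncRNA + 980 coding associations merge into the 1558-edge
        integrated network over 1096 genes and a shared 214-disease set."""
        lnc_only, integrated, _ = full_scale_paired_fixture
        assert lnc_only.n_edges == 578
        coding_edges = set(integrated.edges) - set(lnc_only.edges)
        coding = ln.BipartiteAssociationNetwork(
            integrated.genes_of_type("coding"), integrated.diseases, coding_edges
        )
        assert coding.n_edges == 980
        merged = ln.merge_networks(lnc_only, coding)
        assert merged.n_genes == 1096
        assert merged.n_diseases == 214
        assert merged.n_edges == 1558


class TestFilterMinDegree:
    def test_single_pass_on_input_degrees(self):
        net = net_from_edges({("g1", "d1"), ("g1", "d2"), ("g2", "d1")})
        filtered = ln.filter_min_degree(net, 2)
        # g1 and d1 have degree 2 in the INPUT, so only their edge survives,
        # even though both end at degree 1 in the output (single pass).
        assert set(filtered.edges) == {("g1", "d1")}
        assert set(filtered.gene_ids) == {"g1"} and set(filtered.disease_ids) == {"d1"}
        assert ln.filter_min_degree(filtered, 2).n_edges == 0
        assert ln.filter_min_degree(net, 2, iterative=True).n_edges == 0

    def test_complete_bipartite_unchanged(self):
        net = net_from_edges({(g, d) for g in ("g1", "g2") for d in ("d1", "d2")})
        assert ln.filter_min_degree(net, 2) == net

    def test_single_edge_filters_to_empty(self):
        filtered = ln.filter_min_degree(net_from_edges({("g1", "d1")}), 2)
        assert filtered.n_edges == 0 and filtered.n_genes == 0

    def test_min_degree_below_one_rejected(self):
        with pytest.raises(ValueError):
            ln.filter_min_degree(net_from_edges({("g1", "d1")}), 0)


class TestExport:
    @pytest.fixture
    def decorated_net(self):
        return ln.BipartiteAssociationNetwork(
            [
                ln.GeneNode("g1", "lncRNA", label="H19"),
                ln.GeneNode("g2", "coding"),
                ln.GeneNode("g3", "coding"),  # isolated
            ],
            [
                ln.DiseaseNode("d1", name="breast cancer", mim="114480", disease_class="Cancer"),
                ln.DiseaseNode("d2"),
                ln.DiseaseNode("d3"),  # isolated
            ],
            {("g1", "d1"), ("g2", "d1"), ("g1", "d2")},
        )

    @pytest.mark.parametrize("fmt", ["graphml", "edgelist"])
    def test_round_trip_identity(self, decorated_net, tmp_path, fmt):
        path = tmp_path / f"net.{fmt}"
        ln.export_graph(decorated_net, path, format=fmt)
        back = (
            ln.read_graphml(path) if fmt == "graphml" else ln.load_associations(path)
        )
        assert back == decorated_net

    def test_edgelist_row_count(self, tmp_path):
        net = net_from_edges({("g1", "d1"), ("g2", "d1"), ("g1", "d2")})
        path = tmp_path / "net.tsv"
        ln.export_graph(net, path, format="edgelist")
        rows = [l for l in path.read_text().splitlines() if l and not l.startswith("#")]
        assert len(rows) == 1 + 3  # header + one row per edge

    def test_empty_network_valid_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        ln.export_graph(ln.BipartiteAssociationNetwork(), path, format="edgelist")
        assert ln.load_associations(path).n_edges == 0

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            ln.export_graph(ln.BipartiteAssociationNetwork(), tmp_path / "x", format="gml")
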