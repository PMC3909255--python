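"""The planted-structure fixture generator."""

import numpy as np
import pytest

import lncnet as ln
from lncnet.projection import _weights_from_adjacency
from lncnet.propagation import _propagate_arrays


class TestDeterminism:
    def test_same_seed_same_network(self):
        a_net, a_truth = ln.generate_network(ln.GeneratorConfig(seed=5))
        b_net, b_truth = ln.generate_network(ln.GeneratorConfig(seed=5))
        assert a_net == b_net
        assert a_truth == b_truth

    def test_different_seeds_differ(self):
        a_net, _ = ln.generate_network(ln.GeneratorConfig(seed=1))
        b_net, _ = ln.generate_network(ln.GeneratorConfig(seed=2))
        assert a_net != b_net


class TestScales:
    def test_small_default_counts(self, small_fixture):
        net, _ = small_fixture
        assert net.n_genes == 250 and net.n_diseases == 60 and net.n_edges == 500

    def test_full_scale_counts(self, full_scale_paired_fixture):
        lnc_only, integrated, _ = full_scale_paired_fixture
        assert integrated.n_genes == 1096  # 295 lncRNAs + 801 coding genes
        assert len(integrated.genes_of_type("lncRNA")) == 295
        assert len(integrated.genes_of_type("coding")) == 801
        assert integrated.n_diseases == 214
        assert integrated.n_edges == 1558
        assert lnc_only.n_edges == 578

    def test_every_disease_reachable(self, small_fixture):
        net, _ = small_fixture
        assert min(net.disease_degrees.values()) >= 1

    def test_heavy_tailed_degrees(self, full_scale_paired_fixture):
        _, integrated, _ = full_scale_paired_fixture
        degrees = np.array(
            list(integrated.gene_degrees.values())
            + list(integrated.disease_degrees.values())
        )
        assert degrees.max() >= 5 * np.median(degrees)


class TestTruth:
    def test_hidden_pairs_absent_but_class_consistent(self, small_fixture):
        net, truth = small_fixture
        assert len(truth.hidden) > 0
        for g, d in truth.hidden:
            assert not net.has_edge(g, d)
            assert truth.gene_class[g] == truth.disease_class[d]

    def test_class_maps_cover_all_nodes(self, small_fixture):
        net, truth = small_fixture
        assert set(truth.disease_class) == set(net.disease_ids)
        assert set(truth.gene_class) == set(net.gene_ids)
        assert net.disease_class_map() == truth.disease_class

    def test_hidden_pairs_rank_better_than_random_pairs(self, small_fixture):
        """Planted-signal recovery: hidden class-consistent associations
        score better than random unassociated pairs."""
        net, truth = small_fixture
        A, genes, diseases = net.adjacency()
        W = _weights_from_adjacency(A)
        g_idx = {g: i for i, g in enumerate(genes)}
        d_idx = {d: j for j, d in enumerate(diseases)}
        cfg = ln.PropagationConfig()

        def rank_of(g, d):
            j = d_idx[d]
            F, *_ = _propagate_arrays(W, A[:, j], cfg)
            cand = np.flatnonzero(A[:, j] == 0)
            order = cand[np.argsort(-F[cand], kind="stable")]
            return 1 + int(np.flatnonzero(order == g_idx[g])[0])

        hidden_ranks = [rank_of(g, d) for g, d in truth.hidden]
        rng = np.random.default_rng(99)
        random_ranks = []
        while len(random_ranks) < len(hidden_ranks):
            g = genes[rng.integers(len(genes))]
            d = diseases[rng.integers(len(diseases))]
            if not net.has_edge(g, d) and (g, d) not in truth.hidden:
                random_ranks.append(rank_of(g, d))
        assert np.median(hidden_ranks) < np.median(random_ranks)


class TestNoSignalControl:
    def test_bias_one_removes_class_enrichment(self):
        """With within_class_bias=1 the same-class link count of the disease
        projection is statistically indistinguishable from shuffles."""
        zs = []
        for seed in range(6):
            net, _ = ln.generate_network(
                ln.GeneratorConfig(seed=seed, within_class_bias=1.0)
            )
            classes = net.disease_class_map()
            proj = ln.one_mode_projection(net, "disease")
            observed = ln.same_class_link_count(proj, classes)
            null = [
                ln.same_class_link_count(
                    ln.one_mode_projection(
                        ln.degree_preserving_shuffle(
                            net, ln.ShuffleConfig(seed=3000 + 50 * seed + i)
                        ),
                        "disease",
                    ),
                    classes,
                )
                for i in range(20)
            ]
            zs.append(ln.ensemble_ztest(observed, null).z)
        assert sum(abs(z) < 2 for z in zs) >= 4
        assert np.mean(np.abs(zs)) < 2


class TestPairedFixture:
    def test_restriction_identity(self, paired_fixture):
        """Integrated minus the coding-gene edges equals the lncRNA-only net."""
        lnc_only, integrated, _ = paired_fixture
        lnc_ids = {g.id for g in integrated.genes_of_type("lncRNA")}
        restricted = ln.BipartiteAssociationNetwork(
            integrated.genes_of_type("lncRNA"),
            integrated.diseases,
            {(g, d) for g, d in integrated.edges if g in lnc_ids},
        )
        assert restricted == lnc_only


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_edges": 10},  # fewer edges than diseases
            {"n_edges": 20000},  # more than possible pairs at default sizes
            {"within_class_bias": 0.5},
            {"degree_exponent": 1.0},
            {"n_lncrna_edges": 600},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ln.GeneratorConfig(**kwargs)

    def test_write_fixture_round_trip(self, tmp_path, small_fixture):
        net, truth = small_fixture
        paths = ln.write_fixture(net, truth, tmp_path)
        back = ln.load_associations(paths["associations"])
        assert back == net
        truth_rows = paths["truth"].read_text().strip().splitlines()
        assert len(truth_rows) == 1 + len(truth.hidden)
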