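import numpy as np
import pytest

from graphvar.graph_autoencoder import (
    EarlyStopper,
    EncoderConfig,
    GAEModel,
    SamplingError,
    TrainConfig,
    encoder_forward,
    evaluate_gae,
    global_mean_pool,
    init_model,
    inner_product_decode,
    load_model,
    negative_sample,
    reconstruction_loss,
    save_model,
    train_gae,
)
from graphvar.protein_graphs import ProteinGraph, build_residue_graph
from graphvar.synthetic_data import generate_structure


def _graph(n_nodes, edges, features=None, scope="residue"):
    feats = features if features is not None else np.zeros((n_nodes, 1))
    return ProteinGraph(
        scope=scope,
        node_features=np.asarray(feats, dtype=float),
        node_index=list(range(1, n_nodes + 1)),
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        edge_types=[frozenset({"peptide"})] * len(edges),
    )


class TestDecoder:
    def test_zero_vectors_give_half(self):
        assert inner_product_decode(np.zeros(4), np.zeros(4)) == 0.5

    def test_orthogonal_unit_vectors_give_half(self):
        assert inner_product_decode(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_log3_dot_product(self):
        u = np.array([np.log(3.0), 0.0])
        v = np.array([1.0, 0.0])
        assert inner_product_decode(u, v) == pytest.approx(0.75)

    def test_symmetry(self, rng):
        for _ in range(20):
            u, v = rng.normal(size=8), rng.normal(size=8)
            assert inner_product_decode(u, v) == pytest.approx(inner_product_decode(v, u))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            inner_product_decode(np.zeros(3), np.zeros(4))


class TestPooling:
    def test_constant_rows(self):
        v = np.array([1.0, -2.0, 3.0])
        assert np.allclose(global_mean_pool(np.tile(v, (5, 1))), v)

    def test_two_rows(self):
        assert np.allclose(global_mean_pool(np.array([[0.0, 2.0], [2.0, 0.0]])), [1.0, 1.0])

    def test_random_matrix_matches_column_means(self, rng):
        m = rng.normal(size=(50, 8))
        np.testing.assert_allclose(global_mean_pool(m), m.mean(axis=0))

    def test_linearity(self, rng):
        m = rng.normal(size=(10, 4))
        np.testing.assert_allclose(global_mean_pool(2 * m), 2 * global_mean_pool(m))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_mean_pool(np.zeros((0, 3)))


class TestReconstructionLoss:
    def test_half_half_closed_form(self):
        assert reconstruction_loss([0.5], [0.5]) == pytest.approx(2 * np.log(2))

    def test_perfect_limit(self):
        assert reconstruction_loss([1.0 - 1e-12], [1e-12]) < 1e-10

    def test_matches_elementwise_sum_oracle(self, rng):
        pos = rng.uniform(0.01, 0.99, size=17)
        neg = rng.uniform(0.01, 0.99, size=9)
        oracle = sum(-np.log(p) for p in pos) / 17 + sum(-np.log(1 - q) for q in neg) / 9
        assert reconstruction_loss(pos, neg) == pytest.approx(oracle)

    def test_non_negative(self, rng):
        for _ in range(20):
            pos = rng.uniform(size=5)
            neg = rng.uniform(size=5)
            assert reconstruction_loss(pos, neg) >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss([], [0.5])


class TestNegativeSampling:
    def test_only_nonedge_is_returned(self):
        g = _graph(3, [(0, 1), (1, 2)])
        neg = negative_sample(g, n_samples=1, seed=0)
        assert neg.tolist() == [[0, 2]]

    def test_never_intersects_edges(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 12))
            all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            k = int(rng.integers(1, len(all_pairs)))
            idx = rng.choice(len(all_pairs), size=k, replace=False)
            edges = [all_pairs[i] for i in idx]
            g = _graph(n, edges)
            if len(edges) == len(all_pairs):
                continue
            neg = negative_sample(g, seed=trial)
            assert not ({tuple(p) for p in neg.tolist()} & set(edges))

    def test_uniform_over_nonedges(self):
        # path 0-1-2-3: non-edges {(0,2),(0,3),(1,3)}; frequency ~ n/3 each
        g = _graph(4, [(0, 1), (1, 2), (2, 3)])
        counts = {}
        n_draws = 3000
        for s in range(n_draws):
            pair = tuple(negative_sample(g, n_samples=1, seed=s)[0])
            counts[pair] = counts.get(pair, 0) + 1
        assert set(counts) == {(0, 2), (0, 3), (1, 3)}
        sigma = np.sqrt(n_draws * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - n_draws / 3) <= 3 * sigma

    def test_complete_graph_rejected(self):
        g = _graph(3, [(0, 1), (0, 2), (1, 2)])
        with pytest.raises(SamplingError):
            negative_sample(g, n_samples=1, seed=0)


class TestEncoderForward:
    def test_shape_contract(self, residue_graph30, tiny_model):
        z = encoder_forward(residue_graph30, tiny_model)
        assert z.shape == (30, 8)

    def test_single_node_zero_model_gives_zero_row(self):
        cfg = EncoderConfig(scope="residue", input_dim=2, embedding_dim=3, n_layers=2)
        model = init_model(cfg, seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        g = _graph(1, [], features=np.zeros((1, 2)))
        np.testing.assert_array_equal(encoder_forward(g, model), np.zeros((1, 3)))

    def test_path_graph_matches_dense_oracle(self):
        # 3-node path, 1-D features and weights: oracle is the dense
        # normalized-adjacency product followed by the layer-norm formula
        cfg = EncoderConfig(scope="residue", input_dim=1, embedding_dim=1, n_layers=1)
        model = init_model(cfg, seed=0)
        w = 0.7
        model.params["W0"] = np.array([[w]])
        model.params["b0"] = np.array([0.0])
        model.params["gamma0"] = np.array([1.3])
        model.params["beta0"] = np.array([-0.2])
        x = np.array([[1.0], [2.0], [3.0]])
        g = _graph(3, [(0, 1), (1, 2)], features=x)

        a = np.array([[1.0, 1, 0], [1, 1, 1], [0, 1, 1]])  # A + I
        dinv = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
        z = dinv @ a @ dinv @ x * w
        zn = (z - z.mean()) / np.sqrt(z.var() + 1e-5)
        oracle = zn * 1.3 - 0.2
        np.testing.assert_allclose(encoder_forward(g, model), oracle, atol=1e-12)

    def test_permutation_equivariance(self, rng, tiny_model):
        g = build_residue_graph(generate_structure(15, seed=4))
        z = encoder_forward(g, tiny_model)
        perm = rng.permutation(15)
        inv = np.argsort(perm)
        permuted = ProteinGraph(
            scope="residue",
            node_features=g.node_features[perm],
            node_index=[g.node_index[p] for p in perm],
            edges=np.array([[min(inv[i], inv[j]), max(inv[i], inv[j])] for i, j in g.edges]),
            edge_types=g.edge_types,
        )
        zp = encoder_forward(permuted, tiny_model)
        np.testing.assert_allclose(zp, z[perm], atol=1e-9)

    def test_scope_mismatch_rejected(self, residue_graph30):
        cfg = EncoderConfig(scope="atomic", input_dim=25, embedding_dim=8)
        with pytest.raises(ValueError):
            encoder_forward(residue_graph30, init_model(cfg))

    def test_layer_count_defaults(self):
        assert EncoderConfig(scope="residue", input_dim=25, embedding_dim=128).n_layers == 2
        assert EncoderConfig(scope="residue", input_dim=25, embedding_dim=256).n_layers == 3


class TestEarlyStopping:
    def test_patience_rule_on_reference_sequence(self):
        stopper = EarlyStopper(patience=3)
        stopped_at = None
        for epoch, acc in enumerate([0.60, 0.70, 0.69, 0.68, 0.67], start=1):
            if stopper.update(epoch, acc):
                stopped_at = epoch
                break
        assert stopped_at == 5
        assert stopper.best_epoch == 2

    def test_monotone_improvement_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(e, e / 20) for e in range(1, 21))
        assert stopper.best_epoch == 20

    def test_plateau_counts_as_no_increase(self):
        stopper = EarlyStopper(patience=2)
        stops = [stopper.update(e, 0.5) for e in range(1, 4)]
        assert stops == [False, False, True]
        assert stopper.best_epoch == 1


@pytest.fixture(scope="module")
def graphs12():
    return [build_residue_graph(generate_structure(12, seed=s)) for s in range(12)]


class TestTraining:
    def test_too_few_graphs_rejected(self, graphs12):
        cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=4, n_layers=2)
        with pytest.raises(ValueError):
            train_gae(graphs12[:5], cfg)

    def test_reproducible_end_to_end(self, graphs12):
        cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=4, n_layers=2)
        tcfg = TrainConfig(seed=7, max_epochs=3)
        m1, h1 = train_gae(graphs12, cfg, tcfg)
        m2, h2 = train_gae(graphs12, cfg, tcfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy
        assert (h1.best_epoch, h1.stopped_epoch, h1.test_auc, h1.test_ap) == (
            h2.best_epoch, h2.stopped_epoch, h2.test_auc, h2.test_ap)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_history_invariants(self, graphs12):
        cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=4, n_layers=2)
        _, h = train_gae(graphs12, cfg, TrainConfig(seed=1, max_epochs=6))
        assert h.stopped_epoch <= 6
        assert h.best_epoch <= h.stopped_epoch
        assert len(h.train_loss) == len(h.val_accuracy) == h.stopped_epoch
        assert 0.0 <= h.test_auc <= 1.0 and 0.0 <= h.test_ap <= 1.0

    def test_evaluate_on_heldout_graphs(self, graphs12):
        cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=8, n_layers=2)
        model, _ = train_gae(graphs12, cfg, TrainConfig(seed=2, max_epochs=8))
        extra = [build_residue_graph(generate_structure(12, seed=100 + s)) for s in range(3)]
        auc, ap = evaluate_gae(model, extra, seed=0)
        assert 0.0 <= auc <= 1.0 and 0.0 <= ap <= 1.0

    def test_checkpoint_round_trip(self, graphs12, tmp_path):
        cfg = EncoderConfig(scope="residue", input_dim=25, embedding_dim=4, n_layers=2)
        model, _ = train_gae(graphs12, cfg, TrainConfig(seed=3, max_epochs=2))
        save_model(model, tmp_path / "m.ckpt")
        back = load_model(tmp_path / "m.ckpt")
        assert back.config == model.config
        z1 = encoder_forward(graphs12[0], model)
        z2 = encoder_forward(graphs12[0], back)
        np.testing.assert_array_equal(z1, z2)


class TestMPNNEncoder:
    def test_edge_features_enter_the_update(self):
        cfg = EncoderConfig(scope="atomic", input_dim=2, embedding_dim=3, n_layers=2)
        model = init_model(cfg, seed=1)
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g1 = ProteinGraph("atomic", feats, [(1, "CA"), (1, "CB"), (2, "CA")],
                          np.array([[0, 1], [1, 2]]), [frozenset({"covalent"})] * 2,
                          edge_features=np.array([0.0, 1.0]))
        g2 = ProteinGraph("atomic", feats, [(1, "CA"), (1, "CB"), (2, "CA")],
                          np.array([[0, 1], [1, 2]]), [frozenset({"covalent"})] * 2,
                          edge_features=np.array([1.0, 0.0]))
        assert not np.allclose(encoder_forward(g1, model), encoder_forward(g2, model))
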