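"""Assignment-scoring network: softmax contracts, an independent dense
re-implementation oracle, permutation equivariance, seeded training."""

import numpy as np
import pytest

from colonytrack.gnn import GNNConfig, TrackerModel, train_tracker, \
    training_graphs
from colonytrack.graph import TrackingGraph, build_graph, label_nodes
from conftest import square_frame

TINY = GNNConfig(hidden_dim=16, n_layers=2, dropout=0.0, epochs=5,
                 min_cells=4, seed=3)


def toy_graph(n_nodes=3, n_edges=2, seed=0):
    rng = np.random.default_rng(seed)
    edges = np.array([[0, 1], [1, 2]][:n_edges], dtype=np.intp) \
        if n_nodes >= 3 else np.zeros((0, 2), dtype=np.intp)
    return TrackingGraph(
        nodes=[(i + 1, i + 1) for i in range(n_nodes)],
        node_features=rng.normal(size=(n_nodes, 14)),
        edges=edges,
        edge_features=rng.normal(size=(len(edges), 12)),
        labels_t=[i + 1 for i in range(n_nodes)],
        labels_t1=[i + 1 for i in range(n_nodes)])


def dense_reference_forward(model: TrackerModel, graph: TrackingGraph):
    """Straight-line numpy re-implementation of the forward pass (loops,
    no autodiff, no sparse ops) used as an independent oracle."""
    p = {k: v.data for k, v in model.params.items()}
    relu = lambda a: np.maximum(a, 0.0)
    nf = ((graph.node_features - model.node_mean)
          / model.node_std).astype(np.float32)
    x = relu(nf @ p["node_W0"] + p["node_b0"]) @ p["node_W1"] + p["node_b1"]
    src, dst, efeat = graph.directed_edges()
    ef = ((efeat - model.edge_mean) / model.edge_std).astype(np.float32)
    if len(src):
        e_emb = relu(ef @ p["edge_W0"] + p["edge_b0"]) @ p["edge_W1"] \
            + p["edge_b1"]
    n = graph.n_nodes
    h = model.config.hidden_dim
    for l in range(model.config.n_layers):
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        y = (x - mu) / np.sqrt(var + 1e-5)
        y = relu(y * p[f"ln{l}_g"] + p[f"ln{l}_b"])
        agg = np.zeros((n, h), dtype=np.float32)
        for j in range(n):
            incoming = [k for k in range(len(src)) if dst[k] == j]
            if not incoming:
                continue
            msgs = np.array([relu(y[src[k]] + e_emb[k]) + p[f"eps{l}"]
                             for k in incoming])
            w = np.exp(msgs - msgs.max())          # same global-shift scheme
            w = w / w.sum(axis=0, keepdims=True)
            agg[j] = (w * msgs).sum(axis=0)
        z = y + agg
        z = relu(z @ p[f"conv{l}_W0"] + p[f"conv{l}_b0"]) \
            @ p[f"conv{l}_W1"] + p[f"conv{l}_b1"]
        x = x + z
    logits = x @ p["out_W"] + p["out_b"]
    ez = np.exp(logits - logits.max(axis=1, keepdims=True))
    return ez / ez.sum(axis=1, keepdims=True)


def test_scores_are_probability_pairs():
    model = TrackerModel(TINY)
    scores = model.forward(toy_graph())
    assert np.allclose(scores.sum(axis=1), 1.0)
    assert (scores > 0).all() and (scores < 1).all()


def test_forward_is_deterministic_in_eval_mode():
    model = TrackerModel(TINY)
    g = toy_graph()
    assert (model.forward(g) == model.forward(g)).all()


@pytest.mark.parametrize("n_nodes,n_edges", [(1, 0), (3, 2)])
def test_forward_matches_dense_reference(n_nodes, n_edges):
    """The vectorized sparse forward equals an independent loop-based
    re-implementation, including the edge-free (isolated node) path."""
    model = TrackerModel(TINY)
    g = toy_graph(n_nodes, n_edges, seed=11)
    got = model.forward(g)
    want = dense_reference_forward(model, g)
    assert np.allclose(got, want, atol=1e-5)


def test_permutation_equivariance():
    model = TrackerModel(TINY)
    g = toy_graph(4, 0, seed=2)
    g.edges = np.array([[0, 2], [1, 3]], dtype=np.intp)
    g.edge_features = np.random.default_rng(3).normal(size=(2, 12))
    perm = np.array([2, 0, 3, 1])
    inv = np.argsort(perm)
    g2 = TrackingGraph(
        nodes=[g.nodes[i] for i in perm],
        node_features=g.node_features[perm],
        edges=np.sort(inv[g.edges], axis=1).astype(np.intp),
        edge_features=g.edge_features.copy(),
        labels_t=g.labels_t, labels_t1=g.labels_t1)
    # keep edge orientation consistent with the sorted index pair
    for k in range(len(g.edges)):
        u, v = inv[g.edges[k]]
        if u > v:
            from colonytrack.features import PAIR_VECTOR_FLIP
            g2.edge_features[k] = g2.edge_features[k] \
                * np.concatenate([PAIR_VECTOR_FLIP, PAIR_VECTOR_FLIP])
    s1 = model.forward(g)
    s2 = model.forward(g2)
    assert np.allclose(s1[perm], s2, atol=1e-5)


@pytest.fixture(scope="module")
def tiny_trained(small_budding_colony):
    movie = small_budding_colony.movie
    cfg = GNNConfig(hidden_dim=16, n_layers=2, dropout=0.1, epochs=8,
                    min_cells=8, seed=0)
    graphs = training_graphs([movie], cfg)
    model, log = train_tracker([movie], cfg, graphs=graphs)
    return model, log, graphs, cfg


def test_training_reduces_loss(tiny_trained):
    _, log, _, _ = tiny_trained
    assert log.epoch_losses[-1] < log.epoch_losses[0]


def test_training_is_seed_reproducible(small_budding_colony, tiny_trained):
    model, _, graphs, cfg = tiny_trained
    model2, _ = train_tracker([small_budding_colony.movie], cfg)
    for k in model.params:
        assert (model.params[k].data == model2.params[k].data).all()


def test_trained_model_separates_correct_nodes(tiny_trained):
    model, _, graphs, _ = tiny_trained
    correct, incorrect = [], []
    for g in graphs[-5:]:
        s = model.forward(g)[:, 1]
        y = np.asarray(g.node_labels, dtype=bool)
        correct.extend(s[y])
        incorrect.extend(s[~y])
    assert np.mean(correct) - np.mean(incorrect) >= 0.5


def test_inverse_frequency_weighting_balances_classes(tiny_trained):
    model, _, graphs, _ = tiny_trained
    g = graphs[0]
    y = np.asarray(g.node_labels)
    n, n_pos = len(y), int(y.sum())
    w = np.where(y == 1, n / (2 * n_pos), n / (2 * (n - n_pos)))
    assert abs(w[y == 1].sum() - w[y == 0].sum()) \
        <= 0.1 * w[y == 0].sum()


def test_empty_training_set_errors(small_budding_colony):
    cfg = GNNConfig(hidden_dim=8, n_layers=2, epochs=1, min_cells=10 ** 6)
    with pytest.raises(ValueError, match="min_cells"):
        train_tracker([small_budding_colony.movie], cfg)


def test_embed_diagnostics_shapes_and_input_layer(tiny_trained):
    model, _, graphs, cfg = tiny_trained
    g = graphs[0]
    for layer in range(cfg.n_layers + 1):
        emb = model.embed_diagnostics(g, layer)
        assert emb.shape == (g.n_nodes, cfg.hidden_dim)
    # layer 0 is exactly the node-embedding MLP output
    p = {k: v.data for k, v in model.params.items()}
    nf = ((g.node_features - model.node_mean) / model.node_std) \
        .astype(np.float32)
    want = np.maximum(nf @ p["node_W0"] + p["node_b0"], 0) \
        @ p["node_W1"] + p["node_b1"]
    assert np.allclose(model.embed_diagnostics(g, 0), want, atol=1e-6)
    with pytest.raises(IndexError):
        model.embed_diagnostics(g, cfg.n_layers + 1)


def test_final_layer_probe_beats_input_probe(tiny_trained):
    """Linear probes: the last message-passing layer should separate
    correct from incorrect assignment nodes better than the input layer
    on held-out transitions (information accumulates through depth)."""
    from sklearn.linear_model import LogisticRegression
    model, _, graphs, cfg = tiny_trained
    train_g, test_g = graphs[:-4], graphs[-4:]

    def probe_acc(layer):
        Xtr = np.concatenate([model.embed_diagnostics(g, layer)
                              for g in train_g])
        ytr = np.concatenate([g.node_labels for g in train_g])
        Xte = np.concatenate([model.embed_diagnostics(g, layer)
                              for g in test_g])
        yte = np.concatenate([g.node_labels for g in test_g])
        clf = LogisticRegression(max_iter=1000).fit(Xtr, ytr)
        return (clf.predict(Xte) == yte).mean()

    assert probe_acc(cfg.n_layers) > probe_acc(0)


def test_checkpoint_roundtrip_and_schema_guard(tiny_trained, tmp_path):
    model, _, graphs, _ = tiny_trained
    path = tmp_path / "tracker.npz"
    model.save(path)
    back = TrackerModel.load(path)
    g = graphs[0]
    assert np.allclose(model.forward(g), back.forward(g))
    # tamper with the stored schema hash -> refusal
    import json
    with np.load(path) as z:
        blobs = dict(z)
    meta = json.loads(bytes(blobs["_meta"]).decode())
    meta["schema_hash"] = "0" * 16
    blobs["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **blobs)
    with pytest.raises(ValueError, match="schema"):
        TrackerModel.load(path)


def test_label_invariant_scores():
    """Relabeling cell IDs leaves scores unchanged (features are
    label-free)."""
    f0 = square_frame(0, [(10, 10), (10, 17), (30, 30)])
    f1 = square_frame(1, [(11, 10), (11, 17), (31, 30)])
    g1 = build_graph(f0, f1, com_gate=None)
    shuffled0 = np.zeros_like(f0.labels)
    shuffled1 = np.zeros_like(f1.labels)
    for old, new in {1: 12, 2: 5, 3: 9}.items():
        shuffled0[f0.labels == old] = new
        shuffled1[f1.labels == old] = new
    from colonytrack.mask_io import LabeledFrame
    g2 = build_graph(LabeledFrame(0, shuffled0), LabeledFrame(1, shuffled1),
                     com_gate=None)
    model = TrackerModel(TINY)
    s1 = {pair: row for pair, row in zip(g1.nodes,
                                         model.forward(g1)[:, 1])}
    s2 = {pair: row for pair, row in zip(g2.nodes,
                                         model.forward(g2)[:, 1])}
    remap = {1: 12, 2: 5, 3: 9}
    for (a, b), v in s1.items():
        assert s2[(remap[a], remap[b])] == pytest.approx(v, abs=1e-6)
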