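import numpy as np
import pytest

from phagehostkg import encoder as enc
from phagehostkg.graph import PHKG
from phagehostkg.kmer import FeatureMatrix


# ---------------------------------------------------------------------------
# elementary operations

def test_attention_coefficient_matches_hand_computation():
    rng = np.random.default_rng(0)
    f_i, f_j = rng.normal(size=3), rng.normal(size=3)
    W, a = rng.normal(size=(4, 6)), rng.normal(size=4)
    z = W @ np.concatenate([f_i, f_j])
    z = np.where(z > 0, z, 0.2 * z)
    assert enc.attention_coefficients(f_i, f_j, W, a) == pytest.approx(float(a @ z))


def test_zero_attention_map_gives_zero():
    f = np.ones(3)
    W = np.ones((4, 6))
    assert enc.attention_coefficients(f, f, W, np.zeros(4)) == 0.0


def test_attention_coefficient_dim_mismatch():
    with pytest.raises(ValueError):
        enc.attention_coefficients(np.ones(3), np.ones(2), np.ones((4, 6)), np.ones(4))


@pytest.mark.parametrize(
    "e,expected",
    [
        ([5.0], [1.0]),
        ([2.0, 2.0, 2.0, 2.0], [0.25] * 4),
        ([0.0, np.log(3.0)], [0.25, 0.75]),
    ],
)
def test_attention_weights(e, expected):
    np.testing.assert_allclose(enc.attention_weights(np.array(e)), expected, atol=1e-12)


def test_attention_weights_stable_at_large_logits():
    w = enc.attention_weights(np.array([1000.0, 1000.0]))
    np.testing.assert_allclose(w, [0.5, 0.5])


@pytest.mark.parametrize(
    "fp,fh,expected",
    [
        ([1.0, 0.0], [0.0, 1.0], 0.0),
        ([1.0, 0.0], [1.0, 0.0], 1.0),
        ([1.0, 2.0], [3.0, 4.0], 11.0),
    ],
)
def test_decoder_score(fp, fh, expected):
    assert enc.decoder_score(np.array(fp), np.array(fh)) == expected
    assert enc.decoder_score(np.array(fh), np.array(fp)) == expected  # symmetric


def test_decoder_dim_mismatch():
    with pytest.raises(ValueError):
        enc.decoder_score(np.ones(3), np.ones(4))


# ---------------------------------------------------------------------------
# layer forward against an explicit per-node reference

def _reference_layer(graph, X, layer, heads):
    """Plain-loop layer update built from the elementary public operations."""
    nodes = graph.nodes
    ix = {n: i for i, n in enumerate(nodes)}
    din = X.shape[1]
    dout = layer["pp"]["W"].shape[1]
    Z = np.zeros((len(nodes), dout))
    for node in nodes:
        i = ix[node]
        for et in ("pp", "hh", "ph"):
            neigh = sorted(graph.neighbors(node, et))
            cls = "p" if node in graph.phages else "h"
            participates = (
                (et == "pp" and cls == "p")
                or (et == "hh" and cls == "h")
                or et == "ph"
            )
            if not participates:
                continue
            members = [ix[n] for n in neigh] + [i]
            for m in range(heads):
                W, a = layer[et]["W"][m], layer[et]["a"][m]
                es = np.array([
                    enc.attention_coefficients(X[i], X[j], W, a) for j in members
                ])
                alpha = enc.attention_weights(es)
                Wr = W[:, din:]
                for w, j in zip(alpha, members):
                    Z[i] += w * (Wr @ X[j])
    return enc.elu(Z / heads)


def test_layer_forward_matches_reference(tiny_graph):
    X = tiny_graph.features.matrix
    params = enc.ModelParams.init(dims=(6, 4), heads=3, seed=2)
    hidden = enc.EmbeddingTable(tiny_graph.nodes, X)
    out = enc.layer_forward(tiny_graph, hidden, params.layers[0], heads=3)
    ref = _reference_layer(tiny_graph, X, params.layers[0], heads=3)
    np.testing.assert_allclose(out.vectors, ref, atol=1e-10)


def test_isolated_node_uses_self_only():
    phages, hosts = ["P0"], ["H0"]
    X = np.array([[1.0, -2.0], [0.5, 3.0]])
    feats = FeatureMatrix(phages + hosts, X, k=1)
    graph = PHKG(phages, hosts, {"pp": set(), "hh": set(), "ph": set()}, feats)
    params = enc.ModelParams.init(dims=(2, 3), heads=2, seed=0)
    hidden = enc.EmbeddingTable(graph.nodes, X)
    out = enc.layer_forward(graph, hidden, params.layers[0], heads=2)
    # phage: self term through pp and ph; host: through hh and ph; alpha = 1
    for row, types in ((0, ("pp", "ph")), (1, ("hh", "ph"))):
        expected = np.zeros(3)
        for et in types:
            Wr = params.layers[0][et]["W"][:, :, 2:]
            expected += np.einsum("mod,d->o", Wr, X[row])
        np.testing.assert_allclose(out.vectors[row], enc.elu(expected / 2), atol=1e-12)


def test_zero_parameters_give_zero_embeddings(tiny_graph):
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=2, seed=0)
    for layer in params.layers:
        for et in layer:
            layer[et]["W"][:] = 0.0
            layer[et]["a"][:] = 0.0
    table = enc.encode(tiny_graph, tiny_graph.features, params)
    np.testing.assert_array_equal(table.vectors, 0.0)


def test_encode_is_deterministic(tiny_graph):
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=2, seed=3)
    t1 = enc.encode(tiny_graph, tiny_graph.features, params)
    t2 = enc.encode(tiny_graph, tiny_graph.features, params)
    np.testing.assert_array_equal(t1.vectors, t2.vectors)


def test_attention_normalization_per_node_type_head(tiny_graph):
    X = tiny_graph.features.matrix
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=4, seed=1)
    _, caches = enc.forward(tiny_graph, X, params)
    for _, _, layer_cache in [(0, 0, caches[0])] + [(1, 0, caches[1])]:
        _Xd, _mask, _Z, per_type = layer_cache
        for et, cache in per_type.items():
            if cache is None:
                continue
            I, J, uniq, starts, seg_of, *_rest, alpha, _att = cache
            sums = np.add.reduceat(alpha, starts, axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_permutation_equivariance(tiny_graph):
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=2, seed=4)
    base = enc.encode(tiny_graph, tiny_graph.features, params)
    # relabel nodes, permuting features correspondingly
    mapping = {"P0": "P9", "P1": "P5", "H0": "H7", "H1": "H3", "H2": "H1"}
    edges = {
        et: {tuple(sorted((mapping[a], mapping[b]))) for a, b in es}
        for et, es in tiny_graph.edges.items()
    }
    new_phages = sorted(mapping[p] for p in tiny_graph.phages)
    new_hosts = sorted(mapping[h] for h in tiny_graph.hosts)
    inv = {v: k for k, v in mapping.items()}
    order = [inv[n] for n in new_phages + new_hosts]
    X = np.array([tiny_graph.features.row(n) for n in order])
    feats = FeatureMatrix(new_phages + new_hosts, X, k=1)
    relabeled = PHKG(new_phages, new_hosts, edges, feats)
    out = enc.encode(relabeled, feats, params)
    for old, new in mapping.items():
        np.testing.assert_allclose(out[new], base[old], atol=1e-10)


# ---------------------------------------------------------------------------
# gradients

def bpr_objective(graph, X, params):
    H, caches = enc.forward(graph, X, params)
    qp, qn = H[0] @ H[2], H[0] @ H[4]
    return float(np.logaddexp(0.0, -(qp - qn))), H, caches


def test_analytic_gradients_match_numerical(tiny_graph):
    X = tiny_graph.features.matrix
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=2, seed=1)
    loss, H, caches = bpr_objective(tiny_graph, X, params)
    dmargin = -1.0 / (1.0 + np.exp((H[0] @ H[2]) - (H[0] @ H[4])))
    dH = np.zeros_like(H)
    dH[0] = dmargin * (H[2] - H[4])
    dH[2] = dmargin * H[0]
    dH[4] = -dmargin * H[0]
    _, grads = enc.backward(dH, caches, params)
    flat = params.flat()
    eps, worst = 1e-6, 0.0
    for ai, arr in enumerate(flat):
        picks = np.random.default_rng(ai).choice(arr.size, size=min(15, arr.size), replace=False)
        for flat_ix in picks:
            idx = np.unravel_index(flat_ix, arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _, _ = bpr_objective(tiny_graph, X, params)
            arr[idx] = orig - eps
            lm, _, _ = bpr_objective(tiny_graph, X, params)
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[ai][idx]
            if abs(num) < 1e-7 and abs(ana) < 1e-7:
                continue  # both vanish; agreement at zero
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana)))
    assert worst < 1e-4


# ---------------------------------------------------------------------------
# checkpoints

def test_checkpoint_roundtrip(tmp_path, tiny_graph):
    params = enc.ModelParams.init(dims=(6, 4, 3), heads=2, seed=9)
    params.fit_input_normalization(tiny_graph.features.matrix)
    config = {"epochs": 5, "seed": 9}
    enc.save_checkpoint(params, config, tmp_path / "ck.npz")
    back, cfg = enc.load_checkpoint(tmp_path / "ck.npz", expect_config=config)
    assert cfg == config
    for a, b in zip(params.flat(), back.flat()):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(back.input_loc, params.input_loc)
    t1 = enc.encode(tiny_graph, tiny_graph.features, params)
    t2 = enc.encode(tiny_graph, tiny_graph.features, back)
    np.testing.assert_array_equal(t1.vectors, t2.vectors)


def test_checkpoint_config_hash_mismatch_refused(tmp_path):
    params = enc.ModelParams.init(dims=(6, 4), heads=1, seed=0)
    enc.save_checkpoint(params, {"epochs": 5}, tmp_path / "ck.npz")
    with pytest.raises(ValueError, match="different configuration"):
        enc.load_checkpoint(tmp_path / "ck.npz", expect_config={"epochs": 6})
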