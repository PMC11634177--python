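"""Network forward-pass contracts, checked against scalar brute-force oracles."""

import numpy as np
import pytest

from actin.chemgraph import MolecularGraph, parse_smiles
from actin.model import (
    CellLineModel,
    DrugEncoderConfig,
    InterfusionConfig,
    ModelConfig,
    embed_atoms,
    encode_drug,
    gatv2_layer,
    interfusion_block,
    interfusion_attention,
    predict_score,
    project_gene,
    topk_pool,
)

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# brute-force oracles (scalar reimplementations, no shared code)
# ---------------------------------------------------------------------------

def gat_oracle(features, edges, model, stage, slope=0.2):
    """Dense per-node GATv2: score every pair, mask non-neighbours (plus
    self-loop), softmax, weighted sum of the right-projected messages,
    concatenate heads, leaky-ReLU."""
    Wl = model.params[f"gat{stage}.Wl"].data
    Wr = model.params[f"gat{stage}.Wr"].data
    a = model.params[f"gat{stage}.a"].data
    n = features.shape[0]
    H, _, dh = Wl.shape
    nbr = {i: {i} for i in range(n)}
    for i, j in edges:
        nbr[i].add(j)
        nbr[j].add(i)
    out = np.zeros((n, H * dh))
    alphas = np.zeros((H, n, n))
    for h in range(H):
        for i in range(n):
            scores = {}
            for j in nbr[i]:
                z = features[i] @ Wl[h] + features[j] @ Wr[h]
                z = np.where(z > 0, z, slope * z)
                scores[j] = float(a[h] @ z)
            mx = max(scores.values())
            exp = {j: np.exp(s - mx) for j, s in scores.items()}
            total = sum(exp.values())
            acc = np.zeros(dh)
            for j in nbr[i]:
                alphas[h, i, j] = exp[j] / total
                acc += alphas[h, i, j] * (features[j] @ Wr[h])
            out[i, h * dh:(h + 1) * dh] = acc
    return np.where(out > 0, out, slope * out), alphas


def interfusion_oracle(x, model, block):
    """Step-by-step scalar pre-LN transformer block on a (2, d) stack."""
    p = {k.split(".", 1)[1]: v.data for k, v in model.params.items()
         if k.startswith(f"blk{block}.")}
    cfg = model.config.interfusion
    H, dk, d = cfg.heads, cfg.d_k, cfg.d

    def ln(row):
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        return (row - mu) / np.sqrt(var + 1e-5)

    pre = np.stack([ln(x[t]) * p["ln1.g"] + p["ln1.b"] for t in range(2)])
    head_outs = []
    for h in range(H):
        Q = pre @ p["Wq"][h]
        K = pre @ p["Wk"][h]
        V = pre @ p["Wv"][h]
        S = Q @ K.T / np.sqrt(dk)
        A = np.zeros((2, 2))
        for t in range(2):
            e = np.exp(S[t] - S[t].max())
            A[t] = e / e.sum()
        head_outs.append(A @ V)
    x_o = np.concatenate(head_outs, axis=1) @ p["Wo"]
    x1 = x + x_o
    pre2 = np.stack([ln(x1[t]) * p["ln2.g"] + p["ln2.b"] for t in range(2)])
    hid = pre2 @ p["ffn.W1"] + p["ffn.b1"]
    hid = np.maximum(hid, 0.0)
    return x1 + hid @ p["ffn.W2"] + p["ffn.b2"]


# ---------------------------------------------------------------------------
# atom embedding
# ---------------------------------------------------------------------------

def test_embed_atoms_shared_map_and_shape(tiny_model):
    g = parse_smiles("CCO")
    from actin.chemgraph import one_hot_atoms
    out = embed_atoms(one_hot_atoms(g), tiny_model)
    assert out.shape == (3, 32)
    np.testing.assert_array_equal(out[0], out[1])  # both carbons


def test_embed_atoms_zero_params_zero_output(tiny_model):
    import copy
    m = CellLineModel("Z", tiny_model.config, seed=0)
    m.params["atom_embed.W"].data[:] = 0
    m.params["atom_embed.b"].data[:] = 0
    out = embed_atoms(np.eye(14), m)
    np.testing.assert_array_equal(out, np.zeros((14, 32)))


def test_embed_atoms_rejects_wrong_width(tiny_model):
    with pytest.raises(ValueError):
        embed_atoms(np.ones((3, 13)), tiny_model)


# ---------------------------------------------------------------------------
# GATv2
# ---------------------------------------------------------------------------

def test_gatv2_matches_brute_force_oracle_on_path_graph(tiny_model):
    n, d = 5, 32
    feats = RNG.normal(size=(n, d))
    edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
    out, alpha = gatv2_layer(feats, edges, tiny_model, stage=0)
    out_o, alpha_o = gat_oracle(feats, edges, tiny_model, stage=0)
    np.testing.assert_allclose(out, out_o, atol=1e-6)
    np.testing.assert_allclose(alpha, alpha_o, atol=1e-6)


def test_gatv2_matches_oracle_on_random_graphs(tiny_model):
    for trial in range(5):
        n = int(RNG.integers(2, 7))
        feats = RNG.normal(size=(n, 32))
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if RNG.random() < 0.5]
        out, alpha = gatv2_layer(feats, edges, tiny_model, stage=1)
        out_o, alpha_o = gat_oracle(feats, edges, tiny_model, stage=1)
        np.testing.assert_allclose(out, out_o, atol=1e-6)
        np.testing.assert_allclose(alpha, alpha_o, atol=1e-6)


def test_gatv2_attention_rows_sum_to_one(tiny_model):
    n = 6
    feats = RNG.normal(size=(n, 32))
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)]
    _, alpha = gatv2_layer(feats, edges, tiny_model, stage=0)
    np.testing.assert_allclose(alpha.sum(axis=-1), np.ones((4, n)), atol=1e-6)
    assert np.all(alpha >= 0)


def test_gatv2_isolated_node_attends_only_itself(tiny_model):
    feats = RNG.normal(size=(1, 32))
    _, alpha = gatv2_layer(feats, [], tiny_model, stage=0)
    np.testing.assert_allclose(alpha[:, 0, 0], np.ones(4), atol=1e-12)


def test_gatv2_rejects_empty_graph(tiny_model):
    with pytest.raises(ValueError):
        gatv2_layer(np.zeros((0, 32)), [], tiny_model)


# ---------------------------------------------------------------------------
# TopK pooling
# ---------------------------------------------------------------------------

def test_topk_ratio_one_keeps_all_nodes_in_order(tiny_model):
    feats = RNG.normal(size=(6, 32))
    kept, edges, idx = topk_pool(feats, [(0, 1), (2, 3)], tiny_model, ratio=1.0)
    assert sorted(idx.tolist()) == list(range(6))
    assert kept.shape == (6, 32)


def test_topk_keeps_ceil_ratio_nodes(tiny_model):
    feats = RNG.normal(size=(10, 32))
    kept, _, idx = topk_pool(feats, [(i, i + 1) for i in range(9)],
                             tiny_model, ratio=0.8)
    assert len(idx) == 8  # ceil(0.8 * 10)


def test_topk_equal_scores_keep_lowest_indices(tiny_model):
    feats = np.tile(RNG.normal(size=32), (7, 1))  # identical rows -> tied scores
    _, _, idx = topk_pool(feats, [(i, i + 1) for i in range(6)],
                          tiny_model, ratio=0.5)
    assert idx.tolist() == [0, 1, 2, 3]  # ceil(0.5*7)=4, lowest indices win


def test_topk_keeps_induced_edges_only(tiny_model):
    feats = RNG.normal(size=(4, 32))
    kept, edges, idx = topk_pool(feats, [(0, 1), (1, 2), (2, 3)], tiny_model,
                                 ratio=0.5)
    remap = {orig: new for new, orig in enumerate(idx)}
    for i, j in edges:
        oi = [o for o, nn in remap.items() if nn == i][0]
        oj = [o for o, nn in remap.items() if nn == j][0]
        assert {oi, oj} in [{0, 1}, {1, 2}, {2, 3}]


# ---------------------------------------------------------------------------
# drug encoder
# ---------------------------------------------------------------------------

def _permute_graph(g: MolecularGraph, perm):
    inv = {old: new for new, old in enumerate(perm)}
    nodes = tuple(g.nodes[old] for old in perm)
    edges = tuple((min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in g.edges)
    return MolecularGraph(nodes=nodes, edges=edges, source_smiles=g.source_smiles)


def test_encode_drug_permutation_invariant(tiny_model):
    g = parse_smiles("CCOS(C)CC(N)Cl")
    base = encode_drug(g, tiny_model)
    rng = np.random.default_rng(3)
    for _ in range(50):
        perm = rng.permutation(g.n_atoms)
        out = encode_drug(_permute_graph(g, perm), tiny_model)
        np.testing.assert_allclose(out, base, atol=1e-6)


def test_encode_drug_output_width(tiny_model, small_molecules):
    for g in small_molecules:
        assert encode_drug(g, tiny_model).shape == (32,)


def test_single_atom_mean_equals_max_readout(tiny_model):
    from actin.model import _encode_drugs_t, _gat_stage_t, _masked_readout, \
        _embed_atoms_t, _with_self_loops
    from actin.autodiff import Tensor
    g = parse_smiles("C")
    from actin.chemgraph import one_hot_atoms
    h = _embed_atoms_t(one_hot_atoms(g)[None], tiny_model)
    mask = np.ones((1, 1))
    h, _ = _gat_stage_t(h, _with_self_loops(np.zeros((1, 1, 1)), mask), mask,
                        tiny_model, 0)
    ro = _masked_readout(h, mask).data[0]
    d = 32
    np.testing.assert_allclose(ro[:d], ro[d:], atol=1e-12)


# ---------------------------------------------------------------------------
# gene projection / interfusion / head
# ---------------------------------------------------------------------------

def test_project_gene_shape_and_determinism(tiny_model):
    v = RNG.normal(size=16)
    out1, out2 = project_gene(v, tiny_model), project_gene(v, tiny_model)
    assert out1.shape == (32,)
    np.testing.assert_array_equal(out1, out2)
    with pytest.raises(ValueError):
        project_gene(np.ones(17), tiny_model)


def test_project_gene_zero_weights_zero_output(tiny_model):
    m = CellLineModel("Z", tiny_model.config, seed=1)
    for k in ("gene_proj.W1", "gene_proj.b1", "gene_proj.W2", "gene_proj.b2"):
        m.params[k].data[:] = 0
    np.testing.assert_array_equal(project_gene(np.ones(16), m), np.zeros(32))


def test_interfusion_matches_scalar_oracle(tiny_model):
    for block in range(2):
        x = RNG.normal(size=(2, 32))
        np.testing.assert_allclose(
            interfusion_block(x, tiny_model, block),
            interfusion_oracle(x, tiny_model, block),
            atol=1e-6,
        )


def test_interfusion_attention_rows_sum_to_one(tiny_model):
    x = RNG.normal(size=(2, 32))
    attn = interfusion_attention(x, tiny_model, 0)
    assert attn.shape == (4, 2, 2)
    np.testing.assert_allclose(attn.sum(axis=-1), np.ones((4, 2)), atol=1e-6)


def test_interfusion_residual_zero_identity(tiny_model):
    """With both sublayer output weights zero the block is the identity."""
    m = CellLineModel("Z", tiny_model.config, seed=2)
    m.params["blk0.Wo"].data[:] = 0
    m.params["blk0.ffn.W2"].data[:] = 0
    m.params["blk0.ffn.b2"].data[:] = 0
    x = RNG.normal(size=(2, 32))
    np.testing.assert_allclose(interfusion_block(x, m, 0), x, atol=1e-12)


def test_predict_score_bounded_and_deterministic(tiny_model):
    for _ in range(20):
        g, d = RNG.normal(size=32), RNG.normal(size=32)
        s = predict_score(g, d, tiny_model)
        assert -1 < s < 1
        assert predict_score(g, d, tiny_model) == s


def test_predict_score_token_order_matters(tiny_model):
    g, d = RNG.normal(size=32), RNG.normal(size=32)
    assert predict_score(g, d, tiny_model) != pytest.approx(
        predict_score(d, g, tiny_model), abs=1e-9)


def test_predict_score_rejects_non_finite(tiny_model):
    bad = np.full(32, np.nan)
    with pytest.raises(ValueError):
        predict_score(bad, np.ones(32), tiny_model)


# ---------------------------------------------------------------------------
# configuration & persistence
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        InterfusionConfig(d=256, d_k=64, heads=3)
    with pytest.raises(ValueError):
        DrugEncoderConfig(pool_ratio=0.0)
    with pytest.raises(ValueError):
        ModelConfig(encoder=DrugEncoderConfig(atom_embed_dim=128, gat_head_dim=32),
                    interfusion=InterfusionConfig())


def test_checkpoint_round_trip(tmp_path, tiny_model):
    path = tmp_path / "model.ckpt"
    tiny_model.save(path)
    loaded = CellLineModel.load(path)
    assert loaded.cell_line == tiny_model.cell_line
    assert loaded.config == tiny_model.config
    for k in tiny_model.params:
        np.testing.assert_array_equal(loaded.params[k].data, tiny_model.params[k].data)
    g = parse_smiles("CCOS(C)CC")
    np.testing.assert_allclose(encode_drug(g, loaded), encode_drug(g, tiny_model),
                               atol=1e-12)
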