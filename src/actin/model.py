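"""The ACTIN network: per-cell-line drug-gene interaction scoring.

Architecture
------------
* **Drug encoder** — atoms one-hot over the 14-element vocabulary are mapped
  to d-dimensional embeddings, then passed through ``n_stages`` rounds of
  GATv2 attention followed by TopK pooling.  After each pooling stage a
  multiscale readout (mean ‖ max over surviving atoms) is taken; the stage
  readouts are concatenated and projected to the d-dimensional common space,
  giving the drug vector D_i.
* **Gene projection** — a two-layer perceptron maps the 128-d node2vec gene
  vector into the same d-dimensional space, giving G_j.
* **Transpositional interfusion** — the 2-token sequence X = [G_j; D_i] is
  processed by N pre-layer-norm transformer encoder blocks (multi-head
  attention with heads·d_k = d, output matrix W_o, FFN with residual
  shortcuts), letting the gene and drug tokens exchange information.
* **Head** — both tokens are flattened and passed through a perceptron with a
  tanh squash, so the interaction score S_{i,j} lies in (-1, 1), the range of
  the step-function targets.

Defaults follow the published configuration (d = 256, d_k = 64, 4 heads,
N = 6 blocks); every width is configurable so tests and benchmarks can run
reduced models.  All forward passes are implemented twice in this repository:
here in vectorised batched form, and as scalar brute-force oracles in the
test suite.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, layer_norm, softmax
from .chemgraph import VOCABULARY, MolecularGraph, one_hot_atoms

N_ELEMENTS = len(VOCABULARY)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEncoderConfig:
    atom_embed_dim: int = 256
    gat_heads: int = 4
    gat_head_dim: int = 64      # heads * head_dim == atom_embed_dim
    pool_ratio: float = 0.8
    n_stages: int = 2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.atom_embed_dim <= 0 or self.gat_heads <= 0 or self.gat_head_dim <= 0:
            raise ValueError("encoder dimensions must be positive")
        if self.gat_heads * self.gat_head_dim != self.atom_embed_dim:
            raise ValueError("gat_heads * gat_head_dim must equal atom_embed_dim")
        if not 0 < self.pool_ratio <= 1:
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.n_stages < 1:
            raise ValueError("need at least one GATv2/pooling stage")


@dataclass(frozen=True)
class InterfusionConfig:
    d: int = 256
    d_k: int = 64
    heads: int = 4
    n_blocks: int = 6
    ffn_hidden: int = 1024

    def __post_init__(self):
        if self.heads * self.d_k != self.d:
            raise ValueError("heads * d_k must equal d")
        if self.n_blocks < 1:
            raise ValueError("need at least one interfusion block")


@dataclass(frozen=True)
class ModelConfig:
    encoder: DrugEncoderConfig = field(default_factory=DrugEncoderConfig)
    interfusion: InterfusionConfig = field(default_factory=InterfusionConfig)
    gene_dim: int = 128

    def __post_init__(self):
        if self.encoder.atom_embed_dim != self.interfusion.d:
            raise ValueError("encoder output width must match interfusion width d")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            encoder=DrugEncoderConfig(**d["encoder"]),
            interfusion=InterfusionConfig(**d["interfusion"]),
            gene_dim=d["gene_dim"],
        )

    @staticmethod
    def reduced(d: int = 64, d_k: int = 16, heads: int = 4, n_blocks: int = 2,
                n_stages: int = 2, gene_dim: int = 128) -> "ModelConfig":
        """A small configuration for benchmarks and tests."""
        return ModelConfig(
            encoder=DrugEncoderConfig(atom_embed_dim=d, gat_heads=heads,
                                      gat_head_dim=d // heads, n_stages=n_stages),
            interfusion=InterfusionConfig(d=d, d_k=d_k, heads=heads,
                                          n_blocks=n_blocks, ffn_hidden=4 * d),
            gene_dim=gene_dim,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

class CellLineModel:
    """All trainable parameters of one per-cell-line model."""

    def __init__(self, cell_line: str, config: ModelConfig, seed: int = 0):
        self.cell_line = cell_line
        self.config = config
        self.seed = int(seed)
        self.metadata: dict = {"seed": self.seed, "epochs_trained": 0,
                               "config_hash": config.hash()}
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- initialisation ----------------------------------------------------
    def _glorot(self, rng, *shape) -> Tensor:
        fan_in, fan_out = shape[-2], shape[-1]
        std = math.sqrt(2.0 / (fan_in + fan_out))
        return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

    def _zeros(self, *shape) -> Tensor:
        return Tensor(np.zeros(shape), requires_grad=True)

    def _ones(self, *shape) -> Tensor:
        return Tensor(np.ones(shape), requires_grad=True)

    def _init_params(self, rng):
        enc, inter = self.config.encoder, self.config.interfusion
        d, dh, H = enc.atom_embed_dim, enc.gat_head_dim, enc.gat_heads
        p = self.params
        p["atom_embed.W"] = self._glorot(rng, N_ELEMENTS, d)
        p["atom_embed.b"] = self._zeros(d)
        for s in range(enc.n_stages):
            p[f"gat{s}.Wl"] = self._glorot(rng, H, d, dh)
            p[f"gat{s}.Wr"] = self._glorot(rng, H, d, dh)
            p[f"gat{s}.a"] = Tensor(rng.normal(0.0, 1.0 / math.sqrt(dh), size=(H, dh)),
                                    requires_grad=True)
            p[f"pool{s}.p"] = Tensor(rng.normal(0.0, 1.0 / math.sqrt(d), size=(d,)),
                                     requires_grad=True)
        p["drug_proj.W"] = self._glorot(rng, enc.n_stages * 2 * d, d)
        p["drug_proj.b"] = self._zeros(d)
        p["gene_proj.W1"] = self._glorot(rng, self.config.gene_dim, d)
        p["gene_proj.b1"] = self._zeros(d)
        p["gene_proj.W2"] = self._glorot(rng, d, d)
        p["gene_proj.b2"] = self._zeros(d)
        dk, Hi = inter.d_k, inter.heads
        for i in range(inter.n_blocks):
            p[f"blk{i}.ln1.g"] = self._ones(inter.d)
            p[f"blk{i}.ln1.b"] = self._zeros(inter.d)
            p[f"blk{i}.Wq"] = self._glorot(rng, Hi, inter.d, dk)
            p[f"blk{i}.Wk"] = self._glorot(rng, Hi, inter.d, dk)
            p[f"blk{i}.Wv"] = self._glorot(rng, Hi, inter.d, dk)
            p[f"blk{i}.Wo"] = self._glorot(rng, Hi * dk, inter.d)
            p[f"blk{i}.ln2.g"] = self._ones(inter.d)
            p[f"blk{i}.ln2.b"] = self._zeros(inter.d)
            p[f"blk{i}.ffn.W1"] = self._glorot(rng, inter.d, inter.ffn_hidden)
            p[f"blk{i}.ffn.b1"] = self._zeros(inter.ffn_hidden)
            p[f"blk{i}.ffn.W2"] = self._glorot(rng, inter.ffn_hidden, inter.d)
            p[f"blk{i}.ffn.b2"] = self._zeros(inter.d)
        p["head.W1"] = self._glorot(rng, 2 * inter.d, inter.d)
        p["head.b1"] = self._zeros(inter.d)
        p["head.W2"] = self._glorot(rng, inter.d, 1)
        p["head.b2"] = self._zeros(1)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self):
        for t in self.params.values():
            t.zero_grad()

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Self-describing single-file checkpoint: JSON config + named arrays."""
        meta = {
            "cell_line": self.cell_line,
            "config": self.config.to_dict(),
            "metadata": self.metadata,
            "seed": self.seed,
        }
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:  # keep the caller's exact filename
            np.savez(fh, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "CellLineModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            config = ModelConfig.from_dict(meta["config"])
            if config.hash() != meta["metadata"]["config_hash"]:
                raise ValueError(f"{path}: config hash mismatch — corrupted checkpoint")
            model = cls(meta["cell_line"], config, seed=meta["seed"])
            model.metadata = meta["metadata"]
            for k in model.params:
                data = npz[f"param:{k}"]
                if data.shape != model.params[k].data.shape:
                    raise ValueError(f"{path}: parameter {k} has wrong shape")
                model.params[k] = Tensor(data, requires_grad=True)
        return model


# ---------------------------------------------------------------------------
# batched graph utilities
# ---------------------------------------------------------------------------

def _pad_graphs(graphs: list[MolecularGraph]):
    """Pad a list of graphs to (one_hot, adjacency, node_mask) arrays."""
    if not graphs:
        raise ValueError("empty graph batch")
    n_max = max(g.n_atoms for g in graphs)
    B = len(graphs)
    onehot = np.zeros((B, n_max, N_ELEMENTS))
    adj = np.zeros((B, n_max, n_max))
    mask = np.zeros((B, n_max))
    for b, g in enumerate(graphs):
        oh = one_hot_atoms(g)
        onehot[b, : g.n_atoms] = oh
        adj[b, : g.n_atoms, : g.n_atoms] = g.adjacency()
        mask[b, : g.n_atoms] = 1.0
    return onehot, adj, mask


def _with_self_loops(adj: np.ndarray, mask: np.ndarray) -> np.ndarray:
    eye = np.eye(adj.shape[1])[None, :, :] * mask[:, :, None]
    return np.clip(adj + eye, 0.0, 1.0)


# ---------------------------------------------------------------------------
# forward passes (batched, differentiable)
# ---------------------------------------------------------------------------

def _embed_atoms_t(onehot, model: CellLineModel) -> Tensor:
    oh = onehot if isinstance(onehot, Tensor) else Tensor(onehot)
    return oh @ model.params["atom_embed.W"] + model.params["atom_embed.b"]


def _gat_stage_t(h: Tensor, adj_self: np.ndarray, mask: np.ndarray,
                 model: CellLineModel, stage: int):
    """One batched GATv2 layer.  Returns (features (B,n,d), attention (B,H,n,n))."""
    enc = model.config.encoder
    B, n, d = h.shape
    H, dh = enc.gat_heads, enc.gat_head_dim
    Wl, Wr = model.params[f"gat{stage}.Wl"], model.params[f"gat{stage}.Wr"]
    a = model.params[f"gat{stage}.a"]

    h4 = h.reshape(B, 1, n, d)
    left = h4 @ Wl            # (B, H, n, dh)
    right = h4 @ Wr           # (B, H, n, dh)
    # GATv2 score: e(i,j) = a^T LeakyReLU(Wl x_i + Wr x_j)
    pair = left.reshape(B, H, n, 1, dh) + right.reshape(B, H, 1, n, dh)
    scores = (pair.leaky_relu(enc.leaky_slope) * a.reshape(1, H, 1, 1, dh)).sum(axis=-1)
    neg = (adj_self[:, None, :, :] - 1.0) * 1e9  # mask non-neighbours
    alpha = softmax(scores + neg, axis=-1)       # rows sum to 1 over N(i) u {i}
    msg = alpha @ right                          # (B, H, n, dh)
    out = msg.swapaxes(1, 2).reshape(B, n, H * dh).leaky_relu(enc.leaky_slope)
    out = out * mask[:, :, None]
    return out, alpha


def _topk_pool_t(h: Tensor, adj: np.ndarray, mask: np.ndarray,
                 model: CellLineModel, stage: int):
    """Batched TopK pooling: keep ceil(ratio*n) atoms by learned score, gate
    kept features by tanh of the normalised score; ties keep lower indices."""
    enc = model.config.encoder
    ratio = enc.pool_ratio
    p = model.params[f"pool{stage}.p"]
    B, n, d = h.shape
    norm = ((p * p).sum() + 1e-12) ** 0.5
    s = (h @ p.reshape(d, 1)).reshape(B, n) * norm.reciprocal()  # (B, n)

    masked_scores = np.where(mask > 0, s.data, -np.inf)
    order = np.argsort(-masked_scores, axis=1, kind="stable")    # ties -> lower index
    n_valid = mask.sum(axis=1).astype(int)
    k_each = np.maximum(1, np.ceil(ratio * n_valid).astype(int))
    k_max = int(k_each.max())
    idx = order[:, :k_max]
    new_mask = (np.arange(k_max)[None, :] < k_each[:, None]).astype(np.float64)

    gate = s.reshape(B, n, 1).gather_nodes(idx).tanh()
    kept = h.gather_nodes(idx) * gate * new_mask[:, :, None]

    b_ix = np.arange(B)[:, None, None]
    new_adj = adj[b_ix, idx[:, :, None], idx[:, None, :]]
    new_adj *= new_mask[:, :, None] * new_mask[:, None, :]
    return kept, new_adj, new_mask, idx


def _masked_readout(h: Tensor, mask: np.ndarray) -> Tensor:
    counts = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    mean = (h * mask[:, :, None]).sum(axis=1) * (1.0 / counts)
    mx = (h + (mask[:, :, None] - 1.0) * 1e9).amax(axis=1)
    return concat([mean, mx], axis=-1)


def _encode_drugs_t(graphs: list[MolecularGraph], model: CellLineModel,
                    collect_attention: bool = False):
    """Batched drug encoder.  Returns (drug vectors (B,d), attention records).

    Attention records are per-stage lists of (alpha (B,H,n,n), element index
    array (B,n), mask (B,n)) describing the graph each GAT layer saw.
    """
    onehot, adj, mask = _pad_graphs(graphs)
    elements = onehot.argmax(axis=-1)  # meaningless on padded rows; mask guards
    h = _embed_atoms_t(onehot, model) * mask[:, :, None]
    enc = model.config.encoder
    readouts, attn_records = [], []
    cur_elements = elements
    for s in range(enc.n_stages):
        adj_self = _with_self_loops(adj, mask)
        h, alpha = _gat_stage_t(h, adj_self, mask, model, s)
        if collect_attention:
            attn_records.append((alpha.data, cur_elements, mask.copy()))
        h, adj, mask, idx = _topk_pool_t(h, adj, mask, model, s)
        cur_elements = np.take_along_axis(cur_elements, idx, axis=1)
        readouts.append(_masked_readout(h, mask))
    multi = concat(readouts, axis=-1)
    d_vec = multi @ model.params["drug_proj.W"] + model.params["drug_proj.b"]
    return d_vec, attn_records


def _project_genes_t(vectors, model: CellLineModel) -> Tensor:
    v = vectors if isinstance(vectors, Tensor) else Tensor(vectors)
    h = (v @ model.params["gene_proj.W1"] + model.params["gene_proj.b1"]).relu()
    return h @ model.params["gene_proj.W2"] + model.params["gene_proj.b2"]


def _interfusion_block_t(x: Tensor, model: CellLineModel, block: int):
    """One pre-LN transformer block on (P, 2, d).  Returns (out, attention)."""
    inter = model.config.interfusion
    P, T, d = x.shape
    H, dk = inter.heads, inter.d_k
    pm = model.params
    pre = layer_norm(x) * pm[f"blk{block}.ln1.g"] + pm[f"blk{block}.ln1.b"]
    x4 = pre.reshape(P, 1, T, d)
    q = x4 @ pm[f"blk{block}.Wq"]     # (P, H, T, dk)
    k = x4 @ pm[f"blk{block}.Wk"]
    v = x4 @ pm[f"blk{block}.Wv"]
    attn = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk)), axis=-1)
    heads = (attn @ v).swapaxes(1, 2).reshape(P, T, H * dk)
    x_o = heads @ pm[f"blk{block}.Wo"]
    x1 = x + x_o
    pre2 = layer_norm(x1) * pm[f"blk{block}.ln2.g"] + pm[f"blk{block}.ln2.b"]
    ffn = (pre2 @ pm[f"blk{block}.ffn.W1"] + pm[f"blk{block}.ffn.b1"]).relu()
    ffn = ffn @ pm[f"blk{block}.ffn.W2"] + pm[f"blk{block}.ffn.b2"]
    return x1 + ffn, attn


def _score_pairs_t(g_vec: Tensor, d_vec: Tensor, model: CellLineModel) -> Tensor:
    """Interaction scores for aligned gene/drug vector batches (P, d) -> (P,)."""
    P, d = g_vec.shape
    x = concat([g_vec.reshape(P, 1, d), d_vec.reshape(P, 1, d)], axis=1)
    for i in range(model.config.interfusion.n_blocks):
        x, _ = _interfusion_block_t(x, model, i)
    flat = x.reshape(P, 2 * d)
    h = (flat @ model.params["head.W1"] + model.params["head.b1"]).relu()
    return (h @ model.params["head.W2"] + model.params["head.b2"]).tanh().reshape(P)


# ---------------------------------------------------------------------------
# public single-input operations
# ---------------------------------------------------------------------------

def embed_atoms(one_hot: np.ndarray, model: CellLineModel) -> np.ndarray:
    """Shared element embedding applied to a one-hot matrix (n, 14) -> (n, d)."""
    one_hot = np.asarray(one_hot, dtype=np.float64)
    if one_hot.ndim != 2 or one_hot.shape[1] != N_ELEMENTS:
        raise ValueError(f"expected (n, {N_ELEMENTS}) one-hot matrix, got {one_hot.shape}")
    return _embed_atoms_t(one_hot, model).data


def gatv2_layer(features: np.ndarray, edges, model: CellLineModel, stage: int = 0):
    """One GATv2 layer on a single graph.

    Returns (updated features (n, d), attention (heads, n, n)); attention row
    i sums to 1 over N(i) plus the implicit self-loop.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a non-empty (n, d) matrix")
    n = features.shape[0]
    adj = np.zeros((1, n, n))
    for i, j in edges:
        adj[0, i, j] = adj[0, j, i] = 1.0
    mask = np.ones((1, n))
    out, alpha = _gat_stage_t(Tensor(features[None]), _with_self_loops(adj, mask),
                              mask, model, stage)
    return out.data[0], alpha.data[0]


def topk_pool(features: np.ndarray, edges, model: CellLineModel, stage: int = 0,
              ratio: float | None = None):
    """TopK pooling on a single graph: (kept features, kept edges, kept indices)."""
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if ratio is not None and not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    enc = model.config.encoder
    eff_model = model
    if ratio is not None and ratio != enc.pool_ratio:
        # transient view with the requested ratio
        import copy
        eff_model = copy.copy(model)
        eff_model.config = ModelConfig(
            encoder=DrugEncoderConfig(
                atom_embed_dim=enc.atom_embed_dim, gat_heads=enc.gat_heads,
                gat_head_dim=enc.gat_head_dim, pool_ratio=ratio,
                n_stages=enc.n_stages, leaky_slope=enc.leaky_slope),
            interfusion=model.config.interfusion, gene_dim=model.config.gene_dim)
    adj = np.zeros((1, n, n))
    for i, j in edges:
        adj[0, i, j] = adj[0, j, i] = 1.0
    kept, new_adj, new_mask, idx = _topk_pool_t(
        Tensor(features[None]), adj, np.ones((1, n)), eff_model, stage)
    k = int(new_mask[0].sum())
    kept_idx = idx[0, :k]
    kept_edges = [(i, j) for i in range(k) for j in range(i + 1, k) if new_adj[0, i, j] > 0]
    return kept.data[0, :k], kept_edges, kept_idx


def encode_drug(graph: MolecularGraph, model: CellLineModel) -> np.ndarray:
    """Encode one molecule into the d-dimensional common space."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    d_vec, _ = _encode_drugs_t([graph], model)
    return d_vec.data[0]


def project_gene(embedding: np.ndarray, model: CellLineModel) -> np.ndarray:
    """Project one 128-d gene vector into the d-dimensional common space."""
    embedding = np.asarray(embedding, dtype=np.float64)
    if embedding.shape != (model.config.gene_dim,):
        raise ValueError(f"expected ({model.config.gene_dim},) gene vector, got {embedding.shape}")
    return _project_genes_t(embedding[None], model).data[0]


def interfusion_block(x: np.ndarray, model: CellLineModel, block: int = 0) -> np.ndarray:
    """Apply one interfusion block to a single (2, d) token stack."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (2, model.config.interfusion.d):
        raise ValueError(f"expected (2, {model.config.interfusion.d}) input, got {x.shape}")
    out, _ = _interfusion_block_t(Tensor(x[None]), model, block)
    return out.data[0]


def interfusion_attention(x: np.ndarray, model: CellLineModel, block: int = 0) -> np.ndarray:
    """Attention matrices (heads, 2, 2) of one block for a single token stack."""
    x = np.asarray(x, dtype=np.float64)
    _, attn = _interfusion_block_t(Tensor(x[None]), model, block)
    return attn.data[0]


def predict_score(g_vec: np.ndarray, d_vec: np.ndarray, model: CellLineModel) -> float:
    """Interaction score S in (-1, 1) for one (gene, drug) vector pair."""
    g_vec = np.asarray(g_vec, dtype=np.float64)
    d_vec = np.asarray(d_vec, dtype=np.float64)
    if not (np.all(np.isfinite(g_vec)) and np.all(np.isfinite(d_vec))):
        raise ValueError("predict_score requires finite inputs")
    d = model.config.interfusion.d
    if g_vec.shape != (d,) or d_vec.shape != (d,):
        raise ValueError(f"expected ({d},) vectors")
    return float(_score_pairs_t(Tensor(g_vec[None]), Tensor(d_vec[None]), model).data[0])


def predict_pairs(model: CellLineModel, graphs: list[MolecularGraph],
                  gene_vectors: np.ndarray,
                  drug_index: np.ndarray | None = None,
                  gene_index: np.ndarray | None = None) -> np.ndarray:
    """Forward pass for many (drug, gene) pairs without gradients.

    ``graphs`` and ``gene_vectors`` list the unique drugs/genes; ``drug_index``
    and ``gene_index`` (same length P) select the pairing.  When omitted the
    inputs are assumed aligned.
    """
    d_unique, _ = _encode_drugs_t(graphs, model)
    g_unique = _project_genes_t(np.asarray(gene_vectors, dtype=np.float64), model)
    d_vec = d_unique if drug_index is None else d_unique.take0(np.asarray(drug_index))
    g_vec = g_unique if gene_index is None else g_unique.take0(np.asarray(gene_index))
    return _score_pairs_t(g_vec, d_vec, model).data
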