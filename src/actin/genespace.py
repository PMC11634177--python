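"""Gene embeddings from a PPI network via node2vec.

Landmark genes are represented by 128-dimensional vectors learned from an
undirected protein-protein interaction network: biased second-order random
walks (return parameter p, in-out parameter q) are fed to skip-gram training
with negative sampling, exactly the node2vec recipe.  Genes that interact
(directly or through shared neighbourhoods) end up close in embedding space,
which gives the downstream model a meaningful notion of gene-gene distance
instead of an arbitrary one-hot code.

The trainer is a compact numpy implementation (the walk corpus for a
~1000-node network is small); tables can also be loaded from TSV when
precomputed embeddings exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np


class DisconnectedGraphError(ValueError):
    """Raised when the PPI graph is not connected."""


class EmbeddingFormatError(ValueError):
    """Raised for malformed embedding tables."""


@dataclass(frozen=True)
class GeneEmbeddingTable:
    """gene_id -> fixed-length real vector."""

    gene_ids: tuple
    vectors: np.ndarray  # (n_genes, dim)
    source: str = "trained"

    def __post_init__(self):
        if len(self.gene_ids) != self.vectors.shape[0]:
            raise ValueError("gene_ids / vectors length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise EmbeddingFormatError("duplicate gene_ids in embedding table")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.gene_ids)})

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def vector(self, gene_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in embedding table") from None


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _random_walks(adj, rng, walk_length, walks_per_node, p, q):
    """node2vec walks over sorted adjacency lists (indices)."""
    n = len(adj)
    neighbour_sets = [set(a.tolist()) for a in adj]
    walks = []
    order = np.arange(n)
    for _ in range(walks_per_node):
        rng.shuffle(order)
        for start in order:
            walk = [int(start)]
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if len(nbrs) == 0:
                    break
                if len(walk) == 1 or (p == 1.0 and q == 1.0):
                    nxt = int(nbrs[rng.integers(len(nbrs))])
                else:
                    prev = walk[-2]
                    prev_nbrs = neighbour_sets[prev]
                    weights = np.array(
                        [1.0 / p if x == prev else (1.0 if x in prev_nbrs else 1.0 / q)
                         for x in nbrs]
                    )
                    weights /= weights.sum()
                    nxt = int(nbrs[rng.choice(len(nbrs), p=weights)])
                walk.append(nxt)
            walks.append(walk)
    return walks


def node2vec_embed(
    edges,
    dim: int = 128,
    walk_length: int = 80,
    walks_per_node: int = 10,
    window: int = 5,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    giant_component: bool = False,
) -> GeneEmbeddingTable:
    """Train node2vec embeddings for every node of an undirected edge list.

    The graph must be connected; with ``giant_component=True`` a disconnected
    input is reduced to its largest component instead of raising.
    Deterministic for a fixed seed and invariant to edge-list row order.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    g = nx.Graph()
    g.add_edges_from((str(a), str(b)) for a, b in edges)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 connected nodes")
    if not nx.is_connected(g):
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        if giant_component:
            g = g.subgraph(max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))).copy()
        else:
            raise DisconnectedGraphError(
                f"PPI graph has {len(comps)} components (sizes {comps[:10]}); "
                "pass giant_component=True to embed the largest only"
            )

    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj = [np.array(sorted(index[u] for u in g.neighbors(v)), dtype=np.int64) for v in nodes]

    rng = np.random.default_rng(seed)
    walks = _random_walks(adj, rng, walk_length, walks_per_node, p, q)

    # skip-gram pairs within the context window
    centers, contexts = [], []
    for walk in walks:
        w = np.asarray(walk, dtype=np.int64)
        for k in range(1, window + 1):
            if len(w) > k:
                centers.append(w[:-k]); contexts.append(w[k:])
                centers.append(w[k:]); contexts.append(w[:-k])
    centers = np.concatenate(centers)
    contexts = np.concatenate(contexts)

    n = len(nodes)
    counts = np.bincount(centers, minlength=n).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()
    noise_cum = np.cumsum(noise)

    w_in = (rng.random((n, dim)) - 0.5) / dim
    w_out = np.zeros((n, dim))

    # small batches keep the stale-gradient accumulation for hub nodes well
    # inside the stable regime (large batches diverge on scale-free graphs);
    # on tiny graphs the batch must shrink with the node count
    batch = int(min(512, max(64, 4 * n)))
    n_batches_total = epochs * (len(centers) + batch - 1) // batch
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(len(centers))
        for lo in range(0, len(perm), batch):
            ix = perm[lo:lo + batch]
            c, o = centers[ix], contexts[ix]
            neg = np.searchsorted(noise_cum, rng.random((len(ix), negative)))
            neg = np.minimum(neg, n - 1)
            cur_lr = max(1e-4, lr * (1.0 - step / max(1, n_batches_total)))
            step += 1

            v = w_in[c]                             # (B, dim)
            g_pos = _sigmoid(np.sum(v * w_out[o], axis=1)) - 1.0        # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, w_out[neg]))    # (B, k)

            d_v = g_pos[:, None] * w_out[o] + np.einsum("bk,bkd->bd", g_neg, w_out[neg])
            clip = 0.5  # guards the stale-gradient feedback loop on hub nodes
            np.add.at(w_in, c, np.clip(-cur_lr * d_v, -clip, clip))
            np.add.at(w_out, o, np.clip(-cur_lr * g_pos[:, None] * v, -clip, clip))
            np.add.at(w_out, neg, np.clip(-cur_lr * g_neg[..., None] * v[:, None, :],
                                          -clip, clip))

    return GeneEmbeddingTable(gene_ids=tuple(nodes), vectors=w_in, source="trained")


def read_embedding_table(path) -> GeneEmbeddingTable:
    """Read a TSV with header ``gene_id e1 .. eD``; strict about shape."""
    lines = [l for l in Path(path).read_text().splitlines()]
    rows = [(i + 1, l) for i, l in enumerate(lines) if l.strip()]
    if not rows:
        raise EmbeddingFormatError(f"{path}: empty embedding table")
    header = rows[0][1].split("\t")
    if header[0] != "gene_id" or len(header) < 3:
        raise EmbeddingFormatError(f"{path}:1: expected header 'gene_id\\te1\\t...\\teD'")
    dim = len(header) - 1
    ids, vecs, seen = [], [], set()
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != dim + 1:
            raise EmbeddingFormatError(
                f"{path}:{lineno}: expected {dim + 1} columns, got {len(parts)}"
            )
        gid = parts[0]
        if gid in seen:
            raise EmbeddingFormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
        seen.add(gid)
        ids.append(gid)
        vecs.append([float(x) for x in parts[1:]])
    if not ids:
        raise EmbeddingFormatError(f"{path}: no data rows")
    return GeneEmbeddingTable(gene_ids=tuple(ids), vectors=np.asarray(vecs), source="loaded")


def write_embedding_table(table: GeneEmbeddingTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(f"e{i + 1}" for i in range(table.dim)) + "\n")
        for gid, vec in zip(table.gene_ids, table.vectors):
            fh.write(gid + "\t" + "\t".join(f"{x:.12g}" for x in vec) + "\n")
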