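"""Per-cell-line training on paired single-drug / single-gene samples.

Every perturbation record becomes one training sample: (molecular graph,
gene vector) -> SF(logFC).  Samples are split at the level of perturbation
instances (one drug treatment of one cell line), so all genes measured under
one treatment share a fold and no drug leaks between train and test.  Models
are trained with the smooth-L1 loss by mini-batch gradient descent (Adam);
each cell line gets its own independently trained model, with identical
hyperparameters across cell lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import model as M
from .autodiff import Tensor
from .chemgraph import MolecularGraph, SmilesParseError, parse_smiles
from .expression import DEFAULT_SF, ExpressionLabel, StepFunctionParams, label, step_function
from .genespace import GeneEmbeddingTable
from .io import PerturbationRecord

__all__ = [
    "PairSample", "SplitSpec", "TrainConfig", "TrainingHistory",
    "build_pairs", "split_instances", "smooth_l1", "train_cell_line",
]


@dataclass(frozen=True)
class PairSample:
    """One (drug, gene) regression sample."""

    drug_id: str
    gene_id: str
    cell_line: str
    graph: MolecularGraph
    gene_vector: np.ndarray
    logFC: float
    target: float              # SF(logFC)
    true_label: ExpressionLabel

    @property
    def instance_id(self) -> tuple:
        return (self.drug_id, self.cell_line)


@dataclass(frozen=True)
class SplitSpec:
    """Instance-level split; fractions must sum to 1."""

    fractions: tuple = (0.8, 0.2)
    seed: int = 0

    def __post_init__(self):
        if len(self.fractions) not in (2, 3):
            raise ValueError("fractions must be (train, test) or (train, val, test)")
        if abs(sum(self.fractions) - 1.0) > 1e-9 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative and sum to 1")

    @property
    def fold_names(self) -> tuple:
        return ("train", "test") if len(self.fractions) == 2 else ("train", "val", "test")


def build_pairs(
    records: list[PerturbationRecord],
    embeddings: GeneEmbeddingTable,
    sf_params: StepFunctionParams = DEFAULT_SF,
) -> list[PairSample]:
    """Turn perturbation records into paired samples; count is preserved."""
    missing_genes = sorted({r.gene_id for r in records if r.gene_id not in embeddings})
    if missing_genes:
        raise KeyError(f"gene(s) missing from embedding table: {', '.join(missing_genes[:20])}")
    graphs: dict[str, MolecularGraph] = {}
    bad_drugs = []
    for r in records:
        if r.drug_id not in graphs:
            try:
                graphs[r.drug_id] = parse_smiles(r.smiles)
            except (SmilesParseError, ValueError):
                bad_drugs.append(r.drug_id)
    if bad_drugs:
        raise SmilesParseError(f"unparseable SMILES for drug(s): {', '.join(sorted(bad_drugs)[:20])}")
    return [
        PairSample(
            drug_id=r.drug_id, gene_id=r.gene_id, cell_line=r.cell_line,
            graph=graphs[r.drug_id], gene_vector=embeddings.vector(r.gene_id),
            logFC=r.logFC, target=float(step_function(r.logFC, sf_params)),
            true_label=label(r.logFC, sf_params.threshold),
        )
        for r in records
    ]


def split_instances(instances, spec: SplitSpec) -> dict:
    """Deterministic instance-level fold assignment.

    All folds but the last get floor(fraction * n) instances; the last fold
    takes the remainder.
    """
    instances = list(dict.fromkeys(instances))  # unique, order-preserving
    if not instances:
        raise ValueError("cannot split an empty instance list")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(instances))
    sizes = [math.floor(f * len(instances)) for f in spec.fractions[:-1]]
    sizes.append(len(instances) - sum(sizes))
    if any(s < 1 and f > 0 for s, f in zip(sizes, spec.fractions)):
        raise ValueError("a requested non-empty fold received no instances")
    assignment = {}
    pos = 0
    for fold, size in zip(spec.fold_names, sizes):
        for k in order[pos:pos + size]:
            assignment[instances[k]] = fold
        pos += size
    return assignment


def smooth_l1(pred, target, beta: float = 1.0) -> float:
    """Mean smooth-L1 loss: 0.5 e^2 / beta for |e| < beta, else |e| - beta/2."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    e = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    if not np.all(np.isfinite(e)):
        raise ValueError("smooth_l1 requires finite inputs")
    ae = np.abs(e)
    return float(np.mean(np.where(ae < beta, 0.5 * e * e / beta, ae - 0.5 * beta)))


def _smooth_l1_t(pred: Tensor, target: np.ndarray, beta: float) -> Tensor:
    """Differentiable batch-mean smooth-L1 (branch mask is constant w.r.t. grad)."""
    e = pred - target
    ae_data = np.abs(e.data)
    quad = (ae_data < beta).astype(np.float64)
    loss = (e * e) * (0.5 / beta) * quad + (e.abs() - 0.5 * beta) * (1.0 - quad)
    return loss.mean()


@dataclass
class TrainConfig:
    batch_size: int = 1000
    epochs: int = 50
    lr: float = 1e-3
    patience: int = 10
    seed: int = 0
    beta: float = 1.0
    split: SplitSpec = field(default_factory=SplitSpec)
    sf_params: StepFunctionParams = field(default_factory=StepFunctionParams)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)   # per-epoch dicts
    folds: dict = field(default_factory=dict)    # instance_id -> fold name


class Adam:
    """Standard Adam over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _PairDataset:
    """Index-based view of pair samples over unique drugs and genes."""

    def __init__(self, pairs: list[PairSample]):
        self.pairs = pairs
        drug_ids = list(dict.fromkeys(p.drug_id for p in pairs))
        gene_ids = list(dict.fromkeys(p.gene_id for p in pairs))
        d_ix = {d: i for i, d in enumerate(drug_ids)}
        g_ix = {g: i for i, g in enumerate(gene_ids)}
        by_drug, by_gene = {}, {}
        for p in pairs:
            by_drug.setdefault(p.drug_id, p.graph)
            by_gene.setdefault(p.gene_id, p.gene_vector)
        self.graphs = [by_drug[d] for d in drug_ids]
        self.gene_vectors = np.stack([by_gene[g] for g in gene_ids])
        self.drug_index = np.array([d_ix[p.drug_id] for p in pairs])
        self.gene_index = np.array([g_ix[p.gene_id] for p in pairs])
        self.targets = np.array([p.target for p in pairs])


def _forward_batch(model: M.CellLineModel, ds: _PairDataset, sel: np.ndarray) -> Tensor:
    d_sel = ds.drug_index[sel]
    g_sel = ds.gene_index[sel]
    used_drugs = np.unique(d_sel)
    remap = np.zeros(len(ds.graphs), dtype=int)
    remap[used_drugs] = np.arange(len(used_drugs))
    d_unique, _ = M._encode_drugs_t([ds.graphs[i] for i in used_drugs], model)
    g_unique = M._project_genes_t(ds.gene_vectors, model)
    return M._score_pairs_t(g_unique.take0(g_sel), d_unique.take0(remap[d_sel]), model)


def predict_dataset(model: M.CellLineModel, pairs: list[PairSample],
                    chunk: int = 4000) -> np.ndarray:
    """Scores for a list of pair samples (no gradient bookkeeping kept)."""
    ds = _PairDataset(pairs)
    out = np.empty(len(pairs))
    for lo in range(0, len(pairs), chunk):
        sel = np.arange(lo, min(lo + chunk, len(pairs)))
        out[sel] = _forward_batch(model, ds, sel).data
    return out


def train_cell_line(
    records: list[PerturbationRecord],
    embeddings: GeneEmbeddingTable,
    model_config: M.ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[M.CellLineModel, TrainingHistory]:
    """Train one model on the records of a single cell line.

    Returns the trained model and a history carrying per-epoch losses and the
    instance-level fold assignment used (so evaluation can address the held
    out fold).  Early stopping on validation loss applies when the split has
    a validation fold; the best-validation parameters are restored.
    """
    model_config = model_config or M.ModelConfig()
    train_config = train_config or TrainConfig()

    cell_lines = sorted({r.cell_line for r in records})
    if len(cell_lines) != 1:
        raise ValueError(f"records span multiple cell lines: {cell_lines}")

    pairs = build_pairs(records, embeddings, train_config.sf_params)
    spec = SplitSpec(train_config.split.fractions, seed=train_config.seed)
    folds = split_instances([p.instance_id for p in pairs], spec)
    by_fold: dict[str, list[PairSample]] = {name: [] for name in spec.fold_names}
    for p in pairs:
        by_fold[folds[p.instance_id]].append(p)

    model = M.CellLineModel(cell_lines[0], model_config, seed=train_config.seed)
    ds = _PairDataset(by_fold["train"])
    val_pairs = by_fold.get("val", [])
    opt = Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(train_config.seed + 1)

    history = TrainingHistory(folds=dict(folds))
    best_val, best_state, patience_left = np.inf, None, train_config.patience
    n_train = len(ds.pairs)
    for epoch in range(train_config.epochs):
        perm = rng.permutation(n_train)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n_train, train_config.batch_size):
            sel = perm[lo:lo + train_config.batch_size]
            model.zero_grad()
            pred = _forward_batch(model, ds, sel)
            loss = _smooth_l1_t(pred, ds.targets[sel], train_config.beta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {n_batches}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches),
                 "lr": train_config.lr, "seed": train_config.seed}
        if val_pairs:
            val_pred = predict_dataset(model, val_pairs)
            val_loss = smooth_l1(val_pred, [p.target for p in val_pairs], train_config.beta)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: t.data.copy() for k, t in model.params.items()}
                patience_left = train_config.patience
            else:
                patience_left -= 1
        history.epochs.append(entry)
        model.metadata["epochs_trained"] = epoch + 1
        if val_pairs and patience_left <= 0:
            break
    if best_state is not None:
        for k, t in model.params.items():
            t.data = best_state[k]
    return model, history
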