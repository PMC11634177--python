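"""Pair construction, instance splits, smooth-L1 and the training loop."""

import numpy as np
import pytest

from actin.autodiff import Tensor
from actin.chemgraph import SmilesParseError
from actin.genespace import GeneEmbeddingTable
from actin.io import PerturbationRecord
from actin.model import ModelConfig
from actin.training import (
    SplitSpec,
    TrainConfig,
    _smooth_l1_t,
    build_pairs,
    predict_dataset,
    smooth_l1,
    split_instances,
    train_cell_line,
)


def _records(n_drugs=3, n_genes=5, cell_line="CL"):
    return [
        PerturbationRecord(f"d{d}", "CCO", cell_line, f"g{g}", 0.1 * d - 0.2 * g)
        for d in range(n_drugs) for g in range(n_genes)
    ]


def _table(n_genes=5, dim=16):
    rng = np.random.default_rng(0)
    return GeneEmbeddingTable(tuple(f"g{g}" for g in range(n_genes)),
                              rng.normal(size=(n_genes, dim)))


def test_build_pairs_preserves_count_and_targets():
    pairs = build_pairs(_records(), _table())
    assert len(pairs) == 15
    zero = [p for p in pairs if p.logFC == 0.0]
    assert all(p.target == 0.0 for p in zero)


def test_build_pairs_missing_gene_named():
    with pytest.raises(KeyError, match="g4"):
        build_pairs(_records(n_genes=5), _table(n_genes=4))


def test_build_pairs_bad_smiles_named():
    recs = _records() + [PerturbationRecord("dBad", "not_smiles(", "CL", "g0", 0.0)]
    with pytest.raises(SmilesParseError, match="dBad"):
        build_pairs(recs, _table())


def test_split_492_instances_at_80_20_gives_393_train():
    folds = split_instances([f"i{k}" for k in range(492)],
                            SplitSpec((0.8, 0.2), seed=0))
    counts = {f: sum(v == f for v in folds.values()) for f in ("train", "test")}
    assert counts == {"train": 393, "test": 99}


def test_split_exact_fractions_three_fold():
    folds = split_instances(list(range(10)), SplitSpec((0.6, 0.2, 0.2), seed=1))
    counts = {f: sum(v == f for v in folds.values()) for f in ("train", "val", "test")}
    assert counts == {"train": 6, "val": 2, "test": 2}


def test_split_deterministic_and_seed_sensitive():
    items = list(range(50))
    a = split_instances(items, SplitSpec((0.8, 0.2), seed=3))
    b = split_instances(items, SplitSpec((0.8, 0.2), seed=3))
    c = split_instances(items, SplitSpec((0.8, 0.2), seed=4))
    assert a == b and a != c


def test_split_rejects_empty_and_bad_fractions():
    with pytest.raises(ValueError):
        split_instances([], SplitSpec((0.8, 0.2)))
    with pytest.raises(ValueError):
        SplitSpec((0.5, 0.2))


@pytest.mark.parametrize("pred,target,beta,expected", [
    (1.0, 1.0, 1.0, 0.0),
    (1.0, 0.5, 1.0, 0.125),   # 0.5 e^2
    (2.0, 0.0, 1.0, 1.5),     # |e| - 0.5
    (0.3, 0.0, 0.5, 0.09),    # 0.5 * 0.09 / 0.5
])
def test_smooth_l1_closed_forms(pred, target, beta, expected):
    assert smooth_l1(pred, target, beta) == pytest.approx(expected, abs=1e-12)


def test_smooth_l1_batch_mean_and_validation():
    assert smooth_l1([1.0, 2.0], [1.0, 0.0], 1.0) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        smooth_l1(1.0, 0.0, beta=0.0)
    with pytest.raises(ValueError):
        smooth_l1(float("nan"), 0.0)


def test_smooth_l1_gradient_matches_numeric():
    rng = np.random.default_rng(4)
    pred = rng.normal(size=20)
    target = rng.normal(size=20)
    t = Tensor(pred.copy(), requires_grad=True)
    _smooth_l1_t(t, target, 1.0).backward()
    num = np.empty(20)
    for i in range(20):
        eps = 1e-6
        p = pred.copy(); p[i] += eps
        m = pred.copy(); m[i] -= eps
        num[i] = (smooth_l1(p, target) - smooth_l1(m, target)) / (2 * eps)
    np.testing.assert_allclose(t.grad, num, atol=1e-5)


def _train_tiny(records, table, **overrides):
    kwargs = dict(batch_size=50, epochs=4, lr=3e-3, seed=0,
                  split=SplitSpec((0.8, 0.2), seed=0))
    kwargs.update(overrides)
    return train_cell_line(records, table,
                           ModelConfig.reduced(d=16, d_k=4, heads=4, n_blocks=1,
                                               n_stages=1, gene_dim=16),
                           TrainConfig(**kwargs))


def test_training_reduces_loss_on_planted_data(tiny_dataset, tiny_gene_table):
    _, _, records = tiny_dataset
    table = GeneEmbeddingTable(tiny_gene_table.gene_ids, tiny_gene_table.vectors)
    model, hist = _train_tiny(records, table)
    losses = [e["train_loss"] for e in hist.epochs]
    assert losses[-1] < losses[0]
    assert model.metadata["epochs_trained"] == len(hist.epochs)


def test_batch_larger_than_dataset_is_one_batch(tiny_dataset, tiny_gene_table):
    _, _, records = tiny_dataset
    model, hist = _train_tiny(records, tiny_gene_table, batch_size=10_000, epochs=2)
    assert len(hist.epochs) == 2


def test_training_is_deterministic(tiny_dataset, tiny_gene_table):
    _, _, records = tiny_dataset
    _, h1 = _train_tiny(records, tiny_gene_table, epochs=2)
    _, h2 = _train_tiny(records, tiny_gene_table, epochs=2)
    assert h1.epochs == h2.epochs


def test_mixed_cell_lines_rejected(tiny_gene_table):
    records = [PerturbationRecord("d1", "CCO", "A", "g0001", 0.0),
               PerturbationRecord("d1", "CCO", "B", "g0001", 0.0)]
    with pytest.raises(ValueError, match="multiple cell lines"):
        train_cell_line(records, tiny_gene_table)


def test_validation_fold_enables_early_stopping(tiny_dataset, tiny_gene_table):
    _, _, records = tiny_dataset
    model, hist = _train_tiny(records, tiny_gene_table, epochs=6, patience=1,
                              split=SplitSpec((0.6, 0.2, 0.2), seed=0))
    assert all("val_loss" in e for e in hist.epochs)
    assert len(hist.epochs) <= 6


def test_predict_dataset_matches_training_forward(tiny_dataset, tiny_gene_table):
    _, _, records = tiny_dataset
    model, hist = _train_tiny(records, tiny_gene_table, epochs=1)
    pairs = build_pairs(records, tiny_gene_table)
    preds = predict_dataset(model, pairs)
    assert preds.shape == (len(pairs),)
    assert np.all(np.abs(preds) < 1)
    np.testing.assert_array_equal(preds, predict_dataset(model, pairs))
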