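"""Interpretability analyses: element-embedding disparity and attention
importance.

Two post-hoc procedures probe what a family of per-cell-line models learned
about chemistry:

* **Element disparity** — each model maps the 14 element one-hots through its
  atom embedding, giving a 14 x d matrix per model.  All models' matrices are
  stacked, reduced by PCA (256 -> 128 by default), and for every element the
  per-component range (max - min across models) and standard deviation across
  models are computed.  Summing over components gives one cumulative
  range/SD per element; elements are ranked descending, and a large value
  means the element's learned representation differs strongly between cell
  lines — a cell-line-specific pharmacophore signal.
* **Attention element importance** — for a single model, GATv2 attention
  coefficients are accumulated over a probe molecule library, grouping the
  incoming attention mass by the source atom's element, per attention head.
  Each head's masses are normalised to fractions summing to 1; the mean over
  heads is appended.  A dominant fraction marks the element the encoder
  attends to when predicting expression changes in that cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from . import model as M
from .chemgraph import VOCABULARY, MolecularGraph


def extract_element_embeddings(model: M.CellLineModel) -> np.ndarray:
    """Per-element learned embeddings: the atom map applied to the 14 unit
    one-hots, rows in vocabulary order; shape (14, d)."""
    return M.embed_atoms(np.eye(M.N_ELEMENTS), model)


def reduce_pca(stacked: np.ndarray, n_components: int = 128):
    """PCA on the row-stacked element embeddings.

    ``n_components`` is clipped to min(requested, n_rows - 1, n_cols).
    Returns (reduced matrix, explained-variance fractions).
    """
    stacked = np.asarray(stacked, dtype=np.float64)
    if stacked.ndim != 2 or stacked.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    k = min(n_components, stacked.shape[0] - 1, stacked.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(stacked)
    return reduced, pca.explained_variance_ratio_


@dataclass
class ElementDisparityReport:
    """Cross-model variability of element embeddings in PCA space."""

    elements: tuple                 # vocabulary order
    n_components: int
    per_component_range: np.ndarray  # (14, k): max - min across models
    per_component_sd: np.ndarray     # (14, k): sd across models
    cumulative_range: np.ndarray     # (14,)
    cumulative_sd: np.ndarray        # (14,)
    ranking: tuple                   # elements by descending cumulative range
    ranking_by_sd: tuple
    top_k: int

    @property
    def top_elements(self) -> tuple:
        return self.ranking[: self.top_k]


def disparity_report(models, n_components: int = 128, top_k: int = 5) -> ElementDisparityReport:
    """Element-embedding disparity across a family of cell-line models."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("disparity needs at least 2 models")
    mats = [extract_element_embeddings(m) for m in models]
    stacked = np.vstack(mats)                       # (n_models*14, d)
    reduced, _ = reduce_pca(stacked, n_components)
    k = reduced.shape[1]
    cube = reduced.reshape(len(models), M.N_ELEMENTS, k)
    rng_ = cube.max(axis=0) - cube.min(axis=0)      # (14, k)
    sd = cube.std(axis=0)
    cum_range = np.abs(rng_).sum(axis=1)
    cum_sd = sd.sum(axis=1)
    order = np.argsort(-cum_range, kind="stable")
    order_sd = np.argsort(-cum_sd, kind="stable")
    return ElementDisparityReport(
        elements=VOCABULARY,
        n_components=k,
        per_component_range=rng_,
        per_component_sd=sd,
        cumulative_range=cum_range,
        cumulative_sd=cum_sd,
        ranking=tuple(VOCABULARY[i] for i in order),
        ranking_by_sd=tuple(VOCABULARY[i] for i in order_sd),
        top_k=top_k,
    )


@dataclass
class ElementImportanceTable:
    """Attention-head x element weight fractions (mean row appended last)."""

    elements: tuple
    fractions: np.ndarray    # (heads + 1, 14); each head row sums to 1
    heads: tuple             # e.g. ("AH1", ..., "AH4", "mean")
    stage: int

    def head_row(self, head: int) -> np.ndarray:
        return self.fractions[head]

    @property
    def mean_row(self) -> np.ndarray:
        return self.fractions[-1]

    def top_element(self, row: int = -1) -> str:
        return self.elements[int(np.argmax(self.fractions[row]))]


def attention_element_importance(
    model: M.CellLineModel,
    molecules,
    stage: int = 1,
    over_present_only: bool = True,
) -> ElementImportanceTable:
    """Per-head element importance from GATv2 attention over a molecule set.

    For every molecule and every atom i, the attention mass alpha_h(i, j)
    (self-loops included) is attributed to the element of the source atom j
    and accumulated per head, then normalised per head to sum to 1.  ``stage``
    selects the GATv2 layer (1-based; stage 1 sees raw chemistry).  With
    ``over_present_only`` the fractions are normalised over elements present
    in the probe set (absent elements have zero mass either way).
    """
    molecules = [m for m in molecules]
    if not molecules:
        raise ValueError("attention importance needs a non-empty molecule set")
    enc = model.config.encoder
    if not 1 <= stage <= enc.n_stages:
        raise ValueError(f"stage must be in 1..{enc.n_stages}")
    _, records = M._encode_drugs_t(molecules, model, collect_attention=True)
    alpha, elements, mask = records[stage - 1]       # (B,H,n,n), (B,n), (B,n)
    H = alpha.shape[1]
    pair_mask = mask[:, None, :, None] * mask[:, None, None, :]  # valid (i, j)
    masses = np.zeros((H, M.N_ELEMENTS))
    weighted = alpha * pair_mask                     # (B, H, n, n)
    per_source = weighted.sum(axis=2)                # (B, H, n): mass onto source j
    for e in range(M.N_ELEMENTS):
        sel = (elements == e) & (mask > 0)           # (B, n)
        masses[:, e] = (per_source * sel[:, None, :]).sum(axis=(0, 2))
    if over_present_only:
        present = masses.sum(axis=0) > 0
    else:
        present = np.ones(M.N_ELEMENTS, dtype=bool)
    masses = np.where(present[None, :], masses, 0.0)
    fractions = masses / masses.sum(axis=1, keepdims=True)
    table = np.vstack([fractions, fractions.mean(axis=0)])
    return ElementImportanceTable(
        elements=VOCABULARY,
        fractions=table,
        heads=tuple(f"AH{h + 1}" for h in range(H)) + ("mean",),
        stage=stage,
    )
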