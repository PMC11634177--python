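"""Signature-reversal drug screening.

Given a disease differential-expression signature (gene -> logFC, e.g.
derived from patient tissue), each library drug's predicted transcriptional
profile is scored for how strongly it *opposes* the signature — the standard
connectivity-map reversal convention: a drug predicted to push disease-raised
genes down and disease-suppressed genes up ranks highest.  The signature is
mapped through the same step function as the training targets so both
vectors live on the bounded (-1, 1) scale before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from . import model as M
from .chemgraph import MolecularGraph, parse_smiles
from .expression import DEFAULT_SF, StepFunctionParams, step_function
from .genespace import GeneEmbeddingTable


@dataclass(frozen=True)
class DiseaseSignature:
    """gene_id -> logFC differential-expression signature."""

    values: dict
    provenance: str = ""

    def __post_init__(self):
        for g, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite signature value for {g}")

    @property
    def gene_ids(self) -> tuple:
        return tuple(self.values)


def read_signature(path, provenance: str = "") -> DiseaseSignature:
    """Read a signature TSV with header gene_id / logFC."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or lines[0].split("\t")[:2] != ["gene_id", "logFC"]:
        raise ValueError(f"{path}: expected header 'gene_id\\tlogFC'")
    values: dict = {}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        if parts[0] in values:
            raise ValueError(f"{path}:{lineno}: duplicate gene_id {parts[0]!r}")
        values[parts[0]] = float(parts[1])
    return DiseaseSignature(values=values, provenance=provenance or str(path))


def predict_profile(model: M.CellLineModel, drug, genes: GeneEmbeddingTable,
                    gene_ids=None) -> np.ndarray:
    """Predicted interaction score for one drug against a list of genes.

    ``drug`` is a SMILES string or a parsed molecular graph; ``gene_ids``
    defaults to every gene in the table.  Missing genes raise with the
    offending ids listed.
    """
    graph = drug if isinstance(drug, MolecularGraph) else parse_smiles(drug)
    ids = list(gene_ids) if gene_ids is not None else list(genes.gene_ids)
    missing = [g for g in ids if g not in genes]
    if missing:
        raise KeyError(f"gene(s) missing from embedding table: {', '.join(missing[:20])}")
    vectors = np.stack([genes.vector(g) for g in ids])
    return M.predict_pairs(model, [graph], vectors,
                           drug_index=np.zeros(len(ids), dtype=int),
                           gene_index=np.arange(len(ids)))


def reversal_score(profile: np.ndarray, signature: DiseaseSignature, gene_ids,
                   sf_params: StepFunctionParams = DEFAULT_SF,
                   method: str = "pearson") -> float:
    """Anticorrelation between a predicted profile and the SF-mapped signature.

    +1 means the drug's predicted effect perfectly opposes the disease
    signature (reversal); -1 means it mimics it.  Only genes present in both
    the profile and the signature contribute; at least two overlapping genes
    with variance on both sides are required.
    """
    profile = np.asarray(profile, dtype=np.float64)
    gene_ids = list(gene_ids)
    if len(profile) != len(gene_ids):
        raise ValueError("profile and gene_ids must align")
    overlap = [(p, signature.values[g]) for p, g in zip(profile, gene_ids)
               if g in signature.values]
    if len(overlap) < 2:
        raise ValueError(f"only {len(overlap)} overlapping gene(s); need >= 2")
    pred = np.array([p for p, _ in overlap])
    sig = step_function(np.array([v for _, v in overlap]), sf_params)
    if np.std(pred) == 0 or np.std(sig) == 0:
        raise ValueError("zero variance on the gene overlap — reversal undefined")
    if method == "pearson":
        r = float(np.corrcoef(pred, sig)[0, 1])
    elif method == "spearman":
        r = float(spearmanr(pred, sig).statistic)
    elif method == "dot":
        r = float(pred @ sig / len(pred))
    else:
        raise ValueError("method must be 'pearson', 'spearman' or 'dot'")
    return -r


def rank_candidates(model: M.CellLineModel, library, genes: GeneEmbeddingTable,
                    signature: DiseaseSignature, top_k: int | None = None,
                    sf_params: StepFunctionParams = DEFAULT_SF,
                    method: str = "pearson") -> list[tuple[str, float]]:
    """Rank a drug library by reversal score, descending; ties by drug_id.

    ``library`` is a list of (drug_id, smiles) pairs.  Signature genes absent
    from the embedding table are simply not scored (they are outside the
    model's gene universe).
    """
    if not library:
        raise ValueError("empty drug library")
    gene_ids = [g for g in genes.gene_ids if g in signature.values]
    scored = []
    for drug_id, smiles in library:
        profile = predict_profile(model, smiles, genes, gene_ids)
        scored.append((drug_id, reversal_score(profile, signature, gene_ids,
                                               sf_params, method)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    if top_k is not None:
        scored = scored[: max(0, min(top_k, len(scored)))]
    return scored
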