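"""Tabular readers/writers and the perturbation record type.

All on-disk formats are UTF-8 TSV with '.' decimals: perturbation tables
(drug_id / smiles / cell_line / gene_id / logFC), PPI edge lists (two
gene_id columns, optional score column ignored) and disease signatures
(gene_id / logFC).  Gene and drug identifiers are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PERTURBATION_COLUMNS = ("drug_id", "smiles", "cell_line", "gene_id", "logFC")


class TableFormatError(ValueError):
    """Raised when a TSV input violates its format contract."""


@dataclass(frozen=True)
class PerturbationRecord:
    """One (drug, cell line, gene) observation with its log2 fold change."""

    drug_id: str
    smiles: str
    cell_line: str
    gene_id: str
    logFC: float

    def __post_init__(self):
        if not np.isfinite(self.logFC):
            raise ValueError(f"non-finite logFC for ({self.drug_id}, {self.gene_id})")


def read_perturbation_table(path) -> list[PerturbationRecord]:
    """Read a perturbation TSV; duplicates of (drug, cell_line, gene) are rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "smiles": str,
                                            "cell_line": str, "gene_id": str})
    missing = [c for c in PERTURBATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    dup_mask = df.duplicated(subset=["drug_id", "cell_line", "gene_id"], keep=False)
    if dup_mask.any():
        lines = [str(i + 2) for i in df.index[dup_mask][:10]]  # +2: header + 1-based
        raise TableFormatError(
            f"{path}: duplicate (drug_id, cell_line, gene_id) rows at line(s) {', '.join(lines)}"
        )
    return [
        PerturbationRecord(r.drug_id, r.smiles, r.cell_line, r.gene_id, float(r.logFC))
        for r in df.itertuples(index=False)
    ]


def write_perturbation_table(records, path) -> None:
    df = pd.DataFrame(
        [(r.drug_id, r.smiles, r.cell_line, r.gene_id, r.logFC) for r in records],
        columns=list(PERTURBATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ppi_edges(path) -> list[tuple[str, str]]:
    """Read a PPI edge list TSV: two gene_id columns; a third score column is ignored."""
    edges = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TableFormatError(f"{path}:{lineno}: expected two tab-separated gene ids")
        edges.append((parts[0], parts[1]))
    return edges


def write_ppi_edges(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
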