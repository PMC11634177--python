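"""Molecular graphs over a fixed 14-element vocabulary.

Drugs are represented as plain undirected graphs: heavy atoms are nodes
(element symbols only), chemical bonds are untyped edges.  Hydrogens are
implicit and dropped, bond orders and stereochemistry are deliberately
ignored — the downstream encoder consumes connectivity plus a one-hot
element feature per atom and nothing else.

The vocabulary covers the 14 elements that dominate small-molecule drug
libraries: C, N, O, Cl, Ca, S, F, Br, I, P, Au, B, Si, Hg.  The one-hot
column index of an element is its position in :data:`VOCABULARY`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit prints parse diagnostics on stderr otherwise

#: Ordered element vocabulary; one-hot index = position.
VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "Cl", "Ca", "S", "F", "Br", "I", "P", "Au", "B", "Si", "Hg",
)

ELEMENT_INDEX: dict[str, int] = {el: i for i, el in enumerate(VOCABULARY)}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class VocabularyError(ValueError):
    """Raised when a molecule contains an element outside the vocabulary."""


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected heavy-atom graph of one molecule.

    ``nodes`` holds element symbols in parser atom order; ``edges`` holds
    unordered index pairs stored as ``(min, max)``.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    source_smiles: str = ""

    def __post_init__(self):
        n = len(self.nodes)
        for el in self.nodes:
            if el not in ELEMENT_INDEX:
                raise VocabularyError(f"element {el!r} not in the 14-element vocabulary")
        for i, j in self.edges:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid edge ({i}, {j}) for {n} nodes")
        if n > 1 and not _connected(n, self.edges):
            raise ValueError("molecular graph must be connected")

    @property
    def n_atoms(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix without self-loops."""
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=np.float64)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


def _connected(n: int, edges) -> bool:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for k in adj[stack.pop()]:
            if k not in seen:
                seen.add(k)
                stack.append(k)
    return len(seen) == n


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises
    ------
    SmilesParseError
        for syntactically invalid or multi-fragment SMILES.
    VocabularyError
        when an atom's element is outside the 14-element vocabulary.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SmilesParseError(f"multi-fragment SMILES not supported: {smiles!r}")
    nodes = []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in ELEMENT_INDEX:
            raise VocabularyError(f"element {symbol!r} in {smiles!r} not in vocabulary")
        nodes.append(symbol)
    edges = tuple(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(nodes=tuple(nodes), edges=edges, source_smiles=smiles)


def one_hot_atoms(graph: MolecularGraph) -> np.ndarray:
    """One-hot atom feature matrix of shape (n_atoms, 14); rows sum to 1."""
    out = np.zeros((graph.n_atoms, len(VOCABULARY)), dtype=np.float64)
    for row, el in enumerate(graph.nodes):
        out[row, ELEMENT_INDEX[el]] = 1.0
    return out


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi library: ``drug_id <TAB> SMILES`` per line, '#' comments."""
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'drug_id<TAB>SMILES', got {raw!r}")
        records.append((parts[0], parts[1]))
    return records


def write_smi(records, path) -> None:
    """Write (drug_id, SMILES) pairs as a .smi library."""
    with open(path, "w") as fh:
        for drug_id, smiles in records:
            fh.write(f"{drug_id}\t{smiles}\n")
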