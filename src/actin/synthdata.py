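"""Synthetic molecules, PPI networks and planted-effect perturbation data.

The generator produces datasets with the statistical structure the predictor
assumes about L1000-style per-cell-line data: a library of small molecules
over the 14-element vocabulary, a scale-free PPI network for gene embedding,
and a drug x gene log-fold-change matrix in which the presence of a chemical
element in a molecule shifts the expression of a planted gene module:

    logFC(d, g) = sum_e direction_e * beta_e * 1[d contains element_e]
                        * 1[g in targets_e]  +  Normal(0, noise_sd)

One call generates one synthetic "cell line"; families of cell-line models
(for the disparity analyses) are built by repeated calls with different
planted effects.

Molecules are random carbon skeletons (a tree with an optional single ring
closure) decorated with heteroatoms under simple valence caps, so every
generated SMILES parses back to an isomorphic heavy-atom graph.  This is
deliberately minimal chemistry: no aromaticity, stereochemistry, charges or
dose/time structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

from .chemgraph import VOCABULARY, MolecularGraph, parse_smiles
from .io import PerturbationRecord


class ConfigurationError(ValueError):
    """Raised for invalid synthetic-data configuration."""


# maximum number of single bonds each element may carry in generated molecules
_VALENCE_CAP = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 4, "B": 3, "Si": 4,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "Au": 1, "Hg": 1, "Ca": 1,
}

#: Default per-molecule inclusion probabilities, loosely matching how often
#: each heteroatom appears in small-molecule drug libraries.  Carbon is the
#: skeleton and is always present.
DEFAULT_PREVALENCE: dict[str, float] = {
    "N": 0.60, "O": 0.70, "S": 0.30, "Cl": 0.15, "F": 0.15, "Br": 0.08,
    "I": 0.05, "P": 0.08, "B": 0.03, "Si": 0.02, "Ca": 0.01, "Au": 0.005,
    "Hg": 0.005,
}


@dataclass(frozen=True)
class PlantedEffect:
    """One element -> gene-module effect planted into the generative model.

    ``target_genes`` are 0-based gene indices; ``beta`` is the effect size in
    logFC units and ``direction`` its sign.
    """

    element: str
    target_genes: frozenset
    beta: float
    direction: int = 1

    def __post_init__(self):
        if self.element not in VOCABULARY:
            raise ConfigurationError(f"effect element {self.element!r} not in vocabulary")
        if not self.target_genes:
            raise ConfigurationError("effect target_genes must be non-empty")
        if not self.beta > 0:
            raise ConfigurationError("effect beta must be > 0")
        if self.direction not in (+1, -1):
            raise ConfigurationError("effect direction must be +1 or -1")
        object.__setattr__(self, "target_genes", frozenset(int(g) for g in self.target_genes))


@dataclass
class SynthConfig:
    """Conditions for one synthetic cell line."""

    n_drugs: int = 200
    n_genes: int = 100
    element_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    noise_sd: float = 0.3
    effects: list = field(default_factory=list)
    seed: int = 42
    cell_line: str = "SYN1"
    min_atoms: int = 8
    max_atoms: int = 20
    ring_prob: float = 0.3

    def __post_init__(self):
        for el, p in self.element_prevalence.items():
            if el not in VOCABULARY:
                raise ConfigurationError(f"prevalence element {el!r} not in vocabulary")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence for {el!r} must be in [0, 1], got {p}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_drugs < 0 or self.n_genes < 1:
            raise ConfigurationError("n_drugs must be >= 0 and n_genes >= 1")
        for eff in self.effects:
            if max(eff.target_genes) >= self.n_genes:
                raise ConfigurationError(
                    f"effect on gene index {max(eff.target_genes)} exceeds n_genes={self.n_genes}"
                )
        if not 2 <= self.min_atoms <= self.max_atoms:
            raise ConfigurationError("need 2 <= min_atoms <= max_atoms")


def gene_id(index: int) -> str:
    """Canonical synthetic gene identifier g0001, g0002, ..."""
    return f"g{index + 1:04d}"


def _build_molecule(rng: np.random.Generator, config: SynthConfig) -> str:
    """Build one random valence-respecting molecule and return its SMILES."""
    hetero: list[str] = []
    for el, p in sorted(config.element_prevalence.items()):
        if el == "C":
            continue
        if rng.random() < p:
            hetero.extend([el] * int(rng.integers(1, 3)))  # 1 or 2 atoms
    n_atoms = int(rng.integers(config.min_atoms, config.max_atoms + 1))
    n_carbon = max(3, n_atoms - len(hetero))
    elements = ["C"] * n_carbon
    degree = [0] * n_carbon
    bonds: list[tuple[int, int]] = []
    cap = lambda k: _VALENCE_CAP[elements[k]]

    # carbon backbone: random tree over the carbons
    for i in range(1, n_carbon):
        candidates = [j for j in range(i) if degree[j] < cap(j)]
        j = int(rng.choice(candidates))
        bonds.append((i, j))
        degree[i] += 1
        degree[j] += 1
    # attach heteroatoms to carbons with spare valence
    for el in hetero:
        candidates = [j for j in range(n_carbon) if degree[j] < cap(j)]
        if not candidates:
            break  # skeleton saturated; drop remaining decorations
        j = int(rng.choice(candidates))
        i = len(elements)
        elements.append(el)
        degree.append(1)
        bonds.append((i, j))
        degree[j] += 1

    mol = Chem.RWMol()
    for el in elements:
        mol.AddAtom(Chem.Atom(el))
    for i, j in bonds:
        mol.AddBond(i, j, Chem.BondType.SINGLE)
    # optional single ring closure between non-adjacent carbons
    if rng.random() < config.ring_prob:
        open_c = [j for j in range(n_carbon) if degree[j] < cap(j)]
        rng.shuffle(open_c)
        bonded = {tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()}
        done = False
        for a in open_c:
            if done:
                break
            for b in open_c:
                if b > a and (a, b) not in bonded:
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    done = True
                    break
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_molecules(n: int, config: SynthConfig) -> list[tuple[str, str, MolecularGraph]]:
    """Generate ``n`` molecules as (drug_id, SMILES, graph) triples.

    Element composition follows ``config.element_prevalence`` (per-molecule
    inclusion probabilities); identical config and seed give identical output.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = np.random.default_rng(config.seed)
    out = []
    for k in range(n):
        smiles = _build_molecule(rng, config)
        out.append((f"d{k + 1:04d}", smiles, parse_smiles(smiles)))
    return out


def generate_ppi(n_genes: int, mean_degree: float, seed: int) -> list[tuple[str, str]]:
    """Scale-free (preferential-attachment) PPI edge list over g0001..gNNNN.

    The graph is undirected, simple and connected with mean degree close to
    ``mean_degree``.
    """
    if n_genes < 2:
        raise ConfigurationError("n_genes must be >= 2")
    if mean_degree < 1:
        raise ConfigurationError("mean_degree must be >= 1")
    m = max(1, int(round(mean_degree / 2)))
    g = nx.barabasi_albert_graph(n_genes, m, seed=int(seed))
    return [(gene_id(a), gene_id(b)) for a, b in sorted(g.edges())]


def generate_perturbations(
    molecules,
    n_genes: int,
    effects,
    noise_sd: float,
    seed: int,
    cell_line: str = "SYN1",
) -> list[PerturbationRecord]:
    """Planted-effect perturbation records: one per (drug, gene).

    ``molecules`` is a list of (drug_id, smiles, graph) triples as produced by
    :func:`generate_molecules`.
    """
    for eff in effects:
        if eff.element not in VOCABULARY:
            raise ConfigurationError(f"effect element {eff.element!r} not in vocabulary")
        if max(eff.target_genes) >= n_genes:
            raise ConfigurationError("effect gene index exceeds n_genes")
    rng = np.random.default_rng(seed)
    signal = np.zeros((len(molecules), n_genes))
    for d, (_, _, graph) in enumerate(molecules):
        present = set(graph.nodes)
        for eff in effects:
            if eff.element in present:
                for gidx in eff.target_genes:
                    signal[d, gidx] += eff.direction * eff.beta
    logfc = signal + (rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0)
    records = []
    for d, (drug_id, smiles, _) in enumerate(molecules):
        for gidx in range(n_genes):
            records.append(
                PerturbationRecord(drug_id, smiles, cell_line, gene_id(gidx), float(logfc[d, gidx]))
            )
    return records


def generate_dataset(config: SynthConfig):
    """Convenience wrapper: molecules + perturbation records for one cell line."""
    molecules = generate_molecules(config.n_drugs, config)
    records = generate_perturbations(
        molecules, config.n_genes, config.effects, config.noise_sd,
        seed=config.seed + 1, cell_line=config.cell_line,
    )
    return molecules, records
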