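"""SMILES → molecular graph featurization.

A drug is represented as a graph over its heavy atoms: one node per atom
with a fixed-width feature vector (one-hot atom symbol, heavy-atom degree,
adjacent-hydrogen count, implicit valence, plus an aromaticity bit), and two
directed edges per chemical bond.  Hydrogens stay implicit — they enter only
through the adjacent-H count feature.  Bond types are not encoded; the graph
layers consume node features and connectivity only.

The default feature layout is the DeepChem-style 78-wide vector common in
graph-based affinity models: 44 atom-symbol slots (43 elements + "other"),
degree 0–10, adjacent hydrogens 0–10, implicit valence 0–10, aromatic flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import BatchFeaturizationError, InputError, SmilesParseError

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "AtomFeatureSpec",
    "MolecularGraph",
    "FeaturizationFailure",
    "smiles_to_graph",
    "atom_feature_vector",
    "featurize_drug_set",
]

#: 43 common element symbols; a trailing "other" slot is appended by the spec.
DEFAULT_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)


@dataclass(frozen=True)
class AtomFeatureSpec:
    """Layout of the per-atom feature vector.

    ``feature_width`` is ``len(symbol_vocab) + 1`` (the "other" slot) plus the
    three count blocks (each ``cap + 1`` wide) plus the aromatic bit.
    """

    symbol_vocab: tuple[str, ...] = DEFAULT_SYMBOLS
    max_degree: int = 10
    max_num_h: int = 10
    max_implicit_valence: int = 10
    include_aromatic_flag: bool = True

    @property
    def feature_width(self) -> int:
        width = (
            len(self.symbol_vocab)
            + 1  # "other" symbol slot
            + (self.max_degree + 1)
            + (self.max_num_h + 1)
            + (self.max_implicit_valence + 1)
        )
        return width + 1 if self.include_aromatic_flag else width


DEFAULT_SPEC = AtomFeatureSpec()


@dataclass
class MolecularGraph:
    """Node features and directed edge list for one drug molecule."""

    node_features: np.ndarray  # (N, F) float64
    edge_index: np.ndarray  # (E, 2) int64, directed (source, target) pairs
    num_nodes: int
    drug_id: str = ""

    def validate(self) -> None:
        n, e = self.num_nodes, self.edge_index
        if self.node_features.shape[0] != n:
            raise InputError("node_features row count != num_nodes")
        if not np.all(np.isfinite(self.node_features)):
            raise InputError("non-finite node feature")
        if e.size:
            if e.min() < 0 or e.max() >= n:
                raise InputError("edge index out of range")
            if np.any(e[:, 0] == e[:, 1]):
                raise InputError("self-loop in edge_index")


@dataclass
class FeaturizationFailure:
    index: int
    smiles: str
    message: str


def _one_hot(value: int, size: int) -> np.ndarray:
    """One-hot of ``value`` over ``size`` slots; values past the cap map to the cap slot."""
    vec = np.zeros(size)
    vec[min(value, size - 1)] = 1.0
    return vec


def atom_feature_vector(
    symbol: str,
    degree: int,
    num_h: int,
    implicit_valence: int,
    aromatic: bool,
    spec: AtomFeatureSpec = DEFAULT_SPEC,
) -> np.ndarray:
    """Concatenate the one-hot blocks for one atom in the spec's fixed order.

    Unknown symbols fall into the trailing "other" slot; counts above a block
    cap map to the cap slot.  Negative counts are rejected.
    """
    if degree < 0 or num_h < 0 or implicit_valence < 0:
        raise InputError("negative atom attribute count")
    n_sym = len(spec.symbol_vocab) + 1
    sym_vec = np.zeros(n_sym)
    try:
        sym_vec[spec.symbol_vocab.index(symbol)] = 1.0
    except ValueError:
        sym_vec[-1] = 1.0  # "other"
    parts = [
        sym_vec,
        _one_hot(degree, spec.max_degree + 1),
        _one_hot(num_h, spec.max_num_h + 1),
        _one_hot(implicit_valence, spec.max_implicit_valence + 1),
    ]
    if spec.include_aromatic_flag:
        parts.append(np.array([1.0 if aromatic else 0.0]))
    return np.concatenate(parts)


def smiles_to_graph(
    smiles: str,
    spec: AtomFeatureSpec = DEFAULT_SPEC,
    drug_id: str = "",
) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    The input string is used as given (no canonicalization); node order is
    RDKit's atom order for that input.  Each bond contributes two directed
    edges.  Raises :class:`SmilesParseError` for unparseable strings and
    :class:`InputError` for an empty one.
    """
    if not smiles:
        raise InputError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    feats = np.array(
        [
            atom_feature_vector(
                a.GetSymbol(),
                a.GetDegree(),
                a.GetTotalNumHs(),
                a.GetImplicitValence(),
                a.GetIsAromatic(),
                spec,
            )
            for a in mol.GetAtoms()
        ]
    ).reshape(mol.GetNumAtoms(), spec.feature_width)
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
    edge_index = (
        np.array(edges, dtype=np.int64)
        if edges
        else np.empty((0, 2), dtype=np.int64)
    )
    graph = MolecularGraph(feats, edge_index, mol.GetNumAtoms(), drug_id)
    graph.validate()
    return graph


def featurize_drug_set(
    smiles_list: list[str],
    spec: AtomFeatureSpec = DEFAULT_SPEC,
) -> tuple[list[MolecularGraph], list[FeaturizationFailure]]:
    """Featurize a batch of SMILES, collecting per-item failures.

    Returns the graphs for the parseable items (input order preserved) and a
    failure record per bad item.  Raises :class:`BatchFeaturizationError`
    only if *every* item fails, and :class:`InputError` on an empty list.
    """
    if not smiles_list:
        raise InputError("empty SMILES list")
    graphs: list[MolecularGraph] = []
    failures: list[FeaturizationFailure] = []
    for i, smi in enumerate(smiles_list):
        try:
            graphs.append(smiles_to_graph(smi, spec, drug_id=f"drug_{i}"))
        except (SmilesParseError, InputError) as exc:
            failures.append(FeaturizationFailure(i, smi, str(exc)))
    if not graphs:
        raise BatchFeaturizationError(
            f"all {len(smiles_list)} SMILES failed featurization"
        )
    return graphs, failures
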