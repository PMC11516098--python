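"""Molecule parsing, graph featurization, scaffolds, and 2D MCS similarity.

The 2D similarity used throughout the toolkit is the fraction of the smaller
molecule's bonds covered by the maximum common substructure (MCS), with
element-agnostic atom matching: two molecules that share a topology but differ
in heteroatom placement still count as structurally overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Chem.Scaffolds import MurckoScaffold


class ParseError(ValueError):
    """Raised when a SMILES cannot be parsed or violates input contracts."""


class DegenerateMoleculeError(ValueError):
    """Raised for operations undefined on the given molecule (e.g. 0 bonds)."""


# Rotatable bond: single, non-ring bond between two non-terminal heavy atoms,
# amide C-N excluded (strict definition).
_ROTATABLE_SMARTS = Chem.MolFromSmarts(
    "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"
)
_AMIDE_SMARTS = Chem.MolFromSmarts("[C;$(C=O)]-[N;$(NC=O)]")


@dataclass(frozen=True)
class Molecule:
    """A parsed 2D structure with the counts the descriptor pipeline needs."""

    id: str
    smiles: str
    n_heavy_atoms: int
    n_bonds: int
    n_rotatable_bonds: int
    scaffold_key: str
    _mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol


def _count_rotatable(mol: Chem.Mol) -> int:
    amide = set()
    for a, b in mol.GetSubstructMatches(_AMIDE_SMARTS):
        amide.add(frozenset((a, b)))
    n = 0
    for a, b in mol.GetSubstructMatches(_ROTATABLE_SMARTS):
        if frozenset((a, b)) in amide:
            continue
        n += 1
    return n


def parse_molecule(smiles: str, id: str = "") -> Molecule:
    """Parse a SMILES into a :class:`Molecule`.

    Multi-fragment inputs (salts, mixtures) are rejected: preparation is an
    upstream responsibility and silently keeping the largest fragment hides
    data errors.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ParseError(f"multi-fragment SMILES (strip salts upstream): {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    return Molecule(
        id=id or canonical,
        smiles=canonical,
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        n_bonds=mol.GetNumBonds(),
        n_rotatable_bonds=_count_rotatable(mol),
        scaffold_key=murcko_scaffold_from_rdkit(mol),
        _mol=mol,
    )


def murcko_scaffold_from_rdkit(mol: Chem.Mol) -> str:
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def murcko_scaffold(mol: Molecule) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; "" for acyclic input."""
    return murcko_scaffold_from_rdkit(mol.rdkit_mol)


# ---------------------------------------------------------------------------
# Graph featurization
# ---------------------------------------------------------------------------

ATOM_VOCAB = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se")
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_FORMAL_CHARGES = (-2, -1, 0, 1, 2)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

# one-hot blocks: atom type (+unknown), hybridization (+other), formal charge
# (+other), chiral tag, then binary in-ring and aromatic flags
NODE_FEATURE_DIM = (len(ATOM_VOCAB) + 1) + (len(_HYBRIDIZATIONS) + 1) \
    + (len(_FORMAL_CHARGES) + 1) + len(_CHIRAL_TAGS) + 2
EDGE_FEATURE_DIM = len(_BOND_TYPES) + 1


@dataclass(frozen=True)
class MolGraph:
    """Featurized molecular graph (undirected bond list)."""

    node_features: np.ndarray  # (n_atoms, NODE_FEATURE_DIM)
    edge_features: np.ndarray  # (n_bonds, EDGE_FEATURE_DIM)
    adjacency: np.ndarray      # (n_bonds, 2) atom-index pairs


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # explicit "unknown" slot, never a silent drop
    return vec


def featurize(mol: Molecule) -> MolGraph:
    """Build per-atom and per-bond feature vectors.

    Node blocks: atom type, hybridization, formal charge, chiral tag (one-hot
    with explicit unknown slots), then in-ring and aromatic binary flags.
    Edge block: bond type one-hot.
    """
    rdmol = mol.rdkit_mol
    nodes = []
    for atom in rdmol.GetAtoms():
        row = (
            _one_hot(atom.GetSymbol(), list(ATOM_VOCAB))
            + _one_hot(atom.GetHybridization(), list(_HYBRIDIZATIONS))
            + _one_hot(atom.GetFormalCharge(), list(_FORMAL_CHARGES))
            + _one_hot(atom.GetChiralTag(), list(_CHIRAL_TAGS))[:-1]
            + [float(atom.IsInRing()), float(atom.GetIsAromatic())]
        )
        nodes.append(row)
    edges, pairs = [], []
    for bond in rdmol.GetBonds():
        edges.append(_one_hot(bond.GetBondType(), list(_BOND_TYPES)))
        pairs.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    node_features = np.asarray(nodes, dtype=np.float64)
    edge_features = (
        np.asarray(edges, dtype=np.float64)
        if edges else np.zeros((0, EDGE_FEATURE_DIM))
    )
    adjacency = (
        np.asarray(pairs, dtype=np.int64) if pairs else np.zeros((0, 2), dtype=np.int64)
    )
    return MolGraph(node_features, edge_features, adjacency)


# ---------------------------------------------------------------------------
# Maximum-common-substructure similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCSResult:
    """MCS bond count and the smaller-molecule-normalized similarity."""

    n_bonds_mcs: int
    similarity: float
    exhausted: bool = True  # False when the search hit its time budget


def mcs_similarity(
    a: Molecule,
    b: Molecule,
    *,
    match_bond_order: bool = False,
    timeout_s: int = 10,
) -> MCSResult:
    """Structural-overlap similarity of the smaller molecule.

    similarity = bonds(MCS) / min(bonds(a), bonds(b)).

    Atoms are matched as wildcards (element-agnostic) and, by default, bonds
    are matched on ring membership only, ignoring bond order, so aromatic and
    aliphatic ring systems can align. ``match_bond_order=True`` switches to
    order-respecting bond matching.
    """
    if a.n_bonds < 1 or b.n_bonds < 1:
        raise DegenerateMoleculeError(
            "MCS similarity is undefined for single-heavy-atom molecules"
        )
    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareAny
    params.BondTyper = (
        rdFMCS.BondCompare.CompareOrderExact
        if match_bond_order
        else rdFMCS.BondCompare.CompareAny
    )
    params.BondCompareParameters.RingMatchesRingOnly = True
    params.AtomCompareParameters.RingMatchesRingOnly = True
    params.Timeout = timeout_s
    res = rdFMCS.FindMCS([a.rdkit_mol, b.rdkit_mol], params)
    n = int(res.numBonds)
    return MCSResult(
        n_bonds_mcs=n,
        similarity=n / min(a.n_bonds, b.n_bonds),
        exhausted=not res.canceled,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_smi(path) -> list[Molecule]:
    """Read a .smi file: one SMILES (+ optional whitespace-separated id) per line."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            out.append(parse_molecule(smiles, mol_id))
    return out


def read_smiles_csv(path, smiles_column: str, id_column: str | None = None) -> list[Molecule]:
    import pandas as pd

    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ParseError(f"no column {smiles_column!r} in {path}")
    out = []
    for i, row in df.iterrows():
        mol_id = str(row[id_column]) if id_column else f"mol{i}"
        out.append(parse_molecule(row[smiles_column], mol_id))
    return out


def write_smi(molecules, path) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.smiles}\t{mol.id}\n")
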