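"""Conformer ensemble generation, strain filtering, and RMSD leader clustering.

Two ensemble schemes define the conformational spaces the descriptors are
computed over:

* ``global``  — wide coverage: strain threshold 1.4806 kcal/mol per rotatable
  bond, RMSD clustering cutoff 1.0 Å;
* ``near_native`` — conformers close to bound-like geometries: 0.5060
  kcal/mol per rotatable bond, cutoff 2.0 Å.

The per-rotatable-bond constants come from a strain-energy survey of
protein-bound ligand conformations (first quartile and upper 95% CI of the
mean, respectively) and are treated as fixed parameters here.

The generation backend is a contract: any callable producing (coordinates,
energy) conformers works. The built-in backend embeds with distance geometry
(ETKDGv3) and minimizes with MMFF94.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_graph import Molecule

GLOBAL_STRAIN_KCAL_PER_ROTBOND = 1.4806
NEAR_NATIVE_STRAIN_KCAL_PER_ROTBOND = 0.5060


class EnsembleError(RuntimeError):
    """Conformer generation or filtering failed."""


@dataclass(frozen=True)
class EnsembleScheme:
    name: str
    strain_factor_kcal_per_rotbond: float
    rmsd_cutoff_angstrom: float
    max_conformers: int = 50

    def __post_init__(self):
        if self.strain_factor_kcal_per_rotbond <= 0:
            raise ValueError("strain factor must be positive")
        if self.rmsd_cutoff_angstrom <= 0:
            raise ValueError("RMSD cutoff must be positive")


GLOBAL_SCHEME = EnsembleScheme("global", GLOBAL_STRAIN_KCAL_PER_ROTBOND, 1.0)
NEAR_NATIVE_SCHEME = EnsembleScheme("near_native", NEAR_NATIVE_STRAIN_KCAL_PER_ROTBOND, 2.0)

SCHEMES = {"global": GLOBAL_SCHEME, "near_native": NEAR_NATIVE_SCHEME}


@dataclass(frozen=True)
class Conformer:
    coordinates: np.ndarray      # (n_atoms_with_H, 3) Å
    energy: float                # kcal/mol (force-field)
    heavy_indices: np.ndarray    # indices of heavy atoms in coordinates


@dataclass(frozen=True)
class ConformerEnsemble:
    molecule_id: str
    scheme: str                  # "raw" before filtering, else scheme name
    n_rotatable_bonds: int
    conformers: tuple[Conformer, ...]
    elements: tuple[str, ...] = field(default=())

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    @property
    def strain_energies(self) -> np.ndarray:
        e = self.energies
        return e - e.min()

    def __len__(self) -> int:
        return len(self.conformers)


def generate_conformers(
    mol: Molecule, budget: int = 50, seed: int = 0
) -> ConformerEnsemble:
    """Embed up to ``budget`` conformers and minimize them with MMFF94.

    Deterministic for a fixed seed. Raises :class:`EnsembleError` when no
    conformer can be embedded or minimized.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rdmol = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
    heavy = np.array(
        [a.GetIdx() for a in rdmol.GetAtoms() if a.GetAtomicNum() > 1], dtype=np.int64
    )
    conformers = []
    # one embedding per derived seed: a shared seed would reproduce the same
    # starting geometry for every conformer and collapse the search
    for i in range(budget):
        trial = Chem.Mol(rdmol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed * 100_003 + i) % (2**31 - 1)
        params.enforceChirality = True
        cid = AllChem.EmbedMolecule(trial, params)
        if cid == -1:
            continue
        results = AllChem.MMFFOptimizeMoleculeConfs(trial, maxIters=2000)
        converged, energy = results[0]
        if converged == -1:  # force field could not be set up
            continue
        coords = np.array(trial.GetConformer(cid).GetPositions(), dtype=np.float64)
        conformers.append(Conformer(coords, float(energy), heavy))
    if not conformers:
        raise EnsembleError(f"embedding failed for {mol.id} ({mol.smiles})")
    conformers.sort(key=lambda c: c.energy)
    elements = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    return ConformerEnsemble(mol.id, "raw", mol.n_rotatable_bonds, tuple(conformers), elements)


def strain_filter(ens: ConformerEnsemble, scheme: EnsembleScheme) -> ConformerEnsemble:
    """Keep conformers within the scheme's strain budget.

    Threshold = strain_factor × max(n_rotatable_bonds, 1); the ``max`` keeps
    the rule meaningful for rigid molecules, whose threshold would otherwise
    collapse to zero and discard everything but the minimum.
    """
    if len(ens) == 0:
        raise EnsembleError("cannot strain-filter an empty ensemble")
    threshold = scheme.strain_factor_kcal_per_rotbond * max(ens.n_rotatable_bonds, 1)
    strains = ens.strain_energies
    kept = [c for c, s in zip(ens.conformers, strains) if s <= threshold]
    # the global minimum has strain 0 and is always retained
    return replace(ens, scheme=scheme.name, conformers=tuple(kept))


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition.

    Plain Kabsch on the given atom order; no graph-automorphism symmetry
    correction (a known v1 limitation for symmetric molecules).
    """
    if p.shape != q.shape:
        raise ValueError("coordinate shapes differ")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def heavy_atom_rmsd(a: Conformer, b: Conformer) -> float:
    return kabsch_rmsd(a.coordinates[a.heavy_indices], b.coordinates[b.heavy_indices])


def rmsd_cluster(ens: ConformerEnsemble, scheme: EnsembleScheme) -> ConformerEnsemble:
    """Energy-ascending leader clustering.

    Conformers are visited lowest energy first; each becomes a new cluster
    representative unless it lies within ``rmsd_cutoff`` of an existing
    representative. Every retained representative is therefore the
    lowest-energy member of its cluster, and all pairwise representative
    RMSDs exceed the cutoff.
    """
    ordered = sorted(ens.conformers, key=lambda c: c.energy)
    reps: list[Conformer] = []
    for conf in ordered:
        if all(heavy_atom_rmsd(conf, r) > scheme.rmsd_cutoff_angstrom for r in reps):
            reps.append(conf)
    capped = reps[: scheme.max_conformers]
    return replace(ens, scheme=scheme.name, conformers=tuple(capped))


def build_ensemble(
    mol: Molecule,
    scheme: EnsembleScheme,
    budget: int = 50,
    seed: int = 0,
    raw: ConformerEnsemble | None = None,
) -> ConformerEnsemble:
    """generate → strain-filter → cluster, optionally reusing a raw ensemble."""
    if raw is None:
        raw = generate_conformers(mol, budget=budget, seed=seed)
    return rmsd_cluster(strain_filter(raw, scheme), scheme)


# ---------------------------------------------------------------------------
# SDF I/O (one record per conformer)
# ---------------------------------------------------------------------------

def write_sdf(ens: ConformerEnsemble, mol: Molecule, path) -> None:
    rdmol = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
    writer = Chem.SDWriter(str(path))
    strains = ens.strain_energies
    for conf, strain in zip(ens.conformers, strains):
        conf_obj = Chem.Conformer(rdmol.GetNumAtoms())
        for i, (x, y, z) in enumerate(conf.coordinates):
            conf_obj.SetAtomPosition(i, (float(x), float(y), float(z)))
        m = Chem.Mol(rdmol)
        m.RemoveAllConformers()
        m.AddConformer(conf_obj, assignId=True)
        m.SetProp("mol_id", ens.molecule_id)
        m.SetProp("strain_kcal", f"{strain:.6f}")
        m.SetProp("energy_kcal", f"{conf.energy:.6f}")
        m.SetProp("scheme", ens.scheme)
        writer.write(m)
    writer.close()


def read_sdf(path) -> list[ConformerEnsemble]:
    """Read ensembles back from SDF; records are grouped by ``mol_id``."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    grouped: dict[str, list] = {}
    scheme_by_id: dict[str, str] = {}
    elements_by_id: dict[str, tuple] = {}
    for m in supplier:
        if m is None:
            continue
        mol_id = m.GetProp("mol_id")
        energy = float(m.GetProp("energy_kcal"))
        coords = np.array(m.GetConformer().GetPositions(), dtype=np.float64)
        heavy = np.array(
            [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1], dtype=np.int64
        )
        grouped.setdefault(mol_id, []).append(Conformer(coords, energy, heavy))
        scheme_by_id[mol_id] = m.GetProp("scheme") if m.HasProp("scheme") else "raw"
        elements_by_id[mol_id] = tuple(a.GetSymbol() for a in m.GetAtoms())
    return [
        ConformerEnsemble(
            mol_id, scheme_by_id[mol_id], 0, tuple(confs), elements_by_id[mol_id]
        )
        for mol_id, confs in grouped.items()
    ]
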