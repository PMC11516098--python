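"""Training-dataset construction: region stratification, pair sampling,
scaffold splitting, and SMILES-randomization augmentation.

Molecule pairs are stratified in the (MCS similarity, MaxSim) plane:

* ``analogous`` — high 2D *and* high conformational-space similarity
  (both ≥ their thresholds, default 0.6);
* ``dense``     — inside the elliptical bulk where most random pairs fall,
  modeled as a 2D Gaussian with a calibrated Mahalanobis radius;
* ``sparse``    — everything else (the informative, under-sampled tail).

Training pairs are drawn to the composition dense:sparse:analogous =
0.30:0.65:0.05, emitted in both orders, and molecules are split into
train/validation/test by Murcko scaffold (7:3 with a 1/10 validation
carve-out from the training scaffolds) so no scaffold leaks across the
train/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_graph import Molecule

REGIONS = ("dense", "sparse", "analogous")


@dataclass(frozen=True)
class SamplerConfig:
    region_ratios: tuple[float, float, float] = (0.30, 0.65, 0.05)
    positive_threshold: float = 0.6
    analogous_mcs_threshold: float = 0.6
    smiles_randomize_p: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.region_ratios):
            raise ValueError("region ratios must be non-negative")
        if abs(sum(self.region_ratios) - 1.0) > 1e-9:
            raise ValueError("region ratios must sum to 1")
        for t in (self.positive_threshold, self.analogous_mcs_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class DensityModel:
    """2D Gaussian over (MCS, MaxSim) with a calibrated dense radius.

    ``d0`` is chosen on the calibration sample so that roughly the target
    fraction (default 30%) of calibration pairs fall inside.
    """

    mean: np.ndarray
    cov_inv: np.ndarray
    d0: float

    @classmethod
    def fit(cls, mcs: np.ndarray, maxsim: np.ndarray, dense_fraction: float = 0.30):
        pts = np.column_stack([mcs, maxsim]).astype(float)
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T) + 1e-9 * np.eye(2)
        cov_inv = np.linalg.inv(cov)
        d = cls._maha(pts, mean, cov_inv)
        d0 = float(np.quantile(d, dense_fraction))
        return cls(mean, cov_inv, d0)

    @staticmethod
    def _maha(pts: np.ndarray, mean: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
        delta = pts - mean
        return np.sqrt(np.einsum("ij,jk,ik->i", delta, cov_inv, delta))

    def mahalanobis(self, mcs: float, maxsim: float) -> float:
        return float(self._maha(np.array([[mcs, maxsim]]), self.mean, self.cov_inv)[0])


def classify_region(
    mcs: float, maxsim: float, cfg: SamplerConfig, density_model: DensityModel | None
) -> str:
    """Assign a pair to exactly one of dense / sparse / analogous."""
    if mcs >= cfg.analogous_mcs_threshold and maxsim >= cfg.positive_threshold:
        return "analogous"
    if density_model is None:
        raise ValueError("a fitted density model is required for dense/sparse labels")
    if density_model.mahalanobis(mcs, maxsim) <= density_model.d0:
        return "dense"
    return "sparse"


def sample_pairs(
    library: list[Molecule],
    n_pairs: int,
    cfg: SamplerConfig,
    labeler,
    density_model: DensityModel | None = None,
    max_draws: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample molecule pairs to the configured region composition.

    ``labeler(mol_a, mol_b) -> (mcs, maxsim)`` supplies the coordinates used
    for stratification (full CSS pipeline or a fast surrogate). When no
    density model is given, one is calibrated on the first draws. Every
    sampled pair is also emitted with the two molecules exchanged. Returns
    (pair table, manifest); the manifest records the achieved composition,
    which can fall short of the target when a region is unreachable.
    """
    if len(library) < 2:
        raise ValueError("need at least two molecules")
    rng = np.random.default_rng(cfg.seed)
    targets = {
        "dense": round(n_pairs * cfg.region_ratios[0]),
        "sparse": round(n_pairs * cfg.region_ratios[1]),
        "analogous": round(n_pairs * cfg.region_ratios[2]),
    }
    targets["sparse"] += n_pairs - sum(targets.values())  # rounding remainder
    max_draws = max_draws or 50 * n_pairs

    if density_model is None:
        calib = []
        for _ in range(min(500, max_draws)):
            i, j = rng.choice(len(library), size=2, replace=False)
            calib.append(labeler(library[i], library[j]))
        calib = np.asarray(calib)
        density_model = DensityModel.fit(calib[:, 0], calib[:, 1])

    buckets: dict[str, list] = {r: [] for r in REGIONS}
    draws = 0
    while draws < max_draws and any(len(buckets[r]) < targets[r] for r in REGIONS):
        i, j = rng.choice(len(library), size=2, replace=False)
        a, b = library[i], library[j]
        mcs, maxsim = labeler(a, b)
        region = classify_region(mcs, maxsim, cfg, density_model)
        if len(buckets[region]) < targets[region]:
            buckets[region].append((a, b, mcs, maxsim, region))
        draws += 1

    shortfall = {r: targets[r] - len(buckets[r]) for r in REGIONS if len(buckets[r]) < targets[r]}
    if shortfall:
        import warnings

        warnings.warn(f"sampler could not reach target composition: short {shortfall}")
    rows = []
    for region in REGIONS:
        for a, b, mcs, maxsim, reg in buckets[region]:
            base = {"MCS": mcs, "MaxSim": maxsim, "region": reg}
            rows.append({"id_a": a.id, "id_b": b.id, "smiles_a": a.smiles,
                         "smiles_b": b.smiles, **base})
            rows.append({"id_a": b.id, "id_b": a.id, "smiles_a": b.smiles,
                         "smiles_b": a.smiles, **base})
    df = pd.DataFrame(rows)
    manifest = {
        "target_composition": targets,
        "achieved_composition": {r: len(buckets[r]) for r in REGIONS},
        "draws": draws,
        "seed": cfg.seed,
        "note": "each pair appears in both orders",
    }
    return df, manifest


def enrich_positives(pool: pd.DataFrame, cfg: SamplerConfig) -> pd.DataFrame:
    """Positive-sample enrichment: MaxSim above threshold and not analogous.

    Pairs with similar conformational spaces but dissimilar 2D structures are
    rare and informative; this filter extracts them from a labeled pool.
    """
    if pool.empty:
        return pool
    keep = (pool["MaxSim"] > cfg.positive_threshold) & (pool["region"] != "analogous")
    return pool[keep].reset_index(drop=True)


def high_similarity_validation_filter(
    pool: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Named preset: MaxSim ≥ threshold and outside the analogous region."""
    if pool.empty:
        return pool
    keep = (pool["MaxSim"] >= threshold) & (pool["region"] != "analogous")
    return pool[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scaffold split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    partition_of: dict[str, str]  # molecule id -> train | validation | test
    scaffold_of: dict[str, str] = field(default_factory=dict)

    def pair_partition(self, id_a: str, id_b: str) -> str:
        """Partition of a pair derived from its member molecules.

        Both in train(/validation) → that partition; exactly one training-set
        molecule → "cross"; no training molecule → "test".
        """
        pa, pb = self.partition_of[id_a], self.partition_of[id_b]
        in_train = [p in ("train", "validation") for p in (pa, pb)]
        if all(in_train):
            return "validation" if "validation" in (pa, pb) else "train"
        if any(in_train):
            return "cross"
        return "test"

    def to_json(self, path) -> None:
        scaffold_partition = {}
        for mol_id, part in self.partition_of.items():
            scaffold_partition[self.scaffold_of.get(mol_id, "")] = part
        with open(path, "w") as fh:
            json.dump(
                {"molecules": self.partition_of, "scaffolds": scaffold_partition},
                fh, indent=1, sort_keys=True,
            )


def scaffold_split(
    library: list[Molecule],
    train_fraction: float = 0.7,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> SplitAssignment:
    """Split molecules into train/validation/test by whole Murcko scaffolds.

    Scaffolds are shuffled with the seed and assigned greedily to the
    training side until it holds ``train_fraction`` of the molecules; the
    remainder is the test set. ``validation_fraction`` of the training
    molecules (again whole scaffolds) is then carved out as validation.
    """
    groups: dict[str, list[Molecule]] = {}
    for mol in library:
        groups.setdefault(mol.scaffold_key, []).append(mol)
    if len(groups) < 2:
        raise ValueError("need at least two distinct scaffolds to split")
    scaffolds = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(scaffolds)

    n_total = len(library)
    target = train_fraction * n_total
    train_scaffolds, n_train = [], 0
    test_scaffolds = []
    for sk in scaffolds:
        if n_train < target:
            train_scaffolds.append(sk)
            n_train += len(groups[sk])
        else:
            test_scaffolds.append(sk)
    if not test_scaffolds:  # guarantee a non-empty test side
        test_scaffolds.append(train_scaffolds.pop())
        n_train -= len(groups[test_scaffolds[0]])

    # polish: move or swap whole scaffolds while that brings the training
    # molecule count closer to the target (scaffold granularity can be
    # coarse, a plain greedy fill may overshoot badly)
    improved = True
    while improved:
        improved = False
        best = (abs(n_train - target), None)
        for sk in train_scaffolds:
            if len(train_scaffolds) > 1:
                d = abs(n_train - len(groups[sk]) - target)
                if d < best[0]:
                    best = (d, ("to_test", sk, None))
        for sk in test_scaffolds:
            if len(test_scaffolds) > 1:
                d = abs(n_train + len(groups[sk]) - target)
                if d < best[0]:
                    best = (d, ("to_train", sk, None))
        for sa in train_scaffolds:
            for sb in test_scaffolds:
                d = abs(n_train - len(groups[sa]) + len(groups[sb]) - target)
                if d < best[0]:
                    best = (d, ("swap", sa, sb))
        if best[1] is not None:
            kind, sa, sb = best[1]
            if kind == "to_test":
                train_scaffolds.remove(sa); test_scaffolds.append(sa)
                n_train -= len(groups[sa])
            elif kind == "to_train":
                test_scaffolds.remove(sa); train_scaffolds.append(sa)
                n_train += len(groups[sa])
            else:
                train_scaffolds.remove(sa); test_scaffolds.append(sa)
                test_scaffolds.remove(sb); train_scaffolds.append(sb)
                n_train += len(groups[sb]) - len(groups[sa])
            improved = True

    val_scaffolds, n_val = [], 0
    n_train_mols = sum(len(groups[sk]) for sk in train_scaffolds)
    for sk in list(train_scaffolds):
        if n_val < validation_fraction * n_train_mols and len(train_scaffolds) > 1:
            train_scaffolds.remove(sk)
            val_scaffolds.append(sk)
            n_val += len(groups[sk])

    partition_of, scaffold_of = {}, {}
    for part, scaffold_list in (
        ("train", train_scaffolds), ("validation", val_scaffolds), ("test", test_scaffolds)
    ):
        for sk in scaffold_list:
            for mol in groups[sk]:
                partition_of[mol.id] = part
                scaffold_of[mol.id] = sk
    return SplitAssignment(partition_of, scaffold_of)


# ---------------------------------------------------------------------------
# SMILES randomization
# ---------------------------------------------------------------------------

def randomize_smiles(smiles: str, p: float, rng: np.random.Generator) -> str:
    """With probability ``p`` return a random-atom-order SMILES, else canonical.

    The output always re-canonicalizes to the same molecule; this is pure
    augmentation for sequence-based consumers of the pair tables.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    if rng.random() >= p:
        return canonical
    order = rng.permutation(mol.GetNumAtoms()).tolist()
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)
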