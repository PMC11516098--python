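"""Conformational-space-similarity (CSS) labels for molecule pairs.

Every molecule pair is scored over two conformer ensembles per molecule
(global and near-native schemes) in both directions (A→B and B→A). The
resulting conformer-pair score matrices are reduced to four raw descriptors
per (direction, scheme) — the matrix max and min — and then to the advanced
descriptor family:

* ``MaxSim``          — max of the four raw values of a direction
* ``MaxDistance``     — min of the four
* ``MaxOverlap``      — (MaxSim + MaxDistance) / 2
* ``MaxAggregation``  — (Global_MAX + Near_MAX) / 2
* ``CrossX``          — (X(A→B) + X(B→A)) / 2, symmetric under pair swap

The conformer-pair scorer is pluggable: any callable mapping an ordered pair
of conformers to [0, 1] is admissible. The built-in scorer combines a
rotation-invariant shape term (distance moments against four reference
points, in the spirit of ultrafast shape recognition) with a directional
pharmacophore-coverage term: the fraction of the *reference* conformer's
feature types that the query can supply. Normalizing by the reference makes
the score directional, mimicking query-onto-reference superposition.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .chem_graph import Molecule, mcs_similarity
from .conf_ensemble import (
    GLOBAL_SCHEME,
    NEAR_NATIVE_SCHEME,
    Conformer,
    ConformerEnsemble,
    build_ensemble,
    generate_conformers,
)

RAW_NAMES = ("Global_MAX", "Global_MIN", "Near_MAX", "Near_MIN")
ADVANCED_NAMES = (
    "MaxSim", "MaxDistance", "MaxOverlap", "MaxAggregation",
    "CrossSim", "CrossDistance", "CrossOverlap", "CrossAggregation",
)
#: fixed, versioned column order of the label table
LABEL_COLUMNS = (
    "smiles_a", "smiles_b",
    "Global_MAX_ab", "Global_MIN_ab", "Near_MAX_ab", "Near_MIN_ab",
    "Global_MAX_ba", "Global_MIN_ba", "Near_MAX_ba", "Near_MIN_ba",
    "MaxSim", "MaxDistance", "MaxOverlap", "MaxAggregation",
    "CrossSim", "CrossDistance", "CrossOverlap", "CrossAggregation",
    "MCS",
)


class DegenerateGeometryError(ValueError):
    pass


class SchemeMismatchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Built-in directional conformer-pair scorer
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _load_pharmacophores(path: str | None = None) -> dict[str, list]:
    if path is None:
        text = resources.files("csmol.data").joinpath("pharmacophores.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        name: [Chem.MolFromSmarts(s) for s in patterns]
        for name, patterns in raw.items()
    }


def pharmacophore_types(mol: Chem.Mol, config_path: str | None = None) -> frozenset[str]:
    """Feature types (donor/acceptor/aromatic/hydrophobe/cation/anion) present."""
    found = set()
    for name, patterns in _load_pharmacophores(config_path).items():
        if any(mol.HasSubstructMatch(p) for p in patterns):
            found.add(name)
    return frozenset(found)


def shape_moments(coords: np.ndarray) -> np.ndarray:
    """12 rotation/translation-invariant distance moments of a conformer.

    Distances of every atom to 4 reference points — centroid, the atom
    closest to the centroid, the atom farthest from the centroid, and the
    atom farthest from that one — summarized by mean, standard deviation,
    and cube-root of the third central moment.
    """
    if len(coords) < 3:
        raise DegenerateGeometryError("need >= 3 atoms for shape moments")
    centroid = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - centroid, axis=1)
    cst = coords[np.argmin(d_ctd)]
    fct = coords[np.argmax(d_ctd)]
    ftf = coords[np.argmax(np.linalg.norm(coords - fct, axis=1))]
    moments = []
    for ref in (centroid, cst, fct, ftf):
        d = np.linalg.norm(coords - ref, axis=1)
        mu = d.mean()
        sigma = d.std()
        skew3 = ((d - mu) ** 3).mean()
        moments.extend([mu, sigma, np.cbrt(skew3)])
    return np.asarray(moments)


@dataclass
class MomentFeatureScorer:
    """Built-in stand-in for a 3D pharmacophore-shape aligner.

    score(query→reference) = shape_term × coverage_term where
    shape_term = 1 / (1 + mean |Δmoments|) and coverage_term is the fraction
    of the reference molecule's pharmacophore feature types that also occur
    in the query (1.0 when the reference has none).
    """

    config_path: str | None = None

    def feature_types(self, mol: Molecule) -> frozenset[str]:
        return pharmacophore_types(mol.rdkit_mol, self.config_path)

    def __call__(
        self,
        query_conf: Conformer,
        ref_conf: Conformer,
        query_types: frozenset[str],
        ref_types: frozenset[str],
    ) -> float:
        mq = shape_moments(query_conf.coordinates[query_conf.heavy_indices])
        mr = shape_moments(ref_conf.coordinates[ref_conf.heavy_indices])
        shape = 1.0 / (1.0 + float(np.abs(mq - mr).mean()))
        coverage = (
            len(ref_types & query_types) / len(ref_types) if ref_types else 1.0
        )
        return float(np.clip(shape * coverage, 0.0, 1.0))


def score_pair(
    query_conf: Conformer,
    ref_conf: Conformer,
    query_mol: Molecule,
    ref_mol: Molecule,
    scorer: MomentFeatureScorer | None = None,
) -> float:
    """Directional similarity of one query conformer onto one reference conformer."""
    scorer = scorer or MomentFeatureScorer()
    return scorer(
        query_conf, ref_conf, scorer.feature_types(query_mol), scorer.feature_types(ref_mol)
    )


# ---------------------------------------------------------------------------
# Matrix reduction to raw and advanced descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairScoreMatrix:
    query_id: str
    reference_id: str
    scheme: str
    scores: np.ndarray  # (n_query_conf, n_ref_conf) in [0, 1]

    def __post_init__(self):
        s = self.scores
        if s.size == 0:
            raise ValueError("empty score matrix")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("scores must lie in [0, 1]")


def score_ensembles(
    query: ConformerEnsemble,
    ref: ConformerEnsemble,
    query_mol: Molecule,
    ref_mol: Molecule,
    scorer: MomentFeatureScorer | None = None,
) -> PairScoreMatrix:
    """Full query-conformer × reference-conformer score matrix."""
    if query.scheme != ref.scheme:
        raise SchemeMismatchError(f"{query.scheme} vs {ref.scheme}")
    scorer = scorer or MomentFeatureScorer()
    q_types = scorer.feature_types(query_mol)
    r_types = scorer.feature_types(ref_mol)
    mat = np.empty((len(query), len(ref)))
    for i, qc in enumerate(query.conformers):
        for j, rc in enumerate(ref.conformers):
            mat[i, j] = scorer(qc, rc, q_types, r_types)
    return PairScoreMatrix(query.molecule_id, ref.molecule_id, query.scheme, mat)


@dataclass(frozen=True)
class RawCSS:
    """Raw descriptors of one direction: matrix max/min per scheme."""

    global_max: float
    global_min: float
    near_max: float
    near_min: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(RAW_NAMES, (self.global_max, self.global_min,
                                    self.near_max, self.near_min)))


def reduce_raw(mat_global: PairScoreMatrix, mat_near: PairScoreMatrix) -> RawCSS:
    if mat_global.scheme != "global" or mat_near.scheme != "near_native":
        raise SchemeMismatchError("expected one global and one near_native matrix")
    return RawCSS(
        global_max=float(mat_global.scores.max()),
        global_min=float(mat_global.scores.min()),
        near_max=float(mat_near.scores.max()),
        near_min=float(mat_near.scores.min()),
    )


def advanced_descriptors(raw_ab: RawCSS, raw_ba: RawCSS) -> dict[str, float]:
    """Advanced CSS descriptors from the two directional raw sets.

    The Max* family is reported for the A→B direction; the Cross* family
    averages the two directions and is symmetric under swapping A and B.
    """
    def direction(raw: RawCSS) -> dict[str, float]:
        values = (raw.global_max, raw.global_min, raw.near_max, raw.near_min)
        max_sim = max(values)
        max_dist = min(values)
        return {
            "MaxSim": max_sim,
            "MaxDistance": max_dist,
            "MaxOverlap": (max_sim + max_dist) / 2.0,
            "MaxAggregation": (raw.global_max + raw.near_max) / 2.0,
        }

    ab = direction(raw_ab)
    ba = direction(raw_ba)
    out = dict(ab)
    for name in ("Sim", "Distance", "Overlap", "Aggregation"):
        out[f"Cross{name}"] = (ab[f"Max{name}"] + ba[f"Max{name}"]) / 2.0
    return out


# ---------------------------------------------------------------------------
# End-to-end pair labeling
# ---------------------------------------------------------------------------

def label_pairs(
    library: list[Molecule],
    pairs: list[tuple[str, str]],
    conformer_budget: int = 30,
    seed: int = 0,
    scorer: MomentFeatureScorer | None = None,
) -> pd.DataFrame:
    """Full CSS pipeline for a list of ordered molecule-id pairs.

    conformers → strain filter → cluster → score both directions and schemes
    → raw → advanced descriptors + MCS similarity. Each molecule's ensembles
    are built once and cached; the run is deterministic for a fixed seed
    (each molecule's embedding seed is derived from its id).
    """
    scorer = scorer or MomentFeatureScorer()
    by_id = {m.id: m for m in library}
    cache: dict[str, dict[str, ConformerEnsemble]] = {}

    def ensembles(mol_id: str) -> dict[str, ConformerEnsemble]:
        if mol_id not in cache:
            mol = by_id[mol_id]
            mol_seed = (seed * 1_000_003 + hash_id(mol_id)) % (2**31 - 1)
            raw = generate_conformers(mol, budget=conformer_budget, seed=mol_seed)
            cache[mol_id] = {
                "global": build_ensemble(mol, GLOBAL_SCHEME, raw=raw),
                "near_native": build_ensemble(mol, NEAR_NATIVE_SCHEME, raw=raw),
            }
        return cache[mol_id]

    rows = []
    for id_a, id_b in pairs:
        for mol_id in (id_a, id_b):
            if mol_id not in by_id:
                raise KeyError(f"pair references unknown molecule id {mol_id!r}")
        mol_a, mol_b = by_id[id_a], by_id[id_b]
        try:
            ens_a, ens_b = ensembles(id_a), ensembles(id_b)
            raw_ab = reduce_raw(
                score_ensembles(ens_a["global"], ens_b["global"], mol_a, mol_b, scorer),
                score_ensembles(ens_a["near_native"], ens_b["near_native"], mol_a, mol_b, scorer),
            )
            raw_ba = reduce_raw(
                score_ensembles(ens_b["global"], ens_a["global"], mol_b, mol_a, scorer),
                score_ensembles(ens_b["near_native"], ens_a["near_native"], mol_b, mol_a, scorer),
            )
        except Exception as exc:
            raise RuntimeError(f"CSS labeling failed for pair ({id_a}, {id_b})") from exc
        adv = advanced_descriptors(raw_ab, raw_ba)
        row = {"smiles_a": mol_a.smiles, "smiles_b": mol_b.smiles}
        row.update({f"{k}_ab": v for k, v in raw_ab.as_dict().items()})
        row.update({f"{k}_ba": v for k, v in raw_ba.as_dict().items()})
        row.update(adv)
        row["MCS"] = mcs_similarity(mol_a, mol_b).similarity
        rows.append(row)
    return pd.DataFrame(rows, columns=list(LABEL_COLUMNS))


def hash_id(mol_id: str) -> int:
    """Stable (process-independent) small hash of a molecule id."""
    h = 2166136261
    for ch in mol_id.encode():
        h = (h ^ ch) * 16777619 % (2**31 - 1)
    return h


def write_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return df
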