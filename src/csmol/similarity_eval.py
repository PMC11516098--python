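"""Encoding-space similarity, virtual-screening evaluation, target
identification, benchmark curation, and fingerprint baselines.

Zero-shot screening ranks a labeled library by its similarity to one or more
reference molecules (max over references) and summarizes the ranking with
early-recognition metrics: BEDROC with α = 160.9 (weighting roughly the top
1% of the ranking), AUROC, and the 1% enrichment factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .chem_graph import Molecule, mcs_similarity


class UndefinedSimilarityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vector similarity
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("encoding lengths differ")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(a @ b / (na * nb))


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedSimilarityError("Pearson similarity undefined for constant vector")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def bedroc(active_ranks: np.ndarray, n: int, N: int, alpha: float = 160.9) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon & Bayly).

    ``active_ranks`` are the 1-based ranks of the ``n`` actives in a ranking
    of ``N`` molecules. The robust initial enhancement (RIE) is normalized by
    its analytic extremes — actives at ranks 1..n and at ranks N−n+1..N — so
    the best ranking scores exactly 1 and the worst exactly 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ranks = np.asarray(active_ranks, dtype=float)
    if len(ranks) != n or n < 1 or n > N:
        raise ValueError("need 1 <= n <= N distinct ranks")
    if len(np.unique(ranks)) != n or ranks.min() < 1 or ranks.max() > N:
        raise ValueError("ranks must be distinct integers in [1, N]")

    def rie(r):
        random_mean = (n / N) * (1 - np.exp(-alpha)) / (np.exp(alpha / N) - 1)
        return np.exp(-alpha * r / N).sum() / random_mean

    value = rie(ranks)
    best = rie(np.arange(1, n + 1, dtype=float))
    worst = rie(np.arange(N - n + 1, N + 1, dtype=float))
    return float((value - worst) / (best - worst))


def enrichment_factor(
    active_ranks: np.ndarray, n: int, N: int, fraction: float = 0.01
) -> float:
    """EF at a top fraction: active rate in the top set over the base rate."""
    top = max(1, int(np.ceil(fraction * N)))
    hits = int((np.asarray(active_ranks) <= top).sum())
    return (hits / top) / (n / N)


def auroc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningConfig:
    metric: str = "cosine"  # "cosine", "pearson", or a projection-head name
    bedroc_alpha: float = 160.9
    ef_fraction: float = 0.01
    multi_reference: str = "max"

    def __post_init__(self):
        if self.bedroc_alpha <= 0:
            raise ValueError("bedroc_alpha must be positive")
        if not 0 < self.ef_fraction < 1:
            raise ValueError("ef_fraction must be in (0, 1)")


@dataclass
class ScreeningResult:
    scores: pd.DataFrame  # columns: id, score, label, rank
    bedroc: float
    auroc: float
    ef: float
    ties_broken: int = 0


def _pair_scores(
    references: dict[str, np.ndarray],
    library: dict[str, np.ndarray],
    cfg: ScreeningConfig,
    model=None,
) -> dict[str, float]:
    if cfg.metric == "cosine":
        sim = cosine_similarity
    elif cfg.metric == "pearson":
        sim = pearson_similarity
    else:
        if model is None:
            raise ValueError(f"metric {cfg.metric!r} is a head name; a model is required")
        lib_ids = list(library)
        out = {}
        ref_mat = np.stack(list(references.values()))
        for mol_id in lib_ids:
            enc = np.repeat(library[mol_id][None, :], len(ref_mat), axis=0)
            vals = model.project(cfg.metric, enc, ref_mat)
            out[mol_id] = float(vals.max())
        return out
    return {
        mol_id: max(sim(enc, ref) for ref in references.values())
        for mol_id, enc in library.items()
    }


def screen(
    references: dict[str, np.ndarray],
    library: dict[str, np.ndarray],
    labels: dict[str, int],
    cfg: ScreeningConfig = ScreeningConfig(),
    model=None,
) -> ScreeningResult:
    """Score a labeled library against references and rank it.

    Each library molecule's score is the max over references of the chosen
    metric. Ranking is by descending score with ties broken by stable
    molecule-id order (recorded, because early-recognition metrics are
    rank-sensitive).
    """
    if not references:
        raise ValueError("need at least one reference encoding")
    scores = _pair_scores(references, library, cfg, model)
    df = pd.DataFrame(
        {"id": list(scores), "score": list(scores.values())}
    ).sort_values("id", kind="stable")
    df["label"] = df["id"].map(labels)
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    ties = int(len(df) - df["score"].nunique())

    N = len(df)
    active_ranks = df.loc[df["label"] == 1, "rank"].to_numpy()
    n = len(active_ranks)
    return ScreeningResult(
        scores=df,
        bedroc=bedroc(active_ranks, n, N, cfg.bedroc_alpha),
        auroc=auroc_from_scores(df["score"].to_numpy(), df["label"].to_numpy()),
        ef=enrichment_factor(active_ranks, n, N, cfg.ef_fraction),
        ties_broken=ties,
    )


# ---------------------------------------------------------------------------
# Target identification
# ---------------------------------------------------------------------------

def target_id(
    query_encoding: np.ndarray,
    ligand_encodings: dict[str, np.ndarray],
    targets_of_ligand: dict[str, set],
    true_targets: set,
    cfg: ScreeningConfig = ScreeningConfig(),
    model=None,
) -> tuple[pd.DataFrame, dict]:
    """Rank targets by their best-matching ligand's similarity to the query.

    Each target is one observation: score(T) = max over T's ligands of
    similarity(query, ligand). AUROC/BEDROC are computed over targets with
    the query's true targets as positives.
    """
    all_targets = sorted({t for ts in targets_of_ligand.values() for t in ts})
    if not set(true_targets) & set(all_targets):
        raise UndefinedSimilarityError("query has no true target in the library")
    sims = _pair_scores({"query": query_encoding}, ligand_encodings, cfg, model)
    score_of_target = {
        t: max(sims[lig] for lig, ts in targets_of_ligand.items() if t in ts)
        for t in all_targets
    }
    df = pd.DataFrame({
        "target": all_targets,
        "score": [score_of_target[t] for t in all_targets],
        "label": [int(t in true_targets) for t in all_targets],
    }).sort_values(["score", "target"], ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    N, n = len(df), int(df["label"].sum())
    active_ranks = df.loc[df["label"] == 1, "rank"].to_numpy()
    metrics = {
        "auroc": auroc_from_scores(df["score"].to_numpy(), df["label"].to_numpy()),
        "bedroc": bedroc(active_ranks, n, N, cfg.bedroc_alpha) if N > n else 1.0,
    }
    return df, metrics


# ---------------------------------------------------------------------------
# Target-ID benchmark curation
# ---------------------------------------------------------------------------

_UNIT_TO_NM = {"pm": 1e-3, "nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9}


def _to_nm(value: float, unit: str) -> float:
    key = unit.strip().lower()
    if key not in _UNIT_TO_NM:
        raise ValueError(f"affinity unit {unit!r} not convertible to molar")
    return value * _UNIT_TO_NM[key]


@dataclass
class TargetBenchmark:
    queries: list[str]                      # retained query ligand ids
    refined_queries: list[str]              # queries with > min_targets targets
    library: dict[str, pd.DataFrame]        # query id -> curated library table
    manifest: dict = field(default_factory=dict)


def build_target_benchmark(
    table: pd.DataFrame,
    query_molecules: dict[str, Molecule],
    library_molecules: dict[str, Molecule],
    min_entries: int = 300,
    min_heavy_atoms: int = 12,
    max_affinity_nm: float = 10_000.0,   # 10 µM
    max_mcs_similarity: float = 0.5,
    min_targets: int = 70,
) -> TargetBenchmark:
    """Curate a bioactivity table into a target-identification benchmark.

    Stage 1 keeps query ligands with more than ``min_entries`` activity
    entries and at least ``min_heavy_atoms`` heavy atoms; stage 2 drops
    query-target links weaker than ``max_affinity_nm``; stage 3 drops
    library ligands too similar (MCS) to the query, so no trivially similar
    structure remains; stage 4 marks the refined subset of queries that
    still cover more than ``min_targets`` targets. Counts per stage go into
    the manifest.
    """
    required = {"ligand_id", "smiles", "target_id", "affinity_value", "affinity_unit"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"bioactivity table missing columns: {sorted(missing)}")
    table = table.copy()
    table["affinity_nm"] = [
        _to_nm(v, u) for v, u in zip(table["affinity_value"], table["affinity_unit"])
    ]

    counts = table.groupby("ligand_id").size()
    stage1 = [
        q for q in query_molecules
        if counts.get(q, 0) > min_entries
        and query_molecules[q].n_heavy_atoms >= min_heavy_atoms
    ]

    library = {}
    stage2_links = stage3_ligands = 0
    for q in stage1:
        links = table[(table["ligand_id"] == q)]
        strong = links[links["affinity_nm"] <= max_affinity_nm]
        stage2_links += len(links) - len(strong)
        qmol = query_molecules[q]
        keep_rows = []
        for _, row in strong.iterrows():
            lib_id = row.get("library_ligand_id", row["ligand_id"])
            lib_mol = library_molecules.get(lib_id)
            if lib_mol is not None and lib_mol.n_bonds >= 1 and qmol.n_bonds >= 1:
                if mcs_similarity(qmol, lib_mol).similarity > max_mcs_similarity:
                    stage3_ligands += 1
                    continue
            keep_rows.append(row)
        library[q] = pd.DataFrame(keep_rows).reset_index(drop=True)

    refined = [
        q for q in stage1
        if not library[q].empty and library[q]["target_id"].nunique() > min_targets
    ]
    manifest = {
        "stage1_queries": len(stage1),
        "stage2_links_dropped": stage2_links,
        "stage3_library_ligands_dropped": stage3_ligands,
        "stage4_refined_queries": len(refined),
    }
    return TargetBenchmark(stage1, refined, library, manifest)


# ---------------------------------------------------------------------------
# Fingerprint baselines
# ---------------------------------------------------------------------------

def _fingerprint(mol: Molecule, fp_name: str):
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    rdmol = mol.rdkit_mol
    gens = {
        "ECFP4": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048),
        "ECFP6": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048),
        "FCFP4": lambda: rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=2048,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen()),
        "FCFP6": lambda: rdFingerprintGenerator.GetMorganGenerator(
            radius=3, fpSize=2048,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen()),
        "RDK": lambda: rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048),
        "AtomPair": lambda: rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048),
        "TopologicalTorsion": lambda: rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            fpSize=2048),
    }
    if fp_name in gens:
        return gens[fp_name]().GetFingerprint(rdmol)
    if fp_name == "MACCS":
        return MACCSkeys.GenMACCSKeys(rdmol)
    raise ValueError(f"unknown fingerprint {fp_name!r}")


FINGERPRINT_NAMES = (
    "ECFP4", "ECFP6", "FCFP4", "FCFP6", "RDK", "AtomPair", "TopologicalTorsion", "MACCS",
)
SIMILARITY_METRIC_NAMES = (
    "Tanimoto", "Dice", "Cosine", "Sokal", "Russel", "Kulczynski",
    "McConnaughey", "Tversky",
)


def fingerprint_baseline(
    a: Molecule, b: Molecule, fp_name: str = "ECFP4",
    metric_name: str = "Tanimoto", tversky_alpha: float = 0.5,
) -> float:
    """Bit-fingerprint similarity baseline for the named (fp, metric) pair.

    Tversky uses (α, 1−α), so α near 0 emphasizes containment of b in a and
    α near 1 the reverse; α = 0.5 recovers Dice.
    """
    from rdkit import DataStructs

    fpa = _fingerprint(a, fp_name)
    fpb = _fingerprint(b, fp_name)
    metrics = {
        "Tanimoto": DataStructs.TanimotoSimilarity,
        "Dice": DataStructs.DiceSimilarity,
        "Cosine": DataStructs.CosineSimilarity,
        "Sokal": DataStructs.SokalSimilarity,
        "Russel": DataStructs.RusselSimilarity,
        "Kulczynski": DataStructs.KulczynskiSimilarity,
        "McConnaughey": DataStructs.McConnaugheySimilarity,
    }
    if metric_name == "Tversky":
        value = DataStructs.TverskySimilarity(fpa, fpb, tversky_alpha, 1.0 - tversky_alpha)
    elif metric_name in metrics:
        value = metrics[metric_name](fpa, fpb)
    else:
        raise ValueError(f"unknown similarity metric {metric_name!r}")
    return float(np.clip(value, 0.0, 1.0))
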