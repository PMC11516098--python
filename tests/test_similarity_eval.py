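import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from csmol.chem_graph import parse_molecule
from csmol.similarity_eval import (
    ScreeningConfig,
    UndefinedSimilarityError,
    auroc_from_scores,
    bedroc,
    build_target_benchmark,
    cosine_similarity,
    enrichment_factor,
    fingerprint_baseline,
    pearson_similarity,
    screen,
    target_id,
)

from _oracles import bedroc_direct


def test_cosine_examples():
    v = np.array([0.3, -1.2, 2.0])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(0.9746318, abs=1e-6)
    with pytest.raises(UndefinedSimilarityError):
        cosine_similarity([0, 0], [1, 1])


def test_pearson_examples(rng):
    v = rng.normal(size=20)
    assert pearson_similarity(v, 2 * v + 3) == pytest.approx(1.0, abs=1e-12)
    assert pearson_similarity(v, -v) == pytest.approx(-1.0, abs=1e-12)
    assert pearson_similarity([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    with pytest.raises(UndefinedSimilarityError):
        pearson_similarity([1, 1, 1], [1, 2, 3])


def test_pearson_affine_invariance(rng):
    for _ in range(20):
        a = rng.normal(size=12)
        c, d = rng.uniform(0.1, 5), rng.normal()
        assert pearson_similarity(a, c * a + d) == pytest.approx(1.0, abs=1e-12)
        assert pearson_similarity(a, -c * a + d) == pytest.approx(-1.0, abs=1e-12)


def test_bedroc_endpoints_and_errors():
    assert bedroc(np.arange(1, 11), 10, 1000, 160.9) == pytest.approx(1.0, abs=1e-9)
    assert bedroc(np.arange(991, 1001), 10, 1000, 160.9) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        bedroc([1], 1, 10, -1.0)
    with pytest.raises(ValueError):
        bedroc([1, 1], 2, 10, 160.9)  # ranks must be distinct


def test_bedroc_matches_direct_formula(rng):
    for _ in range(200):
        N = int(rng.integers(20, 1500))
        n = int(rng.integers(1, max(2, N // 4)))
        ranks = rng.choice(np.arange(1, N + 1), size=n, replace=False)
        assert bedroc(ranks, n, N, 160.9) == pytest.approx(
            bedroc_direct(ranks, n, N, 160.9), abs=1e-9
        )


def test_bedroc_matches_rdkit(rng):
    from rdkit.ML.Scoring import Scoring

    for _ in range(25):
        N = int(rng.integers(50, 500))
        n = int(rng.integers(2, N // 5))
        ranks = np.sort(rng.choice(np.arange(1, N + 1), size=n, replace=False))
        labels = np.zeros(N, dtype=int)
        labels[ranks - 1] = 1
        reference = Scoring.CalcBEDROC([(0.0, int(l)) for l in labels], 1, 160.9)
        assert bedroc(ranks, n, N, 160.9) == pytest.approx(reference, abs=1e-6)


def test_enrichment_factor_cases(rng):
    assert enrichment_factor(np.arange(1, 11), 10, 1000, 0.01) == pytest.approx(100.0)
    ranks = np.array([5] + list(range(500, 509)))
    assert enrichment_factor(ranks, 10, 1000, 0.01) == pytest.approx(10.0)
    # uniform-random expectation is 1
    efs = [
        enrichment_factor(
            rng.choice(np.arange(1, 1001), size=10, replace=False), 10, 1000, 0.01
        )
        for _ in range(3000)
    ]
    assert np.mean(efs) == pytest.approx(1.0, abs=0.15)


def test_auroc_equals_mann_whitney(rng):
    scores = rng.normal(size=60)
    labels = (rng.random(60) < 0.4).astype(int)
    u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    expected = u / ((labels == 1).sum() * (labels == 0).sum())
    assert auroc_from_scores(scores, labels) == pytest.approx(expected)


def _toy_encodings(rng, n=30, d=8):
    enc = {f"m{i:03d}": rng.normal(size=d) for i in range(n)}
    return enc


def test_screen_actives_duplicating_reference(rng):
    ref = rng.normal(size=8)
    library = {f"a{i}": ref.copy() for i in range(5)}
    library.update({f"d{i}": rng.normal(size=8) for i in range(45)})
    labels = {k: int(k.startswith("a")) for k in library}
    res = screen({"ref": ref}, library, labels, ScreeningConfig(metric="cosine"))
    assert res.scores.loc[res.scores.label == 1, "score"].min() == pytest.approx(1.0)
    assert res.bedroc > 0.9 and res.auroc == pytest.approx(1.0)
    assert res.ef > 1.0


def test_screen_max_over_references(rng):
    library = _toy_encodings(rng)
    labels = {k: int(i < 5) for i, k in enumerate(library)}
    ref1, ref2 = rng.normal(size=8), rng.normal(size=8)
    cfg = ScreeningConfig(metric="cosine")
    res1 = screen({"r1": ref1}, library, labels, cfg)
    res2 = screen({"r2": ref2}, library, labels, cfg)
    both = screen({"r1": ref1, "r2": ref2}, library, labels, cfg)
    s1 = res1.scores.set_index("id")["score"]
    s2 = res2.scores.set_index("id")["score"]
    sb = both.scores.set_index("id")["score"]
    assert np.allclose(sb, np.maximum(s1[sb.index], s2[sb.index]))


def test_screen_invariant_to_library_order(rng):
    library = _toy_encodings(rng)
    labels = {k: int(i % 3 == 0) for i, k in enumerate(library)}
    ref = {"r": rng.normal(size=8)}
    res1 = screen(ref, library, labels)
    shuffled = dict(reversed(list(library.items())))
    res2 = screen(ref, shuffled, labels)
    pd.testing.assert_frame_equal(res1.scores, res2.scores)
    assert res1.bedroc == res2.bedroc


def test_screen_head_metric_requires_model(rng):
    library = _toy_encodings(rng)
    labels = {k: 1 for k in library}
    with pytest.raises(ValueError):
        screen({"r": rng.normal(size=8)}, library, labels,
               ScreeningConfig(metric="MaxSim"))


def test_target_id_basics(rng):
    ligands = {f"l{i}": rng.normal(size=8) for i in range(20)}
    targets_of = {f"l{i}": {f"T{i % 10}"} for i in range(20)}
    query = ligands["l3"].copy()
    table, metrics = target_id(query, ligands, targets_of, {"T3"})
    assert table.loc[table.target == "T3", "score"].iloc[0] == pytest.approx(1.0)
    assert metrics["auroc"] == pytest.approx(1.0)


def test_target_id_no_discrimination():
    ligands = {f"l{i}": np.array([1.0, 2.0, 3.0]) for i in range(10)}
    targets_of = {f"l{i}": {f"T{i}"} for i in range(10)}
    _, metrics = target_id(np.array([1.0, 2.0, 3.0]), ligands, targets_of, {"T0"})
    assert metrics["auroc"] == pytest.approx(0.5)


def test_target_id_requires_true_target(rng):
    ligands = {"l0": rng.normal(size=4)}
    with pytest.raises(UndefinedSimilarityError):
        target_id(rng.normal(size=4), ligands, {"l0": {"T1"}}, {"T9"})


def test_target_id_reduces_to_screen(rng):
    ligands = {f"l{i}": rng.normal(size=8) for i in range(15)}
    targets_of = {k: {f"T_{k}"} for k in ligands}  # one ligand per target
    true_targets = {f"T_l{i}" for i in range(3)}
    query = rng.normal(size=8)
    _, metrics = target_id(query, ligands, targets_of, true_targets)
    labels = {k: int(f"T_{k}" in true_targets) for k in ligands}
    res = screen({"q": query}, ligands, labels)
    assert metrics["auroc"] == pytest.approx(res.auroc)


def _bench_inputs():
    q_good = parse_molecule("CCOc1ccc(CC(=O)Nc2ccccc2)cc1", "q_good")
    q_few = parse_molecule("CCCCc1ccccc1", "q_few")
    lib_sim = parse_molecule("CCOc1ccc(CC(=O)Nc2ccccc2)cc1", "lib_sim")
    # acyclic, so element-agnostic ring-aware MCS to the query stays small
    lib_diff = parse_molecule("CCCCCCCCCCCC", "lib_diff")
    rows = []
    for i in range(301):
        rows.append({"ligand_id": "q_good", "smiles": q_good.smiles,
                     "library_ligand_id": "lib_diff" if i else "lib_sim",
                     "target_id": f"T{i}", "affinity_value": 100.0,
                     "affinity_unit": "nM"})
    rows.append({"ligand_id": "q_good", "smiles": q_good.smiles,
                 "library_ligand_id": "lib_diff", "target_id": "Tweak",
                 "affinity_value": 20.0, "affinity_unit": "uM"})
    for i in range(299):
        rows.append({"ligand_id": "q_few", "smiles": q_few.smiles,
                     "library_ligand_id": "lib_diff", "target_id": f"T{i}",
                     "affinity_value": 1.0, "affinity_unit": "nM"})
    table = pd.DataFrame(rows)
    queries = {"q_good": q_good, "q_few": q_few}
    library = {"lib_sim": lib_sim, "lib_diff": lib_diff}
    return table, queries, library


def test_build_target_benchmark_stages():
    table, queries, library = _bench_inputs()
    bench = build_target_benchmark(table, queries, library)
    # stage 1: only the ligand with >300 entries and >=12 heavy atoms survives
    assert bench.queries == ["q_good"]
    # stage 2: the 20 uM link was dropped
    assert "Tweak" not in set(bench.library["q_good"]["target_id"])
    # stage 3: the identical library ligand (MCS similarity 1) was dropped
    assert "lib_sim" not in set(bench.library["q_good"]["library_ligand_id"])
    # stage 4: >70 distinct targets remain
    assert bench.refined_queries == ["q_good"]
    assert bench.manifest["stage1_queries"] == 1


def test_build_target_benchmark_unit_error():
    table, queries, library = _bench_inputs()
    table.loc[0, "affinity_unit"] = "furlongs"
    with pytest.raises(ValueError):
        build_target_benchmark(table, queries, library)


def test_fingerprint_baseline_identity_and_disjoint():
    a = parse_molecule("CCOc1ccccc1")
    for fp in ("ECFP4", "MACCS", "RDK", "AtomPair"):
        assert fingerprint_baseline(a, a, fp, "Tanimoto") == pytest.approx(1.0)
    hydrocarbon = parse_molecule("CCCC")
    fluoro = parse_molecule("FC(F)(F)F")
    assert fingerprint_baseline(hydrocarbon, fluoro, "ECFP4", "Tanimoto") == 0.0


def test_tversky_matches_set_algebra_and_is_asymmetric():
    from csmol.similarity_eval import _fingerprint

    sub = parse_molecule("c1ccccc1")
    sup = parse_molecule("CCCc1ccccc1O")
    bits_a = set(_fingerprint(sub, "ECFP4").GetOnBits())
    bits_b = set(_fingerprint(sup, "ECFP4").GetOnBits())
    c = len(bits_a & bits_b)
    only_a, only_b = len(bits_a - bits_b), len(bits_b - bits_a)
    for alpha in (0.2, 0.8):
        expected = c / (alpha * only_a + (1 - alpha) * only_b + c)
        got = fingerprint_baseline(sub, sup, "ECFP4", "Tversky", tversky_alpha=alpha)
        assert got == pytest.approx(expected)
    low = fingerprint_baseline(sub, sup, "ECFP4", "Tversky", tversky_alpha=0.01)
    high = fingerprint_baseline(sub, sup, "ECFP4", "Tversky", tversky_alpha=0.99)
    assert low != pytest.approx(high)  # direction emphasis matters


def test_fingerprint_baseline_unknown_combination():
    a = parse_molecule("CC")
    with pytest.raises(ValueError):
        fingerprint_baseline(a, a, "NoSuchFP", "Tanimoto")
    with pytest.raises(ValueError):
        fingerprint_baseline(a, a, "ECFP4", "NoSuchMetric")
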