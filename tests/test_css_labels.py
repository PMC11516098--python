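import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from csmol.chem_graph import parse_molecule
from csmol.conf_ensemble import Conformer, ConformerEnsemble, generate_conformers
from csmol.css_labels import (
    LABEL_COLUMNS,
    DegenerateGeometryError,
    MomentFeatureScorer,
    PairScoreMatrix,
    RawCSS,
    SchemeMismatchError,
    advanced_descriptors,
    label_pairs,
    read_labels,
    reduce_raw,
    score_ensembles,
    score_pair,
    shape_moments,
    write_labels,
)


def _conf(mol, seed=0):
    return generate_conformers(mol, budget=5, seed=seed).conformers[0]


def test_shape_moments_rigid_motion_invariance(rng):
    coords = rng.normal(size=(9, 3)) * 2
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = coords @ rot.T + np.array([5.0, -1.0, 2.0])
    assert np.allclose(shape_moments(coords), shape_moments(moved), atol=1e-9)


def test_shape_moments_degenerate():
    with pytest.raises(DegenerateGeometryError):
        shape_moments(np.zeros((2, 3)))


def test_score_pair_self_is_one():
    mol = parse_molecule("CCc1ccccc1", "m")
    c = _conf(mol)
    assert score_pair(c, c, mol, mol) == pytest.approx(1.0)


def test_score_pair_directional_feature_coverage():
    benzene = parse_molecule("c1ccccc1", "benzene")
    phenol = parse_molecule("Oc1ccccc1", "phenol")
    scorer = MomentFeatureScorer()
    t_b, t_p = scorer.feature_types(benzene), scorer.feature_types(phenol)
    assert "aromatic" in t_b and "donor" in t_p
    assert t_b < t_p  # phenol supplies strictly more feature types
    cb, cp = _conf(benzene), _conf(phenol)
    # query phenol covers all of benzene's features, not vice versa
    assert score_pair(cp, cb, phenol, benzene) > score_pair(cb, cp, benzene, phenol)


def test_score_pair_range(small_library, rng):
    mols = rng.choice(np.asarray(small_library, dtype=object), size=6, replace=False)
    confs = [(_conf(m), m) for m in mols]
    for ca, ma in confs:
        for cb, mb in confs:
            assert 0.0 <= score_pair(ca, cb, ma, mb) <= 1.0


def test_score_ensembles_matrix_shape_and_diagonal():
    a = parse_molecule("CCCO", "a")
    ens = generate_conformers(a, budget=12, seed=1)
    mat = score_ensembles(ens, ens, a, a)
    assert mat.scores.shape == (len(ens), len(ens))
    assert np.allclose(np.diag(mat.scores), 1.0)


def test_score_ensembles_scheme_mismatch():
    a = parse_molecule("CCCO", "a")
    ens = generate_conformers(a, budget=5, seed=1)
    other = ConformerEnsemble("a", "near_native", 1, ens.conformers, ens.elements)
    with pytest.raises(SchemeMismatchError):
        score_ensembles(ens, other, a, a)


def _mat(values, scheme="global"):
    return PairScoreMatrix("q", "r", scheme, np.atleast_2d(np.asarray(values, dtype=float)))


def test_reduce_raw_examples():
    raw = reduce_raw(_mat([0.8, 0.2, 0.5]), _mat([0.7, 0.3], scheme="near_native"))
    assert raw == RawCSS(0.8, 0.2, 0.7, 0.3)
    ones = reduce_raw(_mat([1.0, 1.0]), _mat([1.0], scheme="near_native"))
    assert ones == RawCSS(1.0, 1.0, 1.0, 1.0)
    single = reduce_raw(_mat([0.4]), _mat([0.4], scheme="near_native"))
    assert single.global_max == single.global_min == 0.4


def test_reduce_raw_rejects_empty():
    with pytest.raises(ValueError):
        PairScoreMatrix("q", "r", "global", np.zeros((0, 0)))


def test_advanced_descriptor_examples():
    raw_ab = RawCSS(0.8, 0.2, 0.7, 0.3)
    raw_ba = RawCSS(0.6, 0.25, 0.55, 0.3)
    adv = advanced_descriptors(raw_ab, raw_ba)
    assert adv["MaxSim"] == pytest.approx(0.8)
    assert adv["MaxDistance"] == pytest.approx(0.2)
    assert adv["MaxOverlap"] == pytest.approx(0.5)
    assert adv["MaxAggregation"] == pytest.approx(0.75)
    assert adv["CrossSim"] == pytest.approx((0.8 + 0.6) / 2)
    all_ones = advanced_descriptors(RawCSS(1, 1, 1, 1), RawCSS(1, 1, 1, 1))
    assert all(v == 1.0 for v in all_ones.values())


def test_advanced_descriptor_invariants(rng):
    for _ in range(500):
        vals = np.sort(rng.random(8))
        raw_ab = RawCSS(vals[7], vals[0], vals[5], vals[2])
        raw_ba = RawCSS(vals[6], vals[1], vals[4], vals[3])
        adv = advanced_descriptors(raw_ab, raw_ba)
        swapped = advanced_descriptors(raw_ba, raw_ab)
        assert adv["MaxDistance"] <= adv["MaxOverlap"] <= adv["MaxSim"]
        assert adv["MaxOverlap"] == (adv["MaxSim"] + adv["MaxDistance"]) / 2
        for name in ("CrossSim", "CrossDistance", "CrossOverlap", "CrossAggregation"):
            assert adv[name] == swapped[name]
            lo = min(adv[name.replace("Cross", "Max")], swapped[name.replace("Cross", "Max")])
            hi = max(adv[name.replace("Cross", "Max")], swapped[name.replace("Cross", "Max")])
            assert lo - 1e-12 <= adv[name] <= hi + 1e-12


def test_label_pairs_self_pair_and_symmetry(tmp_path):
    mols = [parse_molecule("CCCCO", "a"), parse_molecule("CCCN", "b")]
    df = label_pairs(mols, [("a", "a"), ("a", "b"), ("b", "a")],
                     conformer_budget=10, seed=2)
    assert list(df.columns) == list(LABEL_COLUMNS)
    self_row = df.iloc[0]
    assert self_row["MaxSim"] == pytest.approx(1.0, abs=1e-6)
    assert self_row["MCS"] == pytest.approx(1.0)
    ab, ba = df.iloc[1], df.iloc[2]
    for name in ("CrossSim", "CrossDistance", "CrossOverlap", "CrossAggregation", "MCS"):
        assert ab[name] == pytest.approx(ba[name], abs=1e-12)

    path = tmp_path / "labels.csv"
    write_labels(df, path)
    df2 = label_pairs(mols, [("a", "a"), ("a", "b"), ("b", "a")],
                      conformer_budget=10, seed=2)
    path2 = tmp_path / "labels2.csv"
    write_labels(df2, path2)
    assert path.read_bytes() == path2.read_bytes()  # determinism, byte-identical
    assert len(read_labels(path)) == 3


def test_label_pairs_unknown_id():
    mols = [parse_molecule("CCO", "a")]
    with pytest.raises(KeyError):
        label_pairs(mols, [("a", "zzz")])


def test_rigid_rotation_leaves_descriptors_unchanged(rng):
    a = parse_molecule("CCCc1ccccc1", "a")
    b = parse_molecule("CCOc1ccncc1", "b")
    ens_a = generate_conformers(a, budget=8, seed=0)
    ens_b = generate_conformers(b, budget=8, seed=0)
    mat1 = score_ensembles(ens_a, ens_b, a, b)
    rot = Rotation.random(random_state=1).as_matrix()
    rotated = ConformerEnsemble(
        "a", "raw", a.n_rotatable_bonds,
        tuple(
            Conformer(c.coordinates @ rot.T + 7.5, c.energy, c.heavy_indices)
            for c in ens_a.conformers
        ),
        ens_a.elements,
    )
    mat2 = score_ensembles(rotated, ens_b, a, b)
    assert np.allclose(mat1.scores, mat2.scores, atol=1e-6)
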