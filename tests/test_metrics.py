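import numpy as np
import pytest

from conftest import make_candidate
from smilesforge.errors import EmptyReference, TooFew
from smilesforge.metrics import (
    delta_objective,
    depth_report,
    exceedance_series,
    heavy_atom_histogram,
    internal_diversity,
    joint_exceedance_series,
    nearest_reference,
    sa_summary,
)
from smilesforge.objectives import EVS_NAME


def test_internal_diversity_identities():
    clones = [make_candidate({}, fp_bits={1, 2, 3}, smiles=f"C{i}")
              for i in range(3)]
    assert internal_diversity(clones) == 0.0
    disjoint = [
        make_candidate({}, fp_bits={1, 2}, smiles="Ca"),
        make_candidate({}, fp_bits={5, 6}, smiles="Cb"),
    ]
    assert internal_diversity(disjoint) == 1.0
    with pytest.raises(TooFew):
        internal_diversity(clones[:1])


def test_internal_diversity_hand_average():
    # pairwise Tanimotos: (A,B) = 0.5, (A,C) = 0, (B,C) = 0
    a = make_candidate({}, fp_bits={1, 2, 3}, smiles="Ca")
    b = make_candidate({}, fp_bits={2, 3, 4}, smiles="Cb")
    c = make_candidate({}, fp_bits={10, 11, 12}, smiles="Cc")
    expected = (0.5 + 1.0 + 1.0) / 3
    assert internal_diversity([a, b, c]) == pytest.approx(expected)
    # permutation invariance
    assert internal_diversity([c, a, b]) == pytest.approx(expected)


def test_nearest_reference_tie_broken_by_order():
    g = make_candidate({}, fp_bits={1, 2}, smiles="Cg")
    r_far = make_candidate({}, fp_bits={1, 5, 6, 7, 8}, smiles="Cfar")
    r_tie1 = make_candidate({}, fp_bits={1, 2, 3, 4}, smiles="Ctie1")
    r_tie2 = make_candidate({}, fp_bits={1, 2, 3, 4}, smiles="Ctie2")
    neighbour, tc = nearest_reference(g, [r_far, r_tie1, r_tie2])
    assert neighbour is r_tie1
    assert tc == pytest.approx(0.5)
    with pytest.raises(EmptyReference):
        nearest_reference(g, [])


def test_nearest_reference_self_hit():
    g = make_candidate({}, fp_bits={1, 2, 3}, smiles="Cg")
    twin = make_candidate({}, fp_bits={1, 2, 3}, smiles="Ctwin")
    neighbour, tc = nearest_reference(g, [twin])
    assert tc == 1.0


def test_delta_objective():
    refs = [
        make_candidate({"plantsDS": 90.0}, fp_bits={1, 2}, smiles="Cr1"),
        make_candidate({"plantsDS": 50.0}, fp_bits={9}, smiles="Cr2"),
    ]
    g = make_candidate({"plantsDS": 95.0}, fp_bits={1, 2}, smiles="Cg")
    assert delta_objective(g, refs, "plantsDS") == pytest.approx(5.0)
    # a fingerprint duplicate of a reference has delta 0 against itself
    twin = make_candidate({"plantsDS": 90.0}, fp_bits={1, 2}, smiles="Ct")
    assert delta_objective(twin, refs, "plantsDS") == 0.0


def test_exceedance_series_hand_counts():
    cands = [make_candidate({"x": v}, smiles=f"C{i}")
             for i, v in enumerate([1.0, 5.0, 3.0, 7.0])]
    assert list(exceedance_series(cands, "x", 4.0)) == [0, 1, 1, 2]
    assert list(exceedance_series([], "x", 4.0)) == []
    assert list(exceedance_series(cands, "x", 100.0)) == [0, 0, 0, 0]
    # strict comparison: equalling the top does not count
    assert list(exceedance_series(cands, "x", 7.0)) == [0, 0, 0, 0]


def test_joint_exceedance_hand_counts():
    pairs = [(5.0, 5.0), (1.0, 9.0), (6.0, 6.0)]
    cands = [make_candidate({"x": a, "y": b}, smiles=f"C{i}")
             for i, (a, b) in enumerate(pairs)]
    assert list(joint_exceedance_series(cands, ("x", "y"), (4.0, 4.0))) == [1, 1, 2]
    assert list(
        joint_exceedance_series(cands, ("x", "y"), (-np.inf, -np.inf))
    ) == [1, 2, 3]
    assert list(
        joint_exceedance_series(cands, ("x", "y"), (np.inf, 4.0))
    ) == [0, 0, 0]


def test_joint_bounded_by_marginals():
    rng = np.random.default_rng(5)
    cands = [
        make_candidate({"x": float(a), "y": float(b)}, smiles=f"C{i}")
        for i, (a, b) in enumerate(rng.normal(size=(100, 2)))
    ]
    joint = joint_exceedance_series(cands, ("x", "y"), (0.3, -0.2))
    mx = exceedance_series(cands, "x", 0.3)
    my = exceedance_series(cands, "y", -0.2)
    assert np.all(joint <= mx) and np.all(joint <= my)
    assert np.all(np.diff(joint) >= 0) and np.all(np.diff(mx) >= 0)
    assert mx[-1] == sum(1 for c in cands if c.objectives["x"] > 0.3)


def test_depth_report_counts():
    # two-objective view (no EVS tie blocking): Dom values 0, 1, 0
    names = ["a", "b"]
    pool = [
        make_candidate({"a": 2.0, "b": 2.0}, smiles="CC"),
        make_candidate({"a": 1.0, "b": 1.0}, smiles="CCC"),
        make_candidate({"a": 0.0, "b": 3.0}, smiles="CCCC"),
    ]
    report = depth_report(pool, names, thresholds=(0, 1, 3, 5))
    assert list(report["n_total"]) == [2, 3, 3, 3]
    assert list(report["k"]) == [0, 1, 3, 5]
    assert (report["n_total"].diff().dropna() >= 0).all()
    # a mutually non-dominating pool is counted whole in every row
    flat = [make_candidate({"a": 1.0, "b": 1.0}, smiles="C" * (i + 1))
            for i in range(4)]
    flat_report = depth_report(flat, names)
    assert (flat_report["n_total"] == 4).all()


def test_depth_report_separates_references():
    names = [EVS_NAME, "a"]
    pool = [
        make_candidate({"a": 1.0}, evs=1, smiles="CCO"),
        make_candidate({"a": 2.0}, evs=0, smiles="CCN"),
    ]
    report = depth_report(pool, names, thresholds=(0,))
    assert report.loc[0, "n_reference"] == 1
    assert report.loc[0, "n_generated"] == 1


def test_heavy_atom_histogram():
    pool = [make_candidate({}, smiles=f"C{i}", n_heavy=10) for i in range(3)]
    pool.append(make_candidate({}, smiles="Cbig", n_heavy=20))
    hist, frac = heavy_atom_histogram(pool, cutoff=15)
    assert hist[10] == 3 and hist[20] == 1
    assert frac == pytest.approx(0.25)
    assert hist.sum() == len(pool)
    single, frac1 = heavy_atom_histogram(pool[:1])
    assert list(single) == [1] and frac1 == 0.0


def test_sa_summary_clones_and_range():
    from smilesforge.chem_core import Molecule

    mol = Molecule.from_smiles("CCOC(=O)CC")
    clones = [
        make_candidate({}, smiles=mol.smiles_canonical) for _ in range(3)
    ]
    mean, sd = sa_summary(clones)
    assert sd == 0.0
    assert 1.0 <= mean <= 10.0
    with pytest.raises(TooFew):
        sa_summary([])
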