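import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_dominance_counts, make_candidate
from smilesforge.errors import EmptyPool, MissingScore
from smilesforge.objectives import EVS_NAME, ObjectiveVector
from smilesforge.pareto import (
    ElitePool,
    depth_subset,
    dominance_count,
    dominance_counts,
    dominates,
    merge_and_prune,
    pareto_front,
    read_pool_tsv,
    write_pool_tsv,
)

NAMES = ["a", "b"]


def vec(a, b, evs=0):
    return ObjectiveVector(values={EVS_NAME: float(evs), "a": a, "b": b})


def three_pool():
    return [
        make_candidate({"a": 2.0, "b": 2.0}, smiles="CC"),
        make_candidate({"a": 1.0, "b": 1.0}, smiles="CCC"),
        make_candidate({"a": 0.0, "b": 3.0}, smiles="CCCC"),
    ]


def test_strict_dominance_definition():
    assert dominates(vec(2, 2), vec(1, 1), NAMES)
    assert not dominates(vec(2, 1), vec(1, 1), NAMES)  # tie breaks strictness
    assert not dominates(vec(1, 1), vec(1, 1), NAMES)
    assert not dominates(vec(1, 1), vec(2, 2), NAMES)
    # canonical form behind the switch
    assert dominates(vec(2, 1), vec(1, 1), NAMES, strict_all=False)
    assert not dominates(vec(1, 1), vec(1, 1), NAMES, strict_all=False)


def test_dominance_missing_objective():
    with pytest.raises(MissingScore):
        dominates(vec(1, 2), ObjectiveVector(values={EVS_NAME: 0.0, "a": 1.0}),
                  NAMES)


def test_worked_three_vector_pool():
    pool = three_pool()
    counts = dominance_counts(pool, NAMES)
    assert list(counts) == [0, 1, 0]
    assert dominance_count(pool[1], pool, NAMES) == 1
    front = pareto_front(pool, NAMES)
    assert {c.smiles for c in front} == {"CC", "CCCC"}
    assert {c.smiles for c in depth_subset(pool, NAMES, 1)} == {
        "CC", "CCC", "CCCC"
    }
    assert depth_subset(pool, NAMES, 0) == front


def test_front_of_identical_vectors_is_everything():
    pool = [make_candidate({"a": 1.0, "b": 1.0}) for _ in range(4)]
    assert len(pareto_front(pool, NAMES)) == 4


def test_front_singleton_and_empty():
    only = make_candidate({"a": 0.0, "b": 0.0})
    assert pareto_front([only], NAMES) == [only]
    with pytest.raises(EmptyPool):
        pareto_front([], NAMES)


def _random_pool(rng, n, d, ties):
    names = [f"o{i}" for i in range(d)]
    if ties:
        values = rng.integers(0, 4, size=(n, d)).astype(float)
    else:
        values = rng.normal(size=(n, d))
    pool = [
        make_candidate(dict(zip(names, row)), smiles=f"C{i}")
        for i, row in enumerate(values)
    ]
    return pool, names


def test_vectorized_scan_matches_brute_force_oracle(rng):
    # modest version of the exhaustive acceptance check
    for _ in range(30):
        n = int(rng.integers(2, 80))
        d = int(rng.integers(2, 7))
        pool, names = _random_pool(rng, n, d, ties=bool(rng.integers(2)))
        expected = brute_force_dominance_counts(pool, names)
        assert list(dominance_counts(pool, names)) == expected


def test_subsets_nested_in_k(rng):
    pool, names = _random_pool(rng, 60, 3, ties=True)
    previous: set = set()
    for k in (0, 1, 3, 5, 10):
        current = {c.smiles for c in depth_subset(pool, names, k)}
        assert previous <= current
        previous = current


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_strictly_increasing_transform_preserves_dominance(seed):
    rng = np.random.default_rng(seed)
    pool, names = _random_pool(rng, 40, 3, ties=bool(rng.integers(2)))
    before = list(dominance_counts(pool, names))
    transformed = [
        make_candidate(
            {
                names[0]: np.exp(c.objectives[names[0]]),  # strictly increasing
                names[1]: c.objectives[names[1]],
                names[2]: c.objectives[names[2]],
            },
            smiles=c.smiles,
        )
        for c in pool
    ]
    assert list(dominance_counts(transformed, names)) == before


def test_adding_dominated_item_never_changes_front(rng):
    pool, names = _random_pool(rng, 50, 3, ties=False)
    front = {c.smiles for c in pareto_front(pool, names)}
    worst = {
        n: min(c.objectives[n] for c in pool) - 1.0 for n in names
    }
    bigger = pool + [make_candidate(worst, smiles="Cworst")]
    assert {c.smiles for c in pareto_front(bigger, names)} == front
    # removing a non-front item leaves the front unchanged too
    non_front = next(c for c in pool if c.smiles not in front)
    smaller = [c for c in pool if c is not non_front]
    assert {c.smiles for c in pareto_front(smaller, names)} == front


def test_merge_and_prune_protects_references():
    names = [EVS_NAME, "a", "b"]
    ref = make_candidate({"a": 10.0, "b": 10.0}, evs=1, smiles="Cref")
    elite = ElitePool([ref])
    monster = make_candidate({"a": 100.0, "b": 100.0}, evs=0, smiles="Cbig")
    merged = merge_and_prune(elite, [monster], names)
    assert {c.smiles for c in merged} == {"Cref", "Cbig"}

    dominated = make_candidate({"a": 5.0, "b": 5.0}, evs=0, smiles="Csmall")
    merged2 = merge_and_prune(merged, [dominated], names)
    assert {c.smiles for c in merged2} == {"Cref", "Cbig"}  # dropped

    assert {c.smiles for c in merge_and_prune(merged2, [], names)} == {
        "Cref", "Cbig"
    }  # identity on empty merge


def test_pool_tsv_roundtrip(tmp_path):
    names = [EVS_NAME, "a", "b"]
    pool = [
        make_candidate({"a": 1.25, "b": -3.0e-7}, evs=1, smiles="CCO"),
        make_candidate({"a": 0.5, "b": 17.0}, evs=0, smiles="CCN"),
    ]
    path = tmp_path / "pool.tsv"
    write_pool_tsv(pool, names, path)
    back = read_pool_tsv(path)
    assert [c.smiles for c in back] == ["CCO", "CCN"]
    for orig, loaded in zip(pool, back):
        assert loaded.evs == orig.evs
        for n in ("a", "b"):
            assert loaded.objectives[n] == orig.objectives[n]
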