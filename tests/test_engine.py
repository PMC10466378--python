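import filecmp

import numpy as np
import pytest

from smilesforge import engine, fixtures
from smilesforge.engine import (
    Repository,
    RunConfig,
    RunState,
    initialize,
    master_collect,
    master_ingest,
    process_child,
    read_reference_tsv,
    run,
    run_no_ga,
    select_parent,
    worker_emit,
    write_run_outputs,
)
from smilesforge.errors import EmptyPool, UnscoredReference
from smilesforge.objectives import EVS_NAME, ObjectiveSetConfig
from smilesforge.pareto import ElitePool, pareto_front


SEED = 20240901


@pytest.fixture(scope="module")
def setup():
    obj = ObjectiveSetConfig(mode="plants_only")
    scorers = fixtures.surrogate_objective_bundle("plants_only", seed=SEED)
    refs = fixtures.make_reference_set(12, obj, seed=SEED, scorers=scorers)
    rows = [
        (c.smiles, {n: c.objectives[n] for n in obj.objectives if n != EVS_NAME})
        for c in refs
    ]
    return obj, scorers, rows


def make_config(setup, token_model, **kw):
    obj, scorers, _ = setup
    defaults = dict(objective=obj, scorers=scorers, token_model=token_model,
                    target_unique=30, seed=SEED)
    defaults.update(kw)
    return RunConfig(**defaults)


def test_initialize(setup, token_model):
    obj, scorers, rows = setup
    config = make_config(setup, token_model)
    elite, repo = initialize(rows, config)
    assert len(repo) == len(rows) == len(elite)
    assert all(c.evs == 1 for c in elite)


def test_initialize_missing_objective(setup, token_model):
    config = make_config(setup, token_model)
    bad = [("CCO", {"plantsDS": 1.0})]
    with pytest.raises(UnscoredReference):
        initialize(bad, config)


def test_select_parent_uniform(setup, token_model, rng):
    config = make_config(setup, token_model)
    elite, _ = initialize(setup[2][:4], config)
    draws = [select_parent(elite, rng).smiles for _ in range(10_000)]
    freqs = [draws.count(s) / 10_000 for s in elite.smiles()]
    assert all(abs(f - 0.25) < 0.02 for f in freqs)
    with pytest.raises(EmptyPool):
        select_parent(ElitePool([]), rng)


def test_process_child_outcomes(setup, token_model):
    obj, scorers, rows = setup
    config = make_config(setup, token_model)
    elite, repo = initialize(rows, config)
    state = RunState(config=config, repository=repo, elite=elite,
                     rng=np.random.default_rng(SEED))

    # duplicate: a reference re-offered as a child
    assert process_child(rows[0][0], state) == "duplicate"
    assert len(repo) == len(rows)

    # reactive child: archived penalized, elite unchanged
    before_elite = len(state.elite)
    assert process_child("CCCCC(=O)Cl", state) == "penalized"
    assert len(repo) == len(rows) + 1
    assert repo["CCCCC(=O)Cl"].penalized
    assert len(state.elite) == before_elite

    # clean novel child: accepted and archived with EVS 0
    assert process_child("CCCCOCCNCC", state) == "accepted"
    assert state.accepted[-1].evs == 0
    assert len(repo) == len(rows) + 2


def test_run_reaches_target_with_valid_unique_children(setup, token_model):
    config = make_config(setup, token_model, target_unique=40)
    state = run(setup[2], config)
    accepted = state.repository.accepted()
    assert len(accepted) == 40
    smiles = [c.smiles for c in accepted]
    assert len(set(smiles)) == 40
    from smilesforge.chem_core import validate

    assert all(validate(s) for s in smiles)
    # conservation: every attempt ended in exactly one outcome class
    total = sum(state.counters.values())
    assert total >= 40
    assert state.counters["accepted"] == 40


def test_elite_pool_is_front_and_keeps_references(setup, token_model):
    obj = setup[0]
    config = make_config(setup, token_model, target_unique=40)
    state = run(setup[2], config)
    # all references still present
    elite_smiles = set(state.elite.smiles())
    assert {s for s, _ in setup[2]} <= elite_smiles
    # elite equals the front of the clean archive (references included)
    clean = [r.candidate for r in state.repository.records() if not r.penalized]
    expected = {c.smiles for c in pareto_front(clean, obj.objectives)}
    assert elite_smiles == expected


def test_ga_and_no_ga_differ(setup, token_model):
    config = make_config(setup, token_model, target_unique=25)
    ga = run(setup[2], config)
    no_ga = run_no_ga(setup[2], config)
    assert len(ga.repository.accepted()) == len(no_ga.repository.accepted()) == 25
    assert [c.smiles for c in ga.accepted] != [c.smiles for c in no_ga.accepted]


def test_reproducible_byte_identical_outputs(setup, token_model, tmp_path):
    config = make_config(setup, token_model, target_unique=25)
    for name in ("a", "b"):
        state = run(setup[2], config)
        write_run_outputs(state, tmp_path / name)
    for fname in ("repository.tsv", "best_pool.tsv"):
        assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname,
                           shallow=False)


def test_reference_tsv_roundtrip(setup, tmp_path):
    obj, scorers, rows = setup
    refs = fixtures.make_reference_set(5, obj, seed=SEED, scorers=scorers)
    path = tmp_path / "ref.tsv"
    fixtures.write_reference_tsv(refs, obj.objectives, path)
    back = read_reference_tsv(path)
    assert [s for s, _ in back] == [c.smiles for c in refs]
    for (_, values), cand in zip(back, refs):
        for n in obj.objectives:
            if n != EVS_NAME:
                assert values[n] == cand.objectives[n]


def test_worker_master_protocol(setup, token_model, tmp_path):
    obj, scorers, rows = setup
    config = make_config(setup, token_model)
    elite, repo = initialize(rows, config)
    state = RunState(config=config, repository=repo, elite=elite,
                     rng=np.random.default_rng(SEED))

    raw_names = list(scorers.keys())
    children = ["CCCCOCCNCC", "CCCCOCCNCC", "CCCCCCNCCO"]  # one duplicate
    for smiles in children:
        raw = [scorers[n].score_one(smiles) for n in raw_names]
        worker_emit(smiles, raw, tmp_path)
    # malformed message: quarantined, never crashes the master
    (tmp_path / "msgs" / "zz_bad.msg").write_text("not\ta\tvalid\tmessage\n")

    messages = master_collect(tmp_path, n_scores=len(raw_names))
    assert len(messages) == 3
    tally = master_ingest(state, messages)
    assert tally == {"accepted": 2, "duplicate": 1, "penalized": 0}
    assert len(repo) == len(rows) + 2
    assert not list((tmp_path / "msgs").glob("*.msg"))
    assert (tmp_path / "msgs" / "quarantine" / "zz_bad.msg").exists()


def test_repository_is_append_only():
    repo = Repository()
    from conftest import make_candidate

    cand = make_candidate({"a": 1.0}, smiles="CCO")
    repo.add(cand)
    with pytest.raises(KeyError):
        repo.add(cand)
    assert len(repo) == 1
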