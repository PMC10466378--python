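"""A small end-to-end design study: GA vs random-sampling ablation.

Grows a 150-molecule focused library from a 42-molecule surrogate-scored
reference set under the consensus objective set (EVS, plantsDS,
plantsLE, glideDS, glideLE), then repeats the run with parents drawn at
random instead of from the elite pool, and compares how many molecules
beat the reference set's best scores.
"""

from smilesforge import (
    CorpusSpec,
    generate_corpus,
    internal_diversity,
    exceedance_series,
    make_reference_set,
    sa_summary,
    surrogate_objective_bundle,
    train_token_model,
)
from smilesforge.engine import RunConfig, run, run_no_ga
from smilesforge.objectives import EVS_NAME, ObjectiveSetConfig

SEED = 1
obj = ObjectiveSetConfig(mode="consensus")
names = [n for n in obj.objectives if n != EVS_NAME]

scorers = surrogate_objective_bundle("consensus", seed=SEED)
refs = make_reference_set(42, obj, seed=SEED, scorers=scorers)
rows = [(c.smiles, {n: c.objectives[n] for n in names}) for c in refs]
corpus = generate_corpus(CorpusSpec(n_molecules=500, seed=SEED))
model = train_token_model(corpus)

config = RunConfig(objective=obj, scorers=scorers, token_model=model,
                   target_unique=150, seed=SEED)
ga = run(rows, config)
ablation = run_no_ga(rows, config)

print(f"GA: accepted {ga.counters['accepted']}, "
      f"duplicates {ga.counters['duplicate']}, "
      f"penalized {ga.counters['penalized']}, "
      f"elite pool {len(ga.elite)} "
      f"(references retained: {sum(1 for c in ga.elite if c.evs == 1)}/42)")

div = internal_diversity(ga.accepted)
sa_mean, sa_sd = sa_summary(ga.accepted)
print(f"library internal diversity {div:.2f}, SA {sa_mean:.2f} +/- {sa_sd:.2f}")

tops = {n: max(c.objectives[n] for c in refs) for n in names}
print("\nmolecules beating the reference top value (GA vs ablation):")
for n in names:
    a = exceedance_series(ga.accepted, n, tops[n])[-1]
    b = exceedance_series(ablation.accepted, n, tops[n])[-1]
    print(f"  {n:<10s} top={tops[n]:8.3f}   GA {a:3d}   random {b:3d}")
print("\nExceedance counts are extreme-tail statistics: at this small "
      "library size they are low and noisy, but the elite pool always "
      "keeps every validated active eligible as a parent.")
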