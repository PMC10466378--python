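# Methods

## The design loop

The engine maintains two data structures: a **repository**, an
append-only archive keyed by canonical SMILES of every structure
visited during a run, and an **elite pool**, the current strictly
non-dominated subset of the clean archive plus the reference actives.
One iteration is:

1. draw a parent uniformly from the elite pool;
2. mutate its SMILES: draw a substitution count *s* uniformly from
   {1,…,5} and *s* distinct token positions uniformly without
   replacement, then resample tokens at those positions from the token
   model until the proposal parses as a valid molecule (at most 1000
   attempts; on exhaustion the engine redraws the position combination
   once, then moves to a fresh parent);
3. standardize and canonicalize the child; abandon the attempt if the
   canonical SMILES is already archived;
4. screen for reactive/unstable substructures; a hit is archived with
   all objectives at a −10⁹ sentinel (it was visited, so the
   uniqueness check must remember it) and can never reach the elite
   pool;
5. score the survivors, assemble the objective vector with EVS = 0,
   archive, and merge into the elite pool, keeping the strict Pareto
   front.

The run stops when `target_unique` clean, unique generated molecules
have been accepted.  Every attempt ends in exactly one of
{accepted, duplicate, penalized, exhausted}, and the four counters sum
to the number of attempts.

The no-GA ablation replaces step 1 with a uniform draw over all
previously accepted molecules plus the references — the identical
pipeline with selection pressure removed.  Comparing the two runs
isolates what elite-front selection contributes.

## Objectives

All objectives are oriented larger-is-fitter.  For a raw score *S*
from a minimize-raw scorer and heavy-atom count *N*_h:
DS = −*S*, LE = DS/*N*_h, PLE = DS/*N*_h^0.35.  The exponent 0.35 is
the empirical log–log slope of docking score against heavy-atom count:
raw docking scores systematically favor large molecules, plain LE
over-corrects toward fragments, and PLE is size-neutral by
construction (a score of the exact form c·*N*_h^0.35 has PLE = c at
every size; the test suite checks this to 10⁻¹⁰).

Two stock objective sets are provided: `plants_only`
(EVS, plantsDS, plantsLE, plantsPLE — one scorer, three views of its
score plus the actives flag) and `consensus`
(EVS, plantsDS, plantsLE, glideDS, glideLE — two scorers that must
agree before a molecule can dominate).  Custom sets plug in through
the same configuration.

EVS (experimental validation status) is a formal binary objective:
1 for the reference actives, 0 for everything generated.  Docking-type
scores correlate only weakly with true affinity, so without EVS a
confirmed active could be evicted from the parent pool by a generated
molecule with an artefactually high score.  Under strict dominance
(next section) EVS = 1 items can never be dominated, which is the
entire point of the flag.

## Strict dominance

*a* dominates *b* iff *a* > *b* in **every** objective.  This is
stricter than canonical Pareto dominance (≥ everywhere, > somewhere),
which is available behind `strict_all=False` but is not the default:
the EVS guarantee relies on the strict form (an EVS tie blocks
domination outright).  Dominance counts are computed by a vectorized
all-pairs scan, O(n²·d) like the reference definition; the test suite
checks it against an independent pure-Python brute force on hundreds
of random pools, including integer-valued pools dense with ties.

Comparisons are exact float `>` with no epsilon.  Scores come from
deterministic scorers, so ties are exact ties; an epsilon would
silently change front membership.

One consequence worth spelling out: within the generated set all EVS
values tie at 0, so when the *full* objective set is used nothing in
the generated set dominates anything else.  Dominance-depth analytics
(`depth_report`, the Dom ≤ k subset counts) therefore take an explicit
objective list and are normally run on the docking objectives only;
the engine's elite-pool front always uses the full set including EVS.

## The mutation operator

The substitution token model is a smoothed n-gram: conditional token
frequencies given the preceding `order` tokens (default 2), add-one
smoothed over the full alphabet, falling back to unconditional
frequencies for unseen contexts.  The default token unit is
`atom_token` (bracket atoms, Cl/Br and `%nn` ring closures kept
whole), which raises the validity rate of proposals over plain
character substitution — a trained neural generator learns those
constraints implicitly, an untrained stand-in benefits from structural
help; character mode remains available.  The operator is a plug-in
contract: anything that consumes a parent SMILES and a substitution
count and emits candidate SMILES can replace the n-gram model without
touching the engine.

Children identical to their parent are allowed out of the operator and
removed by the downstream uniqueness check, keeping the operator
simple and the pipeline order uniform.

## Scorers and the surrogate bundle

Scorers implement a one-method contract (SMILES in, raw score out);
external executables are supported via a line protocol
(`SMILES<TAB>score` on stdout).  A scorer failure on a molecule maps
to the penalization path, like a reactive-group hit — the molecule is
archived and excluded, never silently scored 0.

The surrogate docking score is
log(score) = log(base) + 0.35·log *N*_h + structural bonus + ε,
with ε a hash-seeded perturbation (SD 0.10 on the log scale by
default — small enough that a least-squares fit on a 500-molecule
corpus recovers the 0.35 slope within ±0.05, large enough that the
score is not a pure size function).  The ChemPLP-like surrogate
(base 30, bonus 0.5 × hetero-atom fraction) and the GLIDE-like
surrogate (base 3, bonus 0.15 × ring count) reward different
structural features and carry independent noise streams, so their
rankings genuinely conflict and consensus fronts are non-trivial.
Scores are deterministic given (canonical SMILES, seed).

## Synthetic inputs

The corpus generator assembles SMILES from a closed fragment grammar
(alkyl chain atoms, N/O/S substitutions, carbonyl/ester decorations,
cyclohexane/benzene/pyridine rings) under adjacency rules that
exclude the alert functionalities (no O–O, no anhydride linkages), so
every emitted string is valid and screen-clean by construction;
uniqueness is enforced by regeneration on collision.  Defaults:
500 molecules of 8–28 heavy atoms for the training corpus, 42
reference molecules of 12–26 heavy atoms — a reference panel of a few
dozen mid-sized actives and a corpus large enough to estimate order-2
token statistics.

What the synthetic setup does *not* emulate: real binding-site
chemistry (no pharmacophores, no metal coordination), tautomer and
ionization enumeration, and the syntax richness of a drug-like corpus
(no stereo descriptors, no fused polycyclics, limited bracket atoms).
Passing tests show the *algorithmic* contracts hold — dominance
semantics, EVS protection, uniqueness, determinism, the size-bias
arithmetic — not that the surrogate landscape ranks molecules the way
a docking program would.

## Numerical and design choices

- Penalty sentinel −10⁹ (configurable); penalized vectors carry
  EVS = 0 and are strictly dominated by any clean positive-scored
  vector, and two penalized vectors never dominate each other.
- Tanimoto of two all-zero fingerprints is defined as 1 (identical
  emptiness) with a warning; fingerprint default is radius 2,
  2048 bits, width configurable.
- Standardization = largest organic fragment + charge neutralization +
  canonicalization, iterated to a fixed point, hence idempotent.
- Internal diversity uses unordered distinct pairs
  (n(n−1)/2 denominator); the pair mean equals the per-molecule mean,
  so the two natural readings coincide.
- Exceedance counts use strict `>` ("better than the top"), and SA
  summaries use the population standard deviation (divide by n).
- Nearest-reference ties break by reference file order,
  deterministically.
- Reference TSVs carry already-oriented objective values; the loader
  attaches EVS = 1 to every row.  The duplicate check always compares
  canonical SMILES.
- Uniform distribution over the substitution count 1–5; the range is
  configurable.
- Stopping is by accepted-molecule count (`target_unique`), the
  desk-scale analogue of running to a fixed library size; the
  acceptance study uses 500 accepted molecules per mode.
- Master-side uniqueness in the worker protocol: workers may race to
  the same structure; the master owns the repository, so the second
  arrival is archived as a duplicate of nothing — simply dropped.

## Known limitations

- Exceedance-of-reference-top counts are extreme-tail statistics; at a
  500-molecule library size they are small (order 1–20) and sensitive
  to the seed, so the GA-vs-ablation gap on any single objective is
  noisy at desk scale even where the underlying selection pressure is
  real.  Larger targets sharpen the comparison at proportional cost.
- The n-gram mutator has no notion of global ring topology beyond what
  validity filtering imposes; it rarely grows or shrinks rings, so the
  library's size distribution stays close to the reference set's.
- Multi-worker runs assert set-level equality under a fixed message
  replay order; they are not byte-reproducible under true concurrency
  (arrival order is the nondeterminism, exactly as in any asynchronous
  master/worker design).
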