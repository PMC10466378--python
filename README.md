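# smilesforge

Target-oriented de novo molecular design by a multiobjective genetic
algorithm whose chromosome is the SMILES string itself.

`smilesforge` is for computational medicinal chemists who want to grow a
focused library around a panel of known actives, optimizing several
scoring criteria at once without collapsing them into a single weighted
fitness.  Parents are drawn from the current non-dominated (Pareto)
front, mutated by rewriting 1–5 token positions of their SMILES with a
corpus-trained conditional token model, and children pass a
standardize → uniqueness → reactive-group screen → scoring pipeline
before competing for a place on the front.

## The method

Every candidate carries an objective vector oriented "larger is
fitter".  For a docking-style raw score *S* (more negative is better)
and heavy-atom count *N*<sub>h</sub>:

- **DS** = −*S* (the negated docking score),
- **LE** = DS / *N*<sub>h</sub> (ligand efficiency; favors fragments),
- **PLE** = DS / *N*<sub>h</sub><sup>0.35</sup> (pondered ligand
  efficiency; 0.35 is the empirical slope of log DS against
  log *N*<sub>h</sub>, so PLE is size-neutral),
- **EVS** ∈ {0, 1}: experimental validation status, 1 for the known
  actives seeding the run and 0 for every generated molecule.

Selection uses **strict Pareto dominance**: *a* dominates *b* only when
*a* is strictly better in *every* objective simultaneously.  The
dominance count Dom(*x*) is the number of pool members dominating *x*;
the elite pool is the Dom = 0 subset after each merge.  Because no
generated molecule can strictly beat a validated active on EVS, the
seeding actives are permanently non-dominated and remain eligible
parents for the whole run — artefactually high scores can never push
the experimentally grounded chemistry out of the gene pool.

Scoring is a pluggable contract: any callable, or any executable that
reads SMILES on stdin and emits `SMILES<TAB>score` lines, can provide
an objective.  The package ships deterministic surrogate scorers whose
log-score grows with log *N*<sub>h</sub> with slope 0.35, so the entire
workflow runs offline at desk scale.

## Worked example

`examples/04_design_study.py` grows a 150-molecule library from a
42-molecule surrogate-scored reference set under the consensus
objective set (EVS, plantsDS, plantsLE, glideDS, glideLE), then repeats
the run with random parent sampling instead of elite selection:

```
GA: accepted 150, duplicates 152, penalized 5, elite pool 83 (references retained: 42/42)
library internal diversity 0.85, SA 3.16 +/- 0.69

molecules beating the reference top value (GA vs ablation):
  plantsDS   top= 128.032   GA   1   random   0
  plantsLE   top=   8.819   GA   0   random   0
  glideDS    top=  13.788   GA   4   random   2
  glideLE    top=   0.772   GA   2   random   4
```

Reading the numbers: the run visited 307 unique structures to accept
150 clean, novel molecules; all 42 validated actives are still in the
elite pool.  Internal diversity is the mean Soergel (1 − Tanimoto)
distance over all pairs on radius-2 Morgan fingerprints — 0.85 means
the library is structurally broad, not a cloud of near-duplicates.  The
SA score (1 = easy to synthesize, 10 = hard) averages 3.2 even though
synthesizability was never an objective.  The exceedance lines count
generated molecules strictly beating the best reference value of each
objective; at this small scale they are tail statistics and stay in the
single digits.

The other examples show the synthetic input generators
(`01_synthetic_inputs.py`), the mutation operator
(`02_mutate_smiles.py`) and the strict-dominance/EVS mechanics
(`03_pareto_selection.py`).  A thin CLI wraps the same library surface:

```bash
smilesforge fixtures corpus --n 500 --seed 1 --out corpus.smi
smilesforge fixtures reference --n 42 --seed 1 --out ref.tsv
smilesforge run --config run.yaml --workdir out/
smilesforge pareto --in out/best_pool.tsv --depth 0 --out front.tsv
smilesforge analyze --repository out/best_pool.tsv --reference ref.tsv --out report/
```

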