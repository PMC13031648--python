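# seqhier

Detect and measure hierarchical structure in ethogram-coded behavioral
sequences (e.g., percussive tool-use action sequences).

The pipeline:

1. **Grammar induction** — lossless hierarchical compression of each
   sequence with the Sequitur algorithm (digram uniqueness + rule
   utility, default `K = 2`), yielding a compressed start sequence and a
   rule book.
2. **Tree metrics** — each rule is encoded as a binary shape string
   (terminal → `1`, embedded rule → `0` followed by its own encoding) and
   scored on six measures: nesting depth, chunk count, phrase length,
   structural entropy, Gini coefficient of non-terminal positions, and
   terminal:non-terminal ratio.
3. **Control simulation** — length-matched i.i.d. (empirical frequency)
   and first-order Markov baselines fitted to the observed data, with
   irreducibility/aperiodicity checks.
4. **Structure sharing** — deduplication of rule shapes per group and
   shared-vs-unique classification of the target group's shapes.
5. **Group comparison** — Bayesian GLMs (Poisson log link for counts,
   zero-inflated beta for bounded measures; flat intercept prior,
   normal(0, 10) contrast priors, 4 chains × 2000 draws after 1000
   warmup) with treatment coding and 95% credible intervals, plus an MLE
   fallback.
6. **Synthetic fixtures** — seeded i.i.d., Markov and planted-motif
   generators so the full pipeline is testable offline.

## CLI

All stages are exposed through one entry point (`seqhier --help`):

```sh
# synthetic three-way suite (planted / markov / iid), 140 sequences
seqhier fixtures --seed 1 --out out/fixtures

# rule books + compressed lengths (min-length filter defaults to 8)
seqhier compress out/fixtures/planted.csv --k 2 --out out/planted

# six complexity measures from the stored rule books
seqhier metrics out/fixtures/planted.csv \
    --rulebooks out/planted/rulebooks --out out/planted

# length-matched markov + random control sets for an observed CSV
seqhier simulate observed.csv --seed 1 --out out/controls

# shared vs unique rule shapes across groups
seqhier share --metrics out/planted/rule_metrics.csv \
    --metrics out/markov/rule_metrics.csv --target-group planted \
    --out out/share

# fit the six outcome models and write the results table
seqhier compare --rule-metrics rules.csv --sequence-metrics seqs.csv \
    --reference-group chimpanzee --seed 1 --out out/report.csv
```

Input sequences are CSV with header
`sequence_id,subject_id,group,position,behavior` (1-based contiguous
positions; `--column-map canonical=actual,...` adapts foreign headers).
An optional ethogram CSV (`code,label`) pins the label↔code mapping;
otherwise codes are assigned by first appearance.

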