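# survbal

Selection of compositional microbiome balances associated with censored
time-to-event outcomes.

A *balance* is the normalized log-ratio of the geometric means of two
disjoint groups of taxa's relative abundances — a single scale-invariant
feature of the microbiome.  `survbal` searches for the balance most
associated with a survival outcome by greedy step-wise selection under
either a Cox proportional-hazards model or a parametric (Weibull/AFT)
survival model, and gates interpretation with a community-level kernel
association pre-test (Bray-Curtis + Jaccard kernels, martingale-residual
permutation p-values, Cauchy-combination omnibus p).  An insignificant
community-level association never blocks the selection; it raises a caution
flag.

## Command line

```bash
# simulate a dataset with a planted balance
survbal simulate --n-samples 200 --n-taxa 12 --plus 0,1 --minus 2,3 \
    --gamma 1.5 --seed 7 --out-dir sim/

# run the full pipeline: read -> filter -> close -> community test ->
# greedy selection -> fit -> report
survbal run --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --time-col time --event-col event --model cox --seed 7 --out-dir out/ --plot

# community-level association test only
survbal test-community --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --time-col time --event-col event
```

`survbal run` writes `report.json` (selected taxa, effect size with 95% CI,
likelihood-ratio p, community-test p-values, caution flag, full config
echo), `balance.tsv` (per-sample balance), `trace.tsv` (selection path),
`distance_*.tsv`, `curves.tsv` (predicted survival at the first/third
balance quartiles) and optionally `curves.png`.  Exit codes: 0 success,
2 validation error, 3 numerical failure.

Input format: TSV/CSV count table with samples in rows, taxa in columns and
the sample id in the first column; a metadata table keyed by the same id
with a positive time column, a 0/1 event column and optional numeric
covariates.

## Python API

```python
import survbal as sb

table, outcome = sb.read_tables("counts.tsv", "meta.tsv", "time", "event")
table = sb.filter_taxa(table, "remove_rare", 1e-4)
comp = sb.close_composition(table, pseudocount=0.5)
result = sb.select_balance(comp, outcome, model="cox", counts=table, seed=1)
print(result.best_spec, result.balance_effect, result.caution)
```

Modules: `preprocess` (tables, filtering, closure), `balance` (log-ratio
balances), `survival` (Cox partial-likelihood and censored AFT maximum
likelihood, survival-curve prediction), `selection` (greedy search +
exhaustive oracle), `community` (distances, kernels, permutation test),
`simulate` (Dirichlet-multinomial counts and balance-driven outcomes),
`pipeline`/`cli` (orchestration and reporting).

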