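# predbench

Benchmarking toolkit for missense pathogenicity prediction programs.

Clinical diagnostic laboratories routinely consult in-silico predictors
(SIFT, PolyPhen-2, MutPred, Condel, FATHMM, ...) to interpret novel missense
variants, but these tools disagree with each other, emit heterogeneous output
vocabularies and scores, frequently fail to produce any prediction, and hedge
with "possible" calls and low-reliability indices. `predbench` implements an
evaluation procedure for this setting, aimed at diagnosticians and methods
developers who need to rank predictors on curated variant sets:

1. **Credibility classification** (`predbench.variant_model`) — a rule engine
   assigning variants to *credibly pathogenic* (published or database-listed
   disease association + clinical case or validation specimen + in-house
   sequencing confirmation) or *credibly benign* (seen in ≥ 2 large
   population resources with MAF strictly above a panel-specific threshold —
   0.001 for dominant gain-of-function panels, 0.010 for recessive
   loss-of-function panels — and dbSNP-validated or published benign).
2. **Harmonization** (`predbench.harmonization`) — maps word labels and
   numeric score bands onto a canonical trichotomy
   Damaging / PossiblyDamaging / Benign (plus Missing), and applies the
   reliability cutoff (index ≥ 5 on the 0–9 scale by default). A call is
   *usable* only if dichotomous and reliable.
3. **Coverage-weighted metrics** (`predbench.metrics`) — per-program
   confusion matrices over usable calls with

   PPV = TP/(TP+FP), NPV = TN/(TN+FN), Spec = TN/(TN+FP),
   Sens = TP/(TP+FN), Accuracy = (TP+TN)/VarUse,
   **PWeight** = VarUse/VarCall, **WAccuracy** = Accuracy × PWeight,

   where VarCall counts variants with any output and VarUse counts usable
   calls; WAccuracy ≡ (TP+TN)/VarCall penalizes low-coverage programs.
4. **Consensus** (`predbench.consensus`) — the three-program combination
   scheme (all-correct / two-correct / two-incorrect / all-incorrect /
   inconsistent / excluded-for-missingness) plus pairwise concordance.
5. **Synthetic data** (`predbench.synthetic_data`) — a seeded generator of
   prediction matrices with per-program call rates, "possible" rates,
   reliability distributions and class-conditional correctness, plus a
   deterministic fixture builder that realizes any confusion-matrix
   composition exactly.

## Worked example

Evaluate a predictor from its confusion composition on two panels and pool:

```python
from predbench import (build_fixture, tabulate, compute_metrics,
                       metrics_table, pool, round_report)

ras  = build_fixture(28, 0, 16, 0, n_possible=9, program="MutPred", panel="RAS")
lgmd = build_fixture(31, 3, 25, 2, n_possible=7, program="MutPred", panel="LGMD")
summaries = [tabulate(b.harmonized(), b.labels, "MutPred", panel)
             for b, panel in [(ras, "RAS"), (lgmd, "LGMD")]]
summaries.append(pool(summaries)["MutPred"])
table = metrics_table(summaries)
print(table[["Dataset", "PPV", "NPV", "Specificity", "Sensitivity",
             "Accuracy", "PWeight", "WAccuracy", "VarUse", "VarCall"]]
      .to_string(index=False))
m = compute_metrics(summaries[-1])
print(f"pooled weighted accuracy: {round_report(100 * m.waccuracy, 1)}%")
```

prints

```
 Dataset   PPV   NPV  Specificity  Sensitivity  Accuracy  PWeight  WAccuracy  VarUse  VarCall
     RAS 1.000 1.000        1.000        1.000     1.000    0.830      0.830      44       53
    LGMD 0.912 0.926        0.893        0.939     0.918    0.897      0.824      61       68
combined 0.952 0.953        0.932        0.967     0.952    0.868      0.826     105      121
pooled weighted accuracy: 82.6%
```

On the RAS panel every emitted dichotomous call is correct (Accuracy 1.000)
but 9 of 53 outputs are "possible" calls, so the coverage-weighted accuracy
drops to 0.830. Pooling sums the confusion counts across panels (never
averages per-panel metrics), giving 100 correct usable calls out of 121
variants with output — 82.6%.

A full pipeline is also exposed as a CLI:

```sh
predbench simulate --seed 4 --out-dir sim/
predbench evaluate --variants sim/variants.tsv --predictions sim/predictions.tsv \
    --consensus-programs ProgA,ProgB,ProgC --out-dir report/
```

which writes per-panel and combined metric tables, a per-class correctness
table, consensus categories and summary, and a run log with the filtering
counts (variants in ≥ with output ≥ reliable ≥ usable) for every program.

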