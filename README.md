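# mbstates

Robust microbiome **state** identification from OTU/taxon abundance tables.

`mbstates` clusters samples of a (typically longitudinal) microbiome study
into data-driven community states, and only reports a clustering when it
survives an internal robustness assessment. The procedure:

1. **Distances** — five abundance-based beta-diversity dissimilarities:
   Jensen-Shannon distance (`jsd`, base 2), its square root (`rjsd`),
   Bray-Curtis, Morisita-Horn and Kulczynski.
2. **Clustering** — two deterministic distance-matrix algorithms:
   PAM (k-medoids with greedy BUILD and best-improvement SWAP) and
   UPGMA hierarchical clustering, each for k = 2..10.
3. **Assessment** — every (algorithm, distance, k) combination is scored by
   average silhouette width (SI), split-half prediction strength
   (PS, 100 repetitions) and bootstrap cluster stability measured by Jaccard
   set similarity (100 resamples).
4. **Selection** — metric *pairs* are ranked by average SI (both members must
   exceed 0.25); scanning in rank order, a candidate k is accepted when its
   leading metric passes PS > 0.80 **or** Jaccard ≥ 0.75 and no cluster is
   smaller than 5 samples. If no candidate passes, the explicit outcome is
   "no robust states", with a full decision trail either way.

With the defaults this evaluates 90 combinations and
90 × (1 SI + 100 PS + 100 Jaccard) = 18,090 scored clustering executions
per dataset.

## CLI

```bash
# generate a synthetic dataset with 3 planted states
mbstates simulate --n-states 3 --samples-per-state 40 --separation 50 \
    --seed 7 --out-prefix demo

# run the full pipeline (BIOM v1/v2 or TSV input)
mbstates run --input demo.tsv --metadata demo_metadata.tsv \
    --seed 7 --outdir out/

# re-render the assessment figure from the saved table
mbstates plot --assessment out/assessment.csv --algorithm pam --out fig.png
```

`run` writes, per algorithm: an assignments CSV (`sampleID,clusterID`), a
decision-trail JSON, the tidy assessment CSV, the three-panel SI/PS/Jaccard
figure, a PCoA ordination colored by state, and (when the metadata carries
`subject_id`/`time_index`) a subjects × time state-sequence diagram.
`--lazy` scores PS/Jaccard only for candidates reached during the selection
scan — much faster and decision-equivalent, since every grid combination
draws from its own coordinate-keyed random stream.

Inputs: BIOM v1 (JSON), BIOM v2 (HDF5), or a TSV OTU table (taxa as rows,
samples as columns, optional trailing semicolon-delimited `taxonomy`
column), plus an optional metadata TSV with a `sample_id` column. Raw counts
are total-sum scaled internally; `--filter dominant|nondominant` and
`--aggregate-level genus` subset/aggregate taxa before clustering.

## Python API

```python
from mbstates import (SyntheticSpec, generate_states_dataset,
                      SelectionConfig, run_pipeline)

table, truth = generate_states_dataset(SyntheticSpec(n_states=3, seed=1))
result = run_pipeline(table, SelectionConfig(rng_seed=1))
states = result["pam"]
print(states.outcome, states.k, states.chosen_metric)
```

## Layout

- `src/mbstates/data_model.py` — abundance table, BIOM/TSV I/O, normalization,
  dominance filtering, taxonomic aggregation
- `src/mbstates/beta_diversity.py` — the five dissimilarities and distance matrices
- `src/mbstates/clustering.py` — PAM and UPGMA on distance matrices
- `src/mbstates/validation.py` — silhouette, prediction strength, Jaccard stability
- `src/mbstates/selection.py` — assessment grid and decision algorithm
- `src/mbstates/reporting.py`, `src/mbstates/cli.py` — figures, PCoA, CLI
- `src/mbstates/synthetic.py` — Dirichlet-multinomial generators with planted states
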