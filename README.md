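# rxseq

Clustering of longitudinal biologic/targeted-synthetic DMARD prescription
histories with a mixture of first-order Markov chains.

The pipeline turns EHR-style prescription records into per-patient drug-class
state sequences (five classes: TNFi, CTLA4-Ig, IL6R, JAKi, anti-CD20),
clusters those sequences with an EM-fitted mixture of Markov chains, selects
the number of clusters by AIC with a Calinski-Harabasz cross-check, and
profiles the resulting clusters against CDAI disease-activity trajectories.
A synthetic cohort generator with a known ground-truth mixture makes every
stage testable without access to clinical data.

## Layout

| module | role |
| --- | --- |
| `rxseq.synthetic` | EHR-style cohort simulator (prescriptions, RA diagnosis codes, CDAI visits) from a known mixture of Markov chains; presets `paper_default` (4 components) and `single_class` |
| `rxseq.sequences` | cohort inclusion filters and 3-month-window encounter rules turning prescriptions into state sequences |
| `rxseq.mixture` | likelihood, EM estimation, posterior assignment, component matching, model JSON serialization |
| `rxseq.selection` | free-parameter counting, AIC, yearly-rate features, Calinski-Harabasz score, candidate-K selection |
| `rxseq.profiles` | cluster composition summaries, yearly CDAI means, one-way ANOVA, Kruskal-Wallis |
| `rxseq.pipeline` / `rxseq.cli` | end-to-end orchestration with one seed, YAML config, and per-stage CLIs |

## CLI

Every stage runs standalone:

```bash
rxseq simulate --preset paper_default --n 2000 --seed 1 --out data/
rxseq build-sequences --rx data/prescriptions.csv --dx data/diagnoses.csv \
    --out built/ [--no-icd-filter]
rxseq select-k --sequences built/sequences.csv --k-min 2 --k-max 5 \
    --restarts 20 --seed 1 --out sel/
rxseq fit --sequences built/sequences.csv --k 4 --restarts 20 --seed 1 \
    --out model.json
rxseq assign --model sel/model.json --sequences built/sequences.csv \
    --out assignments.csv
rxseq profile --sequences built/sequences.csv --assignments assignments.csv \
    --visits data/visits.csv --out prof/
```

or chained from one YAML config:

```bash
rxseq run --config config.yaml
```

```yaml
# config.yaml
seed: 1
output_dir: out
simulate: {preset: paper_default, n_patients: 2000}
filter: {study_start: 2008-01-01, require_icd: true}
fit: {k_candidates: [2, 3, 4, 5], n_restarts: 20}
```

## Notes

- Sequence construction: 91-day windows from the first prescription; empty
  windows contribute no state; within a window consecutive equal classes
  collapse; repeats across window boundaries are retained.
- Inclusion filters: first prescription on/after the study start, an RA
  diagnosis code >= 90 days prior (optional, off in sensitivity mode), and
  two prescriptions >= 90 days apart.
- EM uses per-sequence sufficient statistics pooled over identical sequences,
  flat-Dirichlet restarts, and a small transition pseudocount (1e-6).
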