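# semflow

Knowledge-graph-backed composition, execution, and reward learning for
semantically registered machine-learning microservices.

## The problem

Biomedical data analysis is rarely one model call: a clinical
classification task needs loading, partitioning, model fitting, and
feature optimization; a single-cell RNA-seq clustering task needs loading,
quality control, normalization, embedding, and clustering. `semflow`
treats each of these capabilities as a *microservice* described by a
nine-parameter semantic record (name, description, framework,
dependencies, typed input/output ports, category, license, invoke path)
and keeps everything the system learns — service descriptions, task
contexts, outcome policies, and reusable world facts — as triples in a
partitioned knowledge space that serializes to N-Triples or Turtle.

Given a task (input data kind, free-text domain, desired output kind, plus
a dataset), the framework:

1. **searches its policy knowledge** — an *exact* context match reloads the
   recorded solution with no planning; a *transferable* match (same task,
   different dataset schema) re-executes the recorded workflow on the new
   data, retraining every stage (composition transfer learning);
2. **otherwise composes** — it enumerates every simple chain of
   I/O-compatible services from the input kind to the desired output kind
   (a DFS over the data-kind digraph), ranks candidates by length,
   accumulated reward, and a lexicographic tie-break, and executes them;
3. **learns from the outcome** — a successful *n*-step workflow rewards
   each service exactly 1/*n* (rational arithmetic, so conservation is
   exact); a failed run still rewards each of its *m* surviving steps
   1/*m*, so partially working services gain priority in later searches.
   Selected feature subsets are banked as world knowledge keyed by the
   table schema and reused (the optimizer stage becomes a projection) when
   an identical schema returns.

## Worked example

```python
from pathlib import Path
from semflow import bootstrap, run_task, RunConfig
from semflow.synth import make_heartlike_table, make_parkinsonlike_table, table_to_csv

Path("heart.csv").write_text(table_to_csv(make_heartlike_table(335, seed=1)[0]))
Path("parkinson.csv").write_text(table_to_csv(make_parkinsonlike_table(300, seed=2)[0]))

space, registry = bootstrap()            # nine default services
request = {"input_kind": "csv_path", "domain": "medical",
           "desired_output_kind": "optimized_model"}
cfg = RunConfig(seed=7, top_k=1)

first = run_task(space, request, data_path="heart.csv", config=cfg)
print(first.route, first.chosen[0].steps, round(first.chosen[1].metric, 3))

second = run_task(space, request, data_path="parkinson.csv", config=cfg)
print(second.route, second.planner_invocations, round(second.chosen[1].metric, 3))
```

prints

```
planned ('csv_loader', 'data_split', 'classification_pipeline', 'rfecv_optimize') 0.851
transfer 0 0.833
```

The first run had no prior knowledge, so the planner composed the 4-step
classification workflow and recorded a success policy (each service earned
reward 1/4). The second task differs only in its dataset schema, so the
framework matched the stored context at the *transferable* level and
re-executed the recorded workflow on the new table with zero planner
invocations; the printed numbers are test-set accuracies on the synthetic
tables. Submitting the heart task again would match *exactly*, skip
planning, and — because the optimizer's selected features were banked as
world knowledge — replace the elimination loop with a column projection.

The same loop drives the single-cell scenario: `bootstrap(single_cell=True)`
adds loading, QC, normalization, three embedding alternatives (PCA, t-SNE,
UMAP) and two clustering services (k-means, kNN-graph greedy modularity);
the planner finds six 5-step candidates, and pinning the embedding stage
to UMAP (`Preference((("embedding", "umap_embedding"),))`) leaves exactly
two.

A `semflow` console script exposes the same loop from a shell
(`init`, `register`, `submit [--dry-run] [--prefer KIND=SERVICE]`,
`knowledge`, `replay`, `fixtures`).

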