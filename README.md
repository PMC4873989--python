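# pathprofiler

Mechanism-of-action (MOA) prediction from bioactivity fingerprints.

## The problem

Phenotypic screening finds compounds by what they *do* to cells, not by what
they *bind*. Identifying the molecular target afterwards is the hard part.
One practical answer is pathway profiling: test every compound at a single
concentration across a panel of cellular assays — pathway-reporter readouts
(each contributing percent inhibition with ligand stimulation and percent
activation without it) plus proliferation readouts — and treat the resulting
activity vector as a *bioactivity fingerprint*. Compounds that act through
the same target produce correlated fingerprints even when their chemical
structures are unrelated, so a well-annotated reference panel lets you read
off a probable target for a novel compound from its bioactive neighbors.

`pathprofiler` implements that pipeline for computational chemists and
screening groups:

* **Panel assembly and normalization** — dense compounds × assay-readouts
  percent-activity matrices; per-assay Z-scoring
  `z_ij = (x_ij − μ_j) / σ_j` (population σ).
* **Clustering** — Ward's minimum-variance agglomeration on Euclidean
  distances, with an explicit merge list, deterministic tie-breaking, tree
  cutting, and adjusted-Rand-index evaluation.
* **Bioactivity similarity** — Pearson's correlation between activity
  profiles,
  `Rp = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / (√Σᵢ(xᵢ−x̄)² √Σᵢ(yᵢ−ȳ)²)`,
  over the N panel readouts (N = 39 in the default panel).
* **Structural similarity** — hashed linear atom-bond-path fingerprints
  (an open Daylight-style scheme: paths of 1–7 atoms, 2048 bits, stable
  blake2b hash) compared by the Tanimoto coefficient |A∩B|/|A∪B|.
  Precomputed fingerprints from any toolkit can be substituted.
* **Target prediction** — rank database neighbors by Rp, keep those strictly
  above a threshold (default 0.8), and call the target by majority vote over
  the annotated neighbors. Structural similarity is reported but never
  votes.
* **Screen statistics** — plate percent-activity from control windows, the
  high-content screening hit filter (fold change of mean per-cell cytosolic
  area, inclusive ≥ 2-fold threshold), and four-parameter logistic (4PL)
  dose-response fitting, `y = bottom + (top − bottom)/(1 + (c/IC50)^h)`,
  for IC50 confirmation.
* **Synthetic databases** — generators that plant known MOA classes (sparse
  assay signatures plus Gaussian noise), structures with controllably high
  or low within-class Tanimoto, per-cell area tables, and dose-response
  curves, so the whole pipeline is testable with ground truth.

## Worked example

A synthetic 1910-compound × 39-assay database with planted MOA classes, a
held-out query compound drawn from an unannounced class, and the
neighbor-vote call:

```python
from pathprofiler import (generate_target_id_scenario, rank_neighbors,
                          predict_target)

matrix, annotations, query, truth, target = generate_target_id_scenario(seed=1)
report = rank_neighbors(query, matrix, threshold=0.8, annotations=annotations)
print(f"database: {matrix.shape[0]} compounds x {matrix.shape[1]} assays")
print(f"neighbors with Rp > 0.8: {report.n_neighbors}")
for row in report.rows[:4]:
    print(f"  {row.compound_id}  Rp={row.rp:.3f}  {row.annotation}")
pred = predict_target(report)
print(f"predicted target: {pred.predicted_target}")
print(f"vote: {pred.vote_fraction:.3f} ({len(pred.supporting_compound_ids)}"
      f" of {pred.n_annotated} annotated neighbors)")
```

Output:

```
database: 1910 compounds x 39 assays
neighbors with Rp > 0.8: 12
  N008  Rp=0.980  tubulin disruptor
  N009  Rp=0.976  tubulin disruptor
  N004  Rp=0.973  tubulin disruptor
  N002  Rp=0.973  tubulin disruptor
predicted target: tubulin disruptor
vote: 0.833 (10 of 12 annotated neighbors)
```

Twelve database compounds correlate with the query above Rp 0.8; ten of the
twelve carry the tubulin-disruptor annotation, so the majority vote (10/12 =
0.833 of annotated neighbors) calls the query a tubulin disruptor — even
though, in this scenario, the query's Tanimoto structural similarity to every
one of those neighbors is below 0.3.

The same stages are available from the shell:

```sh
pathprofiler simulate --out-dir db --seed 1
pathprofiler build --activity db/activity.csv --k 13 --out build
pathprofiler query --activity db/activity.csv --annotations db/annotations.csv \
    --query-id C0001 --threshold 0.8 --out report.csv
pathprofiler screen --areas areas.csv --threshold 2.0 --out hits.csv
pathprofiler fit --doseresponse curve.csv --out fit.json
```

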