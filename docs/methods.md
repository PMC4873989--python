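# Methods

## The profiling model

A pathway-profiling database is a dense matrix of percent-activity values:
rows are compounds tested at a single concentration, columns are assay
readouts. The default panel has 39 readouts — 15 pathway-reporter signals
measured in two modes each (percent inhibition with ligand stimulation and
percent activation without it), 8 proliferation/viability readouts in
different cell lines, and one additional single-mode reporter readout. Any
panel width ≥ 2 is accepted; 39 is only the default, and the two-mode
reporter convention is why a 15-signal panel does not divide evenly into it.

Percent activity is computed from plate control windows:
`inhibition% = 100·(1 − (S − B)/(S⁺ − B))` and
`activation% = 100·(S − B)/(S⁺ − B)`, with `B` the background (no-ligand or
vehicle) control mean and `S⁺` the stimulated (or reference-agonist, or
vehicle-growth) control mean. These two readouts are complementary by
construction: within the control window, inhibition% + remaining% = 100.
A zero control window is an error — there is no meaningful scale to report
on.

### Normalization

Each assay column is Z-scored across compounds: `z = (x − μ_j)/σ_j` with the
*population* standard deviation (÷ n). The population/sample choice is a
convention; it is fixed here so that normalized matrices are exactly
reproducible. Zero-variance columns (assays in which nothing was active)
are mapped to all-zeros and flagged rather than raised on: an uninformative
assay should not abort a database build. Normalized matrices must satisfy
|mean| < 1e-9 per column and |sd − 1| < 1e-9 for non-constant columns; this
is enforced at construction.

### Clustering

Ward's minimum-variance agglomeration on Euclidean distances, implemented
with the Lance–Williams recurrence on squared distances and heights reported
on the distance scale. Two "Ward" conventions circulate in software; this
package follows the one where merging two singletons has height equal to
their Euclidean distance, and generally
`d²(A,B) = 2|A||B|/(|A|+|B|)·‖μ_A − μ_B‖²` (the same convention as scipy's
`linkage(method="ward")`, against which the implementation is cross-checked
in tests). Exact ties in the merge objective are broken by the
lexicographically smallest cluster-id pair (leaves are ids 0..n−1, merged
clusters n, n+1, …), which makes trees deterministic at the cost of
row-order dependence *for exact ties only*. Flat clusters come from cutting
the merge list to a user-chosen count k — the reference visual-clustering
workflow defines no cut rule, so k is an explicit parameter (a reasonable
default is the number of distinct annotation labels). Cluster recovery is
scored with the adjusted Rand index (delegated to scikit-learn behind the
package's validating wrapper; tests verify it against brute-force pair
counting).

### Similarity

Bioactivity similarity is Pearson's Rp between two activity profiles over
the panel readouts. A constant profile raises an error instead of returning
NaN — a silent NaN would corrupt neighbor rankings; constant *database* rows
are reported as undefined and excluded from ranking. Rp is computed on the
activity values as given. The workflow default is the raw percent-activity
matrix (the CLI exposes `--zscore` to correlate standardized columns
instead): per-assay Z-scoring rescales assays in which nothing was active up
to unit variance, which dilutes the signature readouts that carry the MOA
signal and drags within-class correlations well below the 0.8 working
threshold the neighbor filter assumes. Per-compound affine changes do not
affect Rp either way.

Structural similarity is the Tanimoto coefficient on hashed-path bit
fingerprints. The classic commercial hashed-path fingerprint is proprietary,
so the package implements an open variant: enumerate all simple linear
atom paths of 1..7 atoms (heavy atoms only; element symbols, lower-cased
when aromatic; bond labels `- = # :`), represent each path by the
lexicographically smaller of its two traversal directions (making the
result independent of atom numbering), and set bit
`blake2b(path, 8 bytes) mod 2048` per distinct path string. Published
similarity ranges from proprietary fingerprints are treated as scenario
descriptors, not reproduction targets; precomputed fingerprints can be
supplied wherever the package accepts a `Fingerprint`. Two empty
fingerprints have Tanimoto 0 by definition.

### Target prediction

Neighbors are database compounds with Rp *strictly above* the threshold
(default 0.8), sorted by Rp descending with ties broken by compound id. The
target call is the majority annotation among annotated neighbors;
unannotated neighbors carry no target signal and abstain, so the vote
fraction is reported over annotated neighbors and the annotated/total
coverage alongside it. No annotated neighbors, an empty neighbor set, or a
tied vote yield `no_prediction` (ties list the tied labels) — these are
results, not errors. The majority-vote formalization is this package's
decision; the underlying screening practice is narrative ("most of the
close neighbors share annotation X"). Note the deliberate asymmetry with
the screen filter: neighbor retention is strict (> threshold), hit selection
is inclusive (≥ threshold), each following the usage its stage mirrors.

### Dose-response fitting

The 4PL model `y = bottom + (top − bottom)/(1 + (c/IC50)^h)` is fitted by
least squares on log-concentration internally (the free midpoint parameter
is log IC50, which keeps the problem well-scaled over decade-spanning
grids), with three starts seeding the midpoint at the 25/50/75% quantiles
of log concentration and the Hill sign chosen from the data's slope; the
best residual sum of squares wins. Fits are canonicalized to h > 0 by the
identity (bottom, top, h) → (top, bottom, −h), so IC50 is always the
midpoint and top ≥ bottom means inhibition. A response range below 1e-9
relative to scale is a degenerate fit (error); non-convergence is reported
honestly in the `converged` flag. Requires ≥ 5 distinct concentrations.

## The synthetic-data generator

Real profiling databases are proprietary, so the generator plants the
statistical structure the analysis assumes:

* Each MOA class has a fixed signature: `round(sparsity × n_assays)`
  readouts carrying ±`signature_scale` percent activity with random signs
  (panels mix inhibition and activation readouts, so signs are arbitrary).
* A member's profile is its class signature plus iid Gaussian noise per
  readout; inactive compounds are pure noise. Gaussian noise is the
  simplest model consistent with standardized percent-activity data;
  heavier-tailed options are out of scope.
* "Detectable activity" is |value| ≥ 3 × noise_sd in ≥ 1 readout.

Defaults (chosen once, as study conditions): 13 classes × 98 members + 636
inactives = 1910 compounds; 39 assays; noise_sd 10 percent-activity units;
signature_scale 50 (five sigma); sparsity 0.25, i.e. ~10 of 39 readouts per
class — the scale of a cytotoxic mechanism lighting up all eight
proliferation readouts plus a few stress-responsive reporters. Under these
conditions the detectable-active fraction is structural, not tuned: an
inactive compound clears 3σ somewhere in 39 readouts with probability
1 − (1 − 0.0027)³⁹ ≈ 0.100, so the expectation is
(1274 + 0.100·636)/1910 ≈ 0.700 (measured 0.701 ± 0.005 over 20 seeds).

Structure generation is independent of activity by design. `diverse` mode
draws 64 random bits of 2048 per compound (expected unrelated-pair Tanimoto
≈ 64/(2·2048 − 64) ≈ 0.016), modelling compounds that share a mechanism but
not a scaffold; `analog` mode gives each class a core bit-set whose bits
members mutate with probability 0.05, modelling a scaffold series (expected
within-class Tanimoto ≈ 0.8). The target-identification scenario plants a
held-out class with 12 high-correlation neighbors, 10 of them annotated with
the true target, inside a full-scale background database; neighbor and
query noise is fixed at 0.1 × signature_scale, deep in the high-similarity
regime, so the count of neighbors above Rp 0.8 is measured, not asserted.

Screen simulation draws per-cell areas from a lognormal (strictly positive
and right-skewed, like real morphology data) with log-sd 0.45 around a mean
of 1500 area units, 200 cells per well, 16 pooled vehicle wells; hits scale
the arm mean by 2.5. Fold change is the ratio of arm means — cells are not
paired between arms, so per-cell ratios are undefined; whether a real screen
would use per-well medians instead is unknowable from the outside, and
mean-of-cells is documented as the choice.

All generators are pure functions of their parameters and seed.

What the generator does *not* emulate: correlated assay noise and plate
effects (edge/row artifacts, batch drift), compound-concentration errors,
partial-efficacy class members, overlapping polypharmacology, and any
pharmacophore-realistic chemistry. Passing tests therefore demonstrate that
the pipeline's statistics behave as designed under the planted model — not
that a particular proprietary database would yield the same headline
numbers.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the clustering-recovery
experiment at 5 classes × 20 compounds (20 seeds), the prediction-recovery
experiment at 100 queries × 10 seeds, the screen at 1408 compounds × 200
cells, and dose-response recovery over 100 noise seeds — sizes at which each
estimate's Monte-Carlo error is well inside the margins being checked,
while a full run stays in seconds. Oracle agreement (Pearson, Ward,
Tanimoto, ARI) is asserted to 1e-9..1e-12 absolute; noise-free 4PL recovery
to 1e-6 relative; normalization contracts to 1e-9.

## Known limitations

* Tanimoto values from the built-in hashed-path fingerprint are not
  bit-compatible with any commercial fingerprint; only supplied-fingerprint
  workflows are comparable across toolkits.
* The Ward implementation is O(n³) with an O(n²) distance matrix — fine for
  databases of a few thousand compounds, not for hundred-thousand-compound
  collections.
* Concentration units are tags, never converted (μg/mL ↔ μM needs molecular
  weights, out of scope), and no plate-effect or B-score correction is
  applied before profiling.
* The vote rule weights all annotated neighbors equally; no
  confidence model or multi-target deconvolution is attempted.
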