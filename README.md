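# erptopo

Randomization statistics for multichannel event-related potentials (ERPs):
topographic consistency testing, topographic analysis of variance (TANOVA)
with global corrections for multiple testing over time, GFP tests,
channel-wise t-maps, MDS-based outlier screening and microstate analysis.

## Who this is for

Groups analyzing averaged multichannel ERP data (one time × channel matrix
per subject and condition) who want statistics that use *all* sensors at
once instead of picking channels and windows a priori.  The scalp field at
one moment is treated as a single multivariate observation — a point in an
n-channel state space — and every test asks how far such points, or their
condition means, lie apart, with significance assessed by permutation.

## The statistics

With average-referenced maps (channel mean 0), the strength of a map
`v = (v_1 … v_n)` is its **global field power**, the population standard
deviation across channels:

    GFP = sqrt( Σ_j (v_j − v̄)² / n )

The distance between two maps — the GFP of their difference map — indexes
how much the underlying source configurations differ.  On top of this:

* **TCT (topographic consistency test)** — per time point and condition,
  the GFP of the grand-mean map across subjects is compared with grand
  means computed after shuffling each subject's potentials across
  channels (which preserves every subject's own GFP but destroys spatial
  structure).  Large grand-mean GFP ⇒ subjects share a topography.
* **TANOVA** — per time point and effect (≤2 within-subject factors,
  optional between-subject groups), the effect size is

      dGFP = sqrt( Σ_i Σ_j (v̄_ij − v̄̄_j)² / n )

  over the c factor-level mean maps; the null shuffles factor levels
  within subjects (and group labels across subjects).  Optional per-map
  GFP normalization isolates *qualitative* (topographic) effects; the
  discarded scaling factor is tested separately by the parallel **GFP
  test** (*quantitative* effects).
* **Overall statistics** — the TANOVA's own permutation runs are recycled
  into null p-series (each run ranked against the other runs), and the
  count of sub-threshold time points, the longest sub-threshold duration,
  or Fisher's −2 Σ ln p of the observed p-series is tested against the
  same quantity in the null runs: a global correction for multiple
  testing over time that respects the (unknown) temporal dependence.
* **t-maps** — post-hoc channel-wise paired/unpaired t statistics of
  window-averaged contrasts, with the TANOVA p of the same contrast.
* **Microstates** — modified k-means or AAHC clustering of grand-mean
  maps into k template maps, cross-validated choice of k (split-half
  subjects, test-set explained variance), label smoothing, and
  randomization tests on per-class quantifiers (onset, offset, duration,
  AUC, center of gravity, mean GFP) across design cells.

All permutation p-values use the add-one convention `(1+b)/(n+1)`.

## Worked example

Simulate a 16-subject study (30 channels, 100 samples at 250 Hz) in which
condition B's first source map is rotated by 40° in topography (a purely
qualitative effect), then test it:

```sh
erptopo simulate study --subjects 16 --channels 30 --timepoints 100 \
    --templates 3 --rotation "B=40" --seed 7
erptopo tanova study --design study/design.json --runs 1000 --seed 11 \
    --null-archive null.npz --out tanova.tsv
erptopo overall null.npz --out overall.tsv
```

`overall.tsv` prints:

```
# n_runs=1000	seed=11	p_threshold=0.05	normalize=0
effect	kind	observed	p	duration_threshold_ms
condition	count	33	0.001998001998
condition	duration	112	0.001998001998	20
condition	fisher	515.7100507	0.000999000999
```

Reading: 33 of 100 time points were individually significant — a
contiguous 12–120 ms period (where the rotated map is active) plus five
isolated later points.  The longest sub-threshold period lasted 112 ms,
far beyond the 20 ms that chance runs of sub-threshold points reach at
the 5% level (`duration_threshold_ms`), so the effect survives every
overall correction (all overall p < 0.002).  The five isolated points are
exactly the false positives the overall statistics exist to discount.

The same workflow continues with `erptopo gfptest` (strength effects),
`erptopo tmap` (where on the scalp), and `erptopo microstate
cluster|cv|fit` (when which map is active).  Every output TSV records
n_runs, seed, p-threshold and normalization in its header; identical
config and seed reproduce outputs bit-exactly.

## Library use

```python
import erptopo as et

ds, truth = et.generate_dataset(et.SyntheticSpec(seed=1))
design = et.define_design({"cond": {"A": 1, "B": 2}}, ds.condition_tags)
res = et.tanova(ds, design, et.RandConfig(n_runs=1000, seed=2))
count = et.overall_test(res, "cond", "count")
```

Microstate clustering follows the scikit-learn estimator protocol
(`MicrostateKMeans`, `MicrostateAAHC` with `fit` / `predict` /
`get_params`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a synthetic study from the given seed and runs every analysis
stage end-to-end — screening, TCT, TANOVA with all three overall
statistics, GFP test, t-mapping, microstate clustering,
cross-validation and quantifier statistics — printing a summary of the
recomputed quantities and writing the JSON result file.
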