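# Methods

This note documents the models, defaults and numerical choices behind
`radtx`, in the order the pipeline runs them.

## Study design and synthetic data

The default design mirrors a six-arm combined-modality animal experiment:
one control arm, one endoradiotherapy (EndoRT) arm, photon- and carbon-ion
external-beam (EBRT) arms, and the two combined arms (PERT/CERT), three
arrays per arm. The two radiation qualities are pooled into a single
*EBRT* category — and likewise the two combined arms — because the gradual
response profile orders treatment *intensity* (EndoRT-only < EBRT-only <
combined), not radiation quality; the arm → category map is configurable
when a study needs to separate them.

### Expression matrix

Intensities are drawn on the natural-log scale and exponentiated, so they
are positive by construction (the intensity distribution of the underlying
bead arrays is not modelled mechanistically; a log-normal is the standard
stand-in for array intensities). Per gene:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2,000 | desk-scale transcript count (a whole-genome chip has ~48,000 probes; 2,000 keeps the full pipeline in seconds while preserving all statistical structure) |
| `baseline_log_mean`, `baseline_log_sd` | 7.0, 0.8 | log-intensity of a gene's baseline (median ≈ 1,100 a.u., comfortably above the background threshold of 100) |
| `frac_up_gradual`, `frac_down_gradual` | 0.05, 0.05 | planted fractions following the gradual profile and its mirror |
| `effect_step` | 2.0 | multiplicative step per template level: an up-gradual gene has expected arm means baseline × 2/4/8 for EndoRT/EBRT/combined |
| `noise_log_sd` | 0.25 | per-observation multiplicative noise (≈ 25% CV), a realistic replicate-level spread for bulk arrays; the source study does not report its replicate variance, so this is a free parameter, not an estimate |
| `missing_rate` | 0.02 | non-assessable reads, missing completely at random (the real "non-assessable" mechanism is detector-side and unspecified; MCAR is the neutral choice) |
| `low_intensity_frac`, `low_intensity_log_mean` | 0.10, 2.0 | genes planted below the intensity filter (≈ 7 a.u., far below the background level of 100) |

Truth labels (`up_gradual`, `down_gradual`, `null`, `low_intensity`)
partition the genes. With zero noise the arm-category means of an
up-gradual gene are exactly in ratio 1 : 2 : 4 (EndoRT : EBRT : combined),
which the tests use as a closed-form check.

### Interaction graph and gene sets

The planted module is a *path* through `module_size` (default 20)
up-gradual genes — connected with the minimal number of edges, which makes
it the hardest connected topology to detect and gives a clean closed-form
edge count. Background edges are Erdős–Rényi with probability
`extra_edge_prob` (default 0.001, i.e. ≈ 2 expected background neighbours
per node at 2,000 genes — sparse, like a curated direct-interaction
database restricted to a selection-sized gene set). One gene set
(`set_planted`) is drawn entirely from up-gradual genes by default; the
other 19 sets are uniform draws of 10–50 genes.

### Efficacy tables

Tumor growth is exponential with an arm-specific doubling time
(control 2.5 d, EndoRT 3 d, EBRT 6 d, combined 14 d, volumes from 86 mm³ —
a fast-growing xenograft whose combined-treatment arms are nearly
arrested), log-normal noise of 0.10 on volume, and caliper width/length
back-computed so that (width² × length)/2 reproduces the volume.
Biodistribution draws mean-preserving log-normal %ID/g per organ around
tumor 9.0, muscle 9.0/107.6 (tumor-to-muscle ratio 107.6), spleen 2.4,
liver 0.6, kidney 0.5, lung 0.5, for 11 animals. The dispersion
(log-sd 0.45, CV ≈ 0.47) treats the reported spread of tumor uptake
(±4.2 around 9.0) as a sample standard deviation; reading it as a standard
error of the mean at n = 11 would imply a CV of ≈ 1.5, implausible for
strictly positive uptake values. At n = 11 the estimated tumor-to-muscle
ratio consequently carries roughly ±20% sampling error — matching the
precision such a biodistribution experiment actually has.

### What the generator does *not* emulate

No probe chemistry, batch or chip effects, no spatial or image-level data,
no informative missingness, no correlation between genes beyond the planted
module/set structure. Passing tests therefore demonstrate that the
*statistical machinery* is correct under its stated model, not that the
pipeline is robust to array artefacts absent from the model.

## Preprocessing

* **Detection filter:** genes with ≥ 30% non-assessable reads are excluded;
  retention is *strict* (< 0.30), so a gene missing in exactly 30% of
  samples is dropped — the boundary case follows the "30% or more" reading.
* **Intensity filter:** mean over assessable reads ≥ 100, boundary
  *inclusive*. Genes with all entries missing have no mean and are dropped
  with a log message.
* **Normalization:** each gene is divided by its arithmetic mean over the
  control-arm samples; log2 of the ratio by default (symmetric up/down
  changes), raw ratios behind `log2=False`. The scale of the original
  analysis is not documented; log2 is this package's choice and the flag
  preserves the alternative. Genes with non-positive control means cannot
  be normalized and are excluded. Missing values are never imputed — all
  downstream means and correlations use pairwise deletion.

Both filters are idempotent, and normalization is scale-equivariant per
gene (property-tested).

## Template matching

The ANOVA screen (one-way across all arms, p < 0.01, top 500 by p) and
average-linkage Euclidean clustering of arm-mean profiles serve to
*derive and justify* the gradual template; the template correlation itself
runs over **all** filtered transcripts, not just the screened ones.
Clustering delegates to scipy's nearest-neighbor-chain linkage, which is
deterministic for a fixed input order; that ordering is the package's
determinism contract for equal-distance merges.

PTM correlates per-sample values against the sample-level template (levels
replicated within arms); an arm-mean mode is available behind a flag.
Control samples are excluded from the template domain — they are the
normalization baseline, and the 3-step profile spans treated categories
only. Significance uses t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom;
at the default design (15 non-control samples) r = 0.8 corresponds to
p ≈ 3.4 × 10⁻⁴, which is why the r ≥ 0.8 cutoff is conventionally paired
with p < 0.001 and r ≥ 0.7 with p < 0.01. Correlation is computed on log2
fold changes by default (the flag above propagates); r is invariant to
per-gene positive affine transforms and flips sign under negative scale,
both property-tested.

Degenerate inputs: genes constant over the template samples have undefined
r and are excluded with a log message, as are genes with fewer than three
paired observations; |r| is clipped to 1 before the t-transform and p is
floored at the smallest positive float.

## Enrichment

Upper-tail hypergeometric p per set, P[X ≥ k], validated against exhaustive
enumeration of all C(N, n) selections for universes up to N = 12.
Significance is declared at **raw** p < 0.05 (matching how such pathway
screens are conventionally reported); Benjamini–Hochberg adjusted values
are emitted as an extra column and are deliberately not the default
criterion. The universe is the set of transcripts surviving preprocessing
restricted to the collection's namespace. Results are sorted by p with
set-id tie-break for determinism. The population map is the binary
gene × significant-set membership matrix, rows and columns ordered by
average-linkage Euclidean clustering so shared genes form visible blocks.

## Interaction networks

The selection induces a subgraph with no interpolated intermediate nodes.
Components of ≥ 2 nodes are reported largest-first; each component's hub is
its highest-degree node, ties broken lexicographically. The largest
component's size is tested against a null of `n_perm` (default 999)
uniform node resamples of the selection size, with add-one correction
p = (1 + #{null ≥ observed})/(n_perm + 1), so p is bounded below by
1/(n_perm + 1) and the test is valid by construction. Uniform resampling
ignores the degree distribution of the actual selection; a
degree-weighted sampling variant is exposed behind a flag for sensitivity
analysis. Under a truly random selection the p-value is approximately
uniform (checked by a KS test over 200 replicates near the percolation
regime, where the largest-component statistic is well spread).

## Efficacy endpoints

Volumes use (width² × length)/2 with the width ≤ length convention
(swapped with a warning). Progression is the *first* measurement day the
volume reaches the threshold (500 or 1000 mm³ depending on the model) — no
interpolation between caliper days, so event times are discrete study
days; animals never crossing are censored at their last observation.
Kaplan–Meier curves and the log-rank test delegate to lifelines (standard
aggregated-risk-set tie handling); the median is the first time the curve
reaches 0.5, undefined (and flagged) when it never does. The two-sample
t-test is pooled-variance Student's by default, Welch behind a flag, with
the conventional significance annotations at p < 0.05 and p < 0.01.
Percent endpoints (growth inhibition, TMR change, network fractions) are
computed at full precision and rounded to integers only for reporting.

## Pipeline and reproducibility

All randomness flows from one top-level seed through named substreams
(expression, gene sets, interactions, efficacy, permutation) via
`numpy.random.SeedSequence.spawn`, so stages can be re-run independently
yet the full run is reproducible byte for byte. Every output file carries
a `# config_hash` / `# seed` header; the run log records version, seeds
and thresholds but no timestamps. The default problem size (2,000 genes,
18 arrays, 999 permutations) runs the full pipeline in a few seconds.

## Known limitations

* The permutation null model for component sizes is a package choice; the
  original analysis does not document its significance method, so its
  printed network p-values are not comparison targets.
* Headline transcript counts from the deposited arrays (e.g. 219 UpCor at
  r ≥ 0.8 of 26,307 transcripts) require the real array data and a
  contemporaneous interaction-database snapshot; the synthetic study tests
  the *properties* of the selection (recovery, false positives, nesting)
  rather than those counts.
* MCAR missingness and gene-independence are simplifications; see the
  generator caveats above.
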