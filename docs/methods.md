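# Methods

## Measurement model

A SILAC protein-painting experiment compares a stimulated (heavy) and a
vehicle (light) cell population after covalent labeling of exposed cysteine
thiols. Working throughout in log2 space, the model for a peptide's
heavy/light ratio is additive:

    log2 R(i,j,r) = a_i + c_{ij}·[j contains Cys] + ε_{ijr},  ε ~ N(0, σ²)

where `a_i` is protein *i*'s abundance change, `c_{ij}` the conformational
(thiol-accessibility) change of cys peptide *j*, and σ the per-replicate
measurement noise. Noncys peptides estimate `a_i`; subtracting their
per-replicate mean from each cys peptide yields the corrected cys ratio, an
unbiased estimate of `c_{ij}` whose SD is σ·√(1 + 1/m) for m quantified
noncys peptides. Correction is per replicate (not on replicate means) so
the downstream one-sample t-statistic sees independent replicate values.

Filtering precedes correction: keratin and other contaminants are removed
by identifier pattern (defaults `^Krt`, `^CON__`, `^REV__`), and proteins
must have ≥ 2 unique peptide sequences with ≥ 1 containing cysteine.
Modified/unmodified forms of one sequence are merged by per-replicate
median at ingestion, so "unique" is sequence-level. Proteins whose peptides
are all cys-containing cannot be corrected and are excluded with a logged
record — exclusion (rather than using cys peptides on both axes) keeps the
abundance and conformation readouts strictly disjoint. The noncys summary
is the arithmetic mean by default; a median mode exists because the
protocol wording ("average") admits either.

## Scaling and thresholds

Replicate corrected ratios are collapsed to `scaled = mean × (1 − p)`, p
from the two-tailed one-sample t-test against 0 (df = n − 1; at the design
n = 3, the tail probability has the closed form 1 − t/√(t² + 2), used as an
independent oracle in the tests). Degenerate-input conventions: identical
nonzero replicates take weight 1; all-zero replicates scale to 0; fewer
than two quantified replicates make the peptide unquantifiable. The weight
`1 − p` is the simplest function that scales a mean by the confidence of
its deviation from 0; it is exposed behind a single function so alternative
weights can be swapped in.

Thresholds come from a vehicle-vs-vehicle control experiment, fitted
separately for the cys (corrected) and noncys (raw) axes, and classification
uses strict inequalities: scaled > upper ⇒ exposed, scaled < lower ⇒
protected, otherwise unchanged (noncys outliers indicate abundance change
and never feed conformational calls). Two fitting methods are provided:

- **empirical** (default): central-coverage sample quantiles, e.g. the
  2.5%/97.5% quantiles at the default 95% coverage. This is the method that
  actually *contains* the nominal fraction of the control data: the scaled
  values are leptokurtic (excess kurtosis ≈ 1.6 at n = 3, because the
  weight compresses the center of the distribution more than the tails),
  and a Gaussian ±1.96·SD band contains only ≈ 92.8% of them.
- **gaussian**: mean ± z·SD with z the two-sided normal quantile
  (1.959964 at 95%). Provided for compatibility with the classical z-score
  framing; under-covers on the scaled scale as noted.

Fitting requires ≥ 30 finite control values with positive SD. No
multiple-testing correction is applied across peptides: control-calibrated
thresholds replace per-peptide significance testing by design.

## Cross-stimulus comparison

The comparison set contains proteins with ≥ 1 quantifiable cys call
(pre-thresholding) in *every* stimulus and ≥ 1 exposed/protected call in at
least one. Per protein and stimulus the summary is the signed max: the
scaled cys value of largest absolute magnitude with its sign (a tie in
magnitude breaks toward the positive value, a fixed deterministic rule).
The signed-by-magnitude reading was chosen over the literal signed maximum
because protein summaries must be able to be strongly negative (protected);
the literal signed maximum remains available via
`signed_max(values, by_magnitude=False)`. Intersection analysis partitions proteins by the
exact combination of stimuli in which they changed; degree is the size of
that combination. Stimulus-dimension hierarchical clustering (average
linkage, Euclidean) is a presentation helper only.

## Network clustering and enrichment

Interaction edges come from a STRING-style scored edge list; edges with
combined score strictly greater than 0.4 (medium confidence) are kept,
duplicates merged by max score, self-loops dropped. Comparison proteins
absent from the network are retained as isolated nodes. Communities are
found by greedy modularity maximization on a lexicographically ordered copy
of the graph (deterministic for identical inputs); divisive
edge-betweenness splitting, scanning the dendrogram for maximal modularity,
is available as `method="girvan_newman"`. Nodes in communities smaller than
`min_cluster_size` (default 3) are flagged orphans but keep their cluster
id, so the partition stays exhaustive.

Connectivity enrichment uses an explicit permutation null rather than any
proprietary test: the observed induced edge count is compared with the edge
counts of `n_perm` (default 999) uniform equal-size subsets of a background
protein set, and p = (1 + #{null ≥ observed}) / (n_perm + 1). The add-one
estimator bounds p below by 1/(n_perm + 1) and avoids zero p-values. This
is a size-matched, non-degree-preserving null; degree-preserving rewiring
is out of scope.

## Feature correlations

Protein response profiles are the signed-max vectors across stimuli
(Spearman over n = number of stimuli; with 5 stimuli the statistic is
coarse by construction and per-pair p-values are never used). Ranks use
average ties; zero-variance profiles give undefined correlations and those
pairs are excluded. For a feature, a pair is *inside* when both proteins
are members, *outside* when exactly one is; neither-member pairs are
discarded (provably irrelevant: they cannot enter any member's mean). Each
member's mean |R_s| per bin is computed, and features with ≥ 3 members
holding both means are tested with a paired two-tailed t-test of
inside − outside — paired because every protein contributes one value to
each bin; Welch's two-sample mode is available behind a flag. For the
direct-interaction feature the inside bin is instead the pairs that share
an edge. Stars follow the usual convention (* < 0.05, ** < 0.01,
*** < 0.001); a Benjamini–Hochberg column is emitted alongside for
transparency but does not gate the stars.

## Cytometry

Treated median fluorescence is divided by the mean of the matched vehicle
replicates (per batch when a batch column is present), and each compound's
normalized values are tested against a hypothetical mean of 1 with a
two-tailed one-sample t-test on the untransformed ratios. Zero-variance
inputs are flagged degenerate rather than tested.

## Synthetic data

The generators emulate the full input surface with known truth:

- **Peptide tables**: default 3 replicates, matching the experimental
  design; i.i.d. Gaussian log2-ratio noise with SD 0.2 — the source
  protocol does not report its empirical ratio scatter, so this is a
  package default chosen as a typical SILAC ratio CV (~15%), not a measured
  value. Abundance shifts apply to all peptides of a selected protein;
  conformation shifts (default 0.8 log2 units = 4σ, random sign per
  protein) to the cys peptides of proteins selected among those carrying
  both peptide kinds, so every planted effect is recoverable after
  correction. Optional uniform random dropout is the only missingness
  mechanism.
- **Networks**: planted-partition graphs (within-cluster edge probability
  p_in ≥ between-cluster p_out) with uniform scores in (0.41, 1.0], above
  the STRING cutoff.
- **Cytometry**: mean-preserving multiplicative log-normal noise, so the
  expected normalized treated value equals the planted fold effect.

What the simulations do **not** emulate: intensity-dependent ratio
variance, peptide-level missingness correlated with abundance, shared-peptide
(razor) ambiguity, correlated replicate effects, scale-free network
topology, and autofluorescence artefacts. Passing tests therefore
demonstrate the pipeline's statistical correctness under its stated model,
not robustness to every pathology of real LC-MS/MS data.

## Numerical and design choices

- All ratio math is in log2 space with the null at 0; raw MaxQuant ratios
  are log2-transformed at ingestion (nonpositive → missing).
- Multi-protein groups take the first accession — the simplest
  deterministic rule; razor-peptide logic is out of scope.
- Thresholds fit on scaled values (not replicate means), mirroring the
  treated-data path the thresholds are applied to.
- Test problem sizes: the calibration/coverage checks use ~4500 simulated
  proteins (≈ 10,500 cys peptides); community recovery uses 2×10-node
  planted partitions with p_in = 0.8, p_out = 0.02; permutation tests use
  999 resamples. These sizes make Monte-Carlo error small relative to the
  tolerances asserted.
- Seeded `numpy.random.default_rng` everywhere; identical configs are
  bit-reproducible.

## Known limitations

- Community structure on real interaction maps depends on the clustering
  implementation and resolution; exact cluster counts from any particular
  external tool are not expected to reproduce.
- The permutation enrichment null differs from STRING's analytical test;
  p-values are comparable in spirit, not numerically.
- Site-level attribution within multi-cysteine peptides is not attempted.
- The pipeline starts at peptide-level quantitation; search-engine output
  quality (FDR, contaminant lists) is taken as given.
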