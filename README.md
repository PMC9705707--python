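# cyspaint

Proteome-wide "protein painting" experiments probe protein conformation in
living cells with a thiol-reactive dye: cysteines that become more
solvent-exposed under a stimulus react more, protected cysteines react less.
Combined with SILAC labeling (stimulus in the heavy channel, vehicle in the
light), every peptide's heavy/light ratio reports either protein abundance
(non-cysteine peptides) or abundance *plus* conformation (cysteine
peptides). `cyspaint` turns peptide-level quantitation tables into
per-peptide conformational-change calls and downstream multi-stimulus
comparisons, for proteomics groups running cysteine-reactivity footprinting
experiments.

## The statistic at the core

For a protein *i* with cys peptide *j*, replicate *r*:

    corrected_cys(i,j,r) = log2 R(i,j,r) − mean_k∈noncys(i) log2 R(i,k,r)

The noncys mean cancels the abundance component, leaving the conformational
signal. Replicates are collapsed by *p*-value-weighted scaling,

    scaled = mean(replicates) × (1 − p),   p = two-tailed one-sample t vs 0,

which shrinks uncertain means toward the null instead of applying a hard
significance cutoff. Classification thresholds are fit on a
vehicle-vs-vehicle control experiment so that they contain 95% of the
control scaled values (the classical z = 1.96 Gaussian fit is available as
an option); a cys peptide above the upper threshold is **exposed**, below
the lower one **protected**, otherwise **unchanged**.

Downstream stages assemble the cross-stimulus comparison set (proteins
quantified under every stimulus and changed under at least one), summarize
each protein by its signed-max scaled ratio, cluster the comparison-protein
interaction network by greedy modularity maximization, and test whether
response profiles are more correlated *inside* a functional feature
(complex, cluster, interaction partnership) than *outside* it, using
pairwise Spearman correlations and a paired two-tailed t-test.

The package also covers the whole-cell readout: median reporter
fluorescence normalized to the vehicle mean, tested against 1.

A synthetic-data module generates every input format with planted ground
truth (abundance shifts, conformation shifts, planted-partition networks,
cytometry fold effects), so the full pipeline is testable end to end
without any external download.

## Worked example

```python
import cyspaint as cp

# control arm: both channels vehicle-treated, true effects all zero
control = cp.generate_control_dataset(
    cp.SimulationConfig(n_proteins=600, seed=0, stimulus="control"))
control_calls, thresholds = cp.run_control(control.peptides)
thr = thresholds["cys"]
print(f"cys thresholds: [{thr.lower:+.3f}, {thr.upper:+.3f}] "
      f"(coverage {thr.coverage:.0%}, n={thr.n})")

# stimulus arm: 10% of proteins carry a planted conformation shift
stimulus = cp.generate_stimulus_dataset(
    cp.SimulationConfig(n_proteins=600, frac_changed=0.1, effect_size=0.8,
                        seed=1, stimulus="drug"))
calls = cp.run_stimulus(stimulus.peptides, thresholds)
cys = calls[(calls["axis"] == "cys") & calls["quantifiable"]]
print(cys["classification"].value_counts().to_string())

merged = cys.merge(stimulus.truth[["peptide_id", "label"]], on="peptide_id")
planted = merged[merged["label"] != "unchanged"]
hit = (planted["classification"] == planted["label"]).mean()
print(f"planted cys peptides recovered in the correct direction: {hit:.1%}")
```

prints

```
cys thresholds: [-0.254, +0.225] (coverage 95%, n=1279)
classification
unchanged    1158
protected      92
exposed        86
planted cys peptides recovered in the correct direction: 100.0%
```

The thresholds bracket ~95% of the 1279 control cys peptides; under the
stimulus, peptides outside them are called protected/exposed, and every
peptide with a planted 0.8 log2-unit shift (4× the replicate noise SD) is
recovered in the correct direction.

The same flow is available from the shell — each stage is a subcommand, and
`run-all` executes the whole synthetic demonstration:

```sh
cyspaint run-all --seed 3 --n-stimuli 3 --n-proteins 200 --out-dir demo/
```

## Layout

- `cyspaint.synthetic` — ground-truth data generators
- `cyspaint.io` — TSV dialects (MaxQuant-style and normalized), edge lists,
  annotations, cytometry tables
- `cyspaint.reactivity` — contaminant removal, protein filters, corrected
  cys ratios
- `cyspaint.scaling` — p-value-weighted scaling, control thresholds,
  classification
- `cyspaint.comparison` — comparison set, signed-max summaries,
  intersection/degree partitions
- `cyspaint.network` — induced networks, community detection, connectivity
  enrichment
- `cyspaint.features` — pairwise Spearman, inside/outside feature tests,
  degree correlation
- `cyspaint.cytometry` — vehicle normalization, one-sample tests
- `cyspaint.cli` — `simulate`, `quantify`, `scale`, `compare`, `network`,
  `correlate`, `cytometry`, `run-all`

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
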