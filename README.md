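# idcensus

A proteome-wide census of protein intrinsic disorder, built for comparative
studies of microbial proteomes — the kind of analysis that asks how much of
an archaeon's proteome is intrinsically disordered, and whether that amount
tracks the organism's habitat (salinity, pH, growth temperature) and its
position on the species tree.

Intrinsically disordered proteins (IDPs) and regions (IDRs) lack a stable
tertiary structure under physiological conditions yet carry out key
regulatory and signalling functions. `idcensus` implements the standard
measurement chain used in disorder bioinformatics:

* **Per-residue disorder scores** in [0, 1]. A bundled propensity predictor
  averages the TOP-IDP disorder-propensity scale over a sliding window
  (default 21 residues) and rescales by the scale's extremes; externally
  computed scores (e.g. from trained predictors such as PONDR or IUPred)
  can be imported from TSV and drive the identical downstream pipeline.
  Residues with score ≥ 0.5 are called disordered.
* **Three proteome-level disorder measures**: IDAA, the fraction of
  disordered residues pooled over the proteome; IDP>30aa, the fraction of
  proteins with at least one disordered run of *more than* 30 consecutive
  residues; and WIDP, the fraction of proteins classified wholly disordered
  by a whole-protein classifier.
* **Whole-protein binary classifiers**: CDF analysis (a protein's
  cumulative score distribution against a boundary calibrated between
  fully ordered and fully disordered reference sets; signed CDF distance,
  positive = ordered) and the charge–hydropathy plot
  (⟨R⟩ = |mean net charge| vs normalized mean Kyte–Doolittle ⟨H⟩, default
  boundary ⟨R⟩ = 2.785⟨H⟩ − 1.151; signed CH distance, positive =
  disordered), combined into the CH–CDF quadrants (ordered, extended
  disordered, molten-globule-like, CH-disordered/CDF-ordered).
* **Composition profiling**: fractional differences
  (C_X − C_ref)/C_ref against a fully-disordered reference composition,
  plotted in order of increasing disorder propensity, and symmetrized
  Kullback–Leibler divergence ½(KL(p‖q) + KL(q‖p)) with the similarity
  bands < 0.01 similar, 0.01–0.05 gray, > 0.05 unlikely similar, > 0.1
  non-similar.
* **Eco/evo reporting**: Pearson/Spearman correlation of disorder measures
  with habitat factors (outliers flagged by studentized residuals), and
  Newick-tree annotation with disorder-content color bins
  (> 30 % red, > 21 % orange, > 17 % yellow, > 14 % light blue,
  ≤ 14 % dark blue).
* **A synthetic proteome generator** with known ground truth: two-state
  Markov proteins with geometric ordered/disordered blocks, state-biased
  residue emission, log-normal lengths, and habitat archetypes
  (thermophile-like π_d = 0.14, mesophile-like 0.20, halophile-like 0.34),
  so the whole pipeline is testable end to end without downloads.

## Worked example

Simulate a small three-species panel, calibrate the decision threshold and
the CDF boundary on synthetic references, and run the census:

```python
from idcensus import generate_species_panel
from idcensus.pipeline import (
    analyze_panel, calibrate_panel_threshold, train_cdf_boundary,
)

panel = generate_species_panel(seed=17, n_species_per_archetype=1, n_proteins=200)
threshold = calibrate_panel_threshold(seed=17)
boundary = train_cdf_boundary(seed=17)
table = analyze_panel(panel, threshold=threshold, boundary=boundary)
print(table[["species_id", "true_disorder_fraction", "idaa", "idp30", "widp"]]
      .round(3).to_string(index=False))
```

```
         species_id  true_disorder_fraction  idaa  idp30  widp
thermophile_like_01                   0.140 0.256  0.330  0.09
  mesophile_like_01                   0.177 0.288  0.380  0.12
  halophile_like_01                   0.340 0.412  0.595  0.27
```

The `true_disorder_fraction` column is the generator's ground truth (the
fraction of residues emitted in the disordered state); `idaa`, `idp30` and
`widp` are the three measures estimated by the pipeline.  The bundled
propensity predictor over-calls disorder in absolute terms (its threshold
sits where the two state score distributions overlap), but the ranking and
spacing of species follow the true disorder content — which is what the
comparative analyses rest on: the halophile-like species is well separated
from the thermophile-like one on all three measures.

The same steps are available from the shell via the `census` command
(`census simulate`, `census score`, `census metrics`, `census classify`,
`census compose`, `census compare`, `census envcorr`, `census tree`); run
`census --help` for the full list.

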