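# Methods

This note records the models, conventions and numerical choices behind
`idcensus`, and what the synthetic benchmarks do and do not demonstrate.

## Per-residue scoring

The bundled predictor assigns each residue its TOP-IDP disorder propensity
(Campen et al., 2008), averages over a centred window, and min–max rescales
with the scale's extreme values (W = −0.884, P = 0.987), so scores land in
[0, 1] with homopolymer anchors at exactly 0 and 1.  Choices:

* **Window, default 21 residues (odd).**  Trained per-residue predictors
  produce smooth profiles; a mid-size window reproduces that smoothness
  while keeping the predictor weight-free and transparent.  Windows are
  truncated at the chain ends rather than padded — no virtual residues are
  invented.  A sequence shorter than the window receives the whole-chain
  mean at every position.
* **Ambiguity codes** (X, B, Z, U, O) receive the scale mean before
  smoothing, and are excluded from composition and charge/hydropathy
  denominators throughout the package, keeping frequency vectors on the
  20-residue simplex.
* **Decision threshold 0.5**, ties to disordered (score ≥ t), so
  thresholds behave as infima and lowering the threshold can never
  decrease any disorder measure.  `calibrate_threshold` maximizes balanced
  per-residue accuracy on the grid 0.00–1.00 step 0.01; ties are broken at
  the midpoint of the optimal grid interval rounded half-to-even, which is
  deterministic and seats the perfectly-separated case at 0.50.

This predictor is a propensity-scale method in its own right, not an
emulation of any trained network; imported score files from external
predictors flow through the identical downstream machinery.

## Disorder measures

* **IDAA** is residue-pooled (total disordered residues / total residues)
  rather than an average of per-protein fractions; "ratio of disordered
  residues in a species" reads most naturally as a pooled ratio, and
  pooling makes the measure invariant to how residues are partitioned into
  proteins.  The protein-averaged variant is exposed as `pooled=False`.
* **IDP>30aa** uses a *strict* inequality: a maximal disordered run must
  exceed `min_run` (default 30), so 31 consecutive residues qualify and 30
  do not.
* **WIDP** is the fraction of proteins with negative CDF distance.  The
  CDF route is used (rather than CH or a consensus) because CDF analysis
  is the more accurate whole-protein classifier in this lineage; a
  distance of exactly zero counts as ordered.  CH or joint calls can be
  substituted by the caller.
* Segments are 1-based inclusive internally and exported as 0-based
  half-open BED.

## Whole-protein classifiers

* **CDF grid**: 20 equal cutpoints k/20, k = 1..20; the curve value at t is
  the fraction of residues with score ≤ t.  The boundary is the midline of
  the class-mean curves of fully ordered vs fully disordered reference
  sets; "active bins" are cutpoints where the class means differ by more
  than 0.02, and the CDF distance is the mean signed gap over active bins
  (positive = ordered).  Grid, tolerance and boundary are calibration
  artifacts and are persisted to JSON with provenance.
* **CH plot**: ⟨H⟩ is the plain (unwindowed) mean of (KD + 4.5)/9 over
  standard residues; ⟨R⟩ = |#K + #R − #D − #E| / n.  Histidine is neutral
  at pH 7 and terminal charges are ignored — the standard simplification.
  The default boundary ⟨R⟩ = 2.785⟨H⟩ − 1.151 is the published linear
  separator (Uversky et al., 2000) and is configurable, as is an optional
  smoothing window for ⟨H⟩.
* **Quadrants**: CDF < 0 & CH < 0 molten-globule-like; CDF < 0 & CH ≥ 0
  extended disordered; CDF ≥ 0 & CH < 0 ordered; CDF ≥ 0 & CH ≥ 0
  disordered by CH but ordered by CDF.  Zero distances resolve by the ≥
  rule, making the partition total and deterministic.

## Composition analysis

Compositions are pooled counts over the 20 standard residues.  The
divergence is the symmetrized, natural-log form
½(KL(p‖q) + KL(q‖p)) — symmetry is required to use it as a distance
matrix.  When a vector contains a zero count, 0.5 is added to every count
of that vector before frequencies are formed (KL is undefined on empty
support); for compositions built from ≥ 10⁴ residues the result is
insensitive to halving the pseudocount (< 10⁻³).  Self-divergence is 0 and
the matrix diagonal is emitted as 0.  Band edges are closed as
[0, 0.01) similar, [0.01, 0.05] gray, (0.05, 0.1] unlikely similar,
(0.1, ∞) non-similar — the prose definitions overlap at 0.05 and 0.1, and
a deterministic partition is required.

The bundled fully-disordered reference composition is a synthetic stand-in
constructed to carry the canonical compositional signature of curated
disordered datasets; it is configurable, and no test asserts its values as
truth.

## Eco/evo reporting

Correlations report both Pearson's r and Spearman's ρ (the source analyses
do not fix a statistic), computed on pairwise-complete species; absent
habitat values are dropped, never imputed.  Categorical salinity is
rank-coded low < normal < high.  Outliers are species with
|externally studentized residual| > 2 from the least-squares fit — a
reproducible numerical stand-in for circling points on a scatter plot; the
deleted form is used because it remains sensitive when two outliers
jointly inflate the residual variance.  Tree color bins are left-open at
14, 17, 21 and 30 % with the bottom bin closed (exactly 14 % is dark blue,
exactly 21 % yellow), partitioning [0, 100] without gaps or overlaps.

## Synthetic proteomes

`simulate` is first-class, tested code, and its defaults are the study
conditions of the benchmark suite.

* **Disorder architecture**: a two-state Markov chain started from its
  stationary distribution; stay probabilities give geometric block lengths
  with mean 40 for disordered blocks (so long >30-residue IDRs occur at
  realistic rates) and an ordered-block mean derived from the target
  fraction, π_d = mean_d/(mean_d + mean_o).  Targets inconsistent with the
  block means (beyond 10⁻⁶) are rejected.
* **Emission**: uniform composition re-weighted ×2 on the
  order-promoting set (I, L, V, W, F, Y, C, N) for the ordered state and
  on the disorder-promoting set (E, K, R, G, Q, S, P, A) for the
  disordered state.  The sets are the established promoting/depleting
  residues; the ×2 factor is a choice (only the sets, not frequencies, are
  established) that yields a realistic, imperfectly separable signal.
* **Lengths**: log-normal, median 180, shape 0.60, floor 20.  These place
  the modal 50-residue bin in 100–200 and the fraction of proteins under
  50 residues below 2 %, the two length-distribution facts the generator
  is meant to honour; about 4 % of proteins exceed 500 residues, lighter
  in the right tail than real proteomes (a log-normal cannot satisfy the
  short-protein constraint and a 10 % >500aa tail simultaneously).
* **Panels**: the default panel is 3 species per archetype × 3 archetypes
  (thermophile-like π_d = 0.14, 85–100 °C; mesophile-like 0.20, 25–37 °C;
  halophile-like 0.34, high salinity), ~500 proteins per species, with
  uniform ±0.02 per-species jitter on π_d.  The archetype extremes mirror
  the reported contrast between low-disorder hyperthermophilic and
  high-disorder halophilic proteomes.  The temperature-gradient panel adds
  12 species whose π_d falls linearly from 0.30 (25 °C) to 0.10 (100 °C)
  plus two high-salinity outlier species (π_d = 0.34) in the warm half of
  the range, where the trend predicts low disorder — mirroring the real
  exceptions (hot-habitat halophiles) that break the temperature trend.
* **Reproducibility**: one master seed; per-species generators are spawned
  streams, so equal seeds give byte-identical FASTA output.

### What the synthetic benchmarks show — and what they do not

The generator emulates disorder block structure, compositional state bias,
length distribution and habitat-linked disorder fractions.  It does not
emulate real gene content, GC/codon pressure, phylogenetic covariance
between species, domain architecture, or the score noise of trained
predictors.  Passing benchmarks therefore demonstrate that the measurement
chain is internally correct and recovers known generator parameters under
realistic signal strengths — not that the bundled propensity predictor
matches trained-predictor accuracy on real proteomes.  On the synthetic
panels the predictor over-calls disorder in absolute terms while
preserving ranking and spacing of species; real-proteome absolute numbers
should come from imported scores of a trained predictor.

## Benchmark problem sizes

The packaged checks run the default panel (9 species × 500 proteins,
≈ 10⁵ residues per species) once at a fixed master seed, with five
replicate panels for the archetype-gap check, 150-protein species for the
temperature-gradient panel, and 150 + 100 proteins per class for CDF
boundary training and hold-out.  At these sizes the pooled true disorder
fraction per species has a standard error near 0.01, the scale against
which the ±0.02 recovery check is read.

## Known limitations

* The propensity predictor's absolute calibration differs from trained
  predictors; its threshold is meaningful only relative to its own score
  distribution.
* CDF boundaries are calibration artifacts: a boundary trained on one
  scorer's output must not be applied to another scorer's curves.
* The outlier rule assumes an approximately linear trend among inliers;
  with very few species the deleted residuals are degenerate and no
  outlier is flagged.
* KL similarity bands were established for large sequence datasets;
  applying them to small compositions (≪ 10⁴ residues) inflates
  divergences through sampling noise.
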