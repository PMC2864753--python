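# Methods

`ferrolimit` re-implements, as a tested and reusable pipeline, the
integrative transcriptome/proteome analysis used to characterise the iron
limitation response of the marine alphaproteobacterium *Candidatus*
Pelagibacter ubique (SAR11): differential transcript calling on a
replicated microarray design, a radial-coordinate expression layout,
AMT-tag (accurate mass and time tag) label-free protein quantitation with
Fisher-combined significance, and a transcript–protein decoupling report.
A synthetic-data generator with planted ground truth exercises every stage
end to end.

## Study design assumed by the pipeline

Six cultures (three iron-limited via siderophore addition, three
iron-replete controls) sampled for mRNA on days 17, 18 and 28 give
18 microarray chips (2 treatments × 3 biological replicates × 3 days).
Proteomics covers 4 samples (2 treatments × days 18/28), each measured in
3 technical LC-MS replicates. `locus_id` joins the two platforms.

## Transcript calling (`transcript_diff`)

Chips are median-scaled: each chip is multiplied by one positive constant
so its median gene fluorescence equals the global median of per-chip
medians. This choice is idempotent, order-preserving within chips, and
deliberately pluggable — cross-chip normalisation for this design admits
several defensible schemes (quantile, mean-scaling), and the module
isolates the decision in `normalize_chips`.

Per gene and day the statistic is the ratio of replicate-mean
fluorescence (iron-limited / iron-replete) with a two-tailed
pooled-variance Student t-test over the 3-vs-3 biological replicates.
Degenerate inputs are handled by convention: both groups constant with
equal means → p = 1; both constant with unequal means → p = 0. Raw
p-values are reported without multiple-testing correction — the tables
this stage emulates report raw p-values (up to ≈0.09 among listed rows),
and the fold filter, not the p-value, defines membership. The
up-regulation filter is inclusive: ratio ≥ 1.5 ("at least 50% more
abundant").

## Radial layout (`radial_layout`)

Each pooled sample (treatment × day; the six-chip-group default) receives
a dimensional anchor on the unit circle. The study orientation places
iron-limited samples on the left, iron-replete on the right, exponential
growth at the bottom and stationary phase at the top. Per gene, the log10
replicate-mean signals are min-subtracted across samples and normalised
to sum to one; the gene's point is the resulting convex combination of
anchor positions (the standard radial-coordinate construction: genes are
attracted to the samples in which they are most abundant, a flat gene
sits at the anchor centroid, and every point stays inside the anchors'
convex hull). Point size is the max-minus-min log10 signal. Zero
fluorescence is floored before the log at the smallest positive value in
the matrix (configurable).

Cluster labels (exponential, stationary, early iron stress, late iron
stress) are assigned by nearest anchor through a sector map; genes within
0.1 circumradii of the centroid are uninformative and stay unassigned. A
point equidistant between anchors of *different* clusters is unassigned;
equidistant anchors sharing a label yield that label (this refinement
keeps genes attracted equally to two same-programme samples labelled
rather than discarded).

The placement rule is isolated behind `gene_position` so an alternative
(e.g. force-directed pairwise springs) can be swapped in; displayed sizes
are presentation-only scalings of `s`.

## AMT-tag quantitation (`proteome_quant`)

The stage order is fixed; every filter only removes records, and only the
normalisation step alters abundances.

1. **Matching.** A feature matches a tag when |Δmass| ≤ 6 ppm of the tag
   mass and |ΔNET| ≤ 0.001 (both inclusive). NET tolerance is treated as
   absolute normalized-elution-time units. Among multiple candidates the
   smallest tolerance-normalised Euclidean distance wins; ties fall back
   to closest mass, then smallest `peptide_id`; a (peptide, sample,
   replicate) keeps only its closest feature. Inputs are assumed already
   aligned in both dimensions.
2. **Replicate presence.** A (peptide, sample) is kept only when observed
   in ≥ 2 of 3 technical replicates. Missing observations are encoded by
   row absence — never zeros — so this count is well defined.
3. **Minus-vs-average normalisation.** Within each sample, every
   non-reference technical replicate is regressed against the reference
   (default: replicate 1, configurable; no run is canonical) over shared
   peptides: m = log10 A_i − log10 A_ref, a = (log10 A_i + log10 A_ref)/2,
   least squares of m on a, corrected x′ = log10 A_i − m*(a). Fewer than
   two distinct shared a-values is an error. Peptides with no reference
   observation cannot be placed in (m, a) space and keep their raw log10
   abundance. On noise-free data with an exactly linear planted bias the
   fit is exact and the procedure is idempotent.
4. **Variability filter.** A (peptide, sample) is dropped when the sample
   standard deviation of the normalised *linear* abundances (10^x′)
   exceeds their mean — i.e. CV > 1. "Measurement value" is read as the
   abundance itself, not its log.
5. **F-score filter.** Per protein with k peptides, the lowest ⌊k/3⌋ by
   maximum PeptideProphet F-score are removed (k ≤ 2 untouched). Floor
   keeps the rule deterministic and never removes more than a third. Ties
   at the cut drop the lexicographically larger peptide id.
6. **Peptide ratios.** Replicate-mean linear abundances are ratioed
   (sample 1 / sample 2) and log10-transformed. Significance is a
   one-tailed Student t-test on the x′ values in the direction of the
   protein-level mean ratio, computed from a provisional equal-weight
   rollup (the opposite-direction rule presupposes a protein direction
   known before testing); peptides moving against their protein's
   direction get p = 1. The test runs on the log scale (the natural scale
   of x′); the scale is configurable in principle but log is the default
   and the tested path.
7. **Rollup.** Proteins with ≥ 3 passing peptides: log10 ratio is the
   arithmetic mean of member peptide log10 ratios, and Fisher's method
   combines member p-values (χ² = −2·Σ ln p, df = 2k, combined p from
   the χ² survival function; p = 0 floored at 1e-300 before the log).

## Integration (`integration_report`)

Transcript and protein tables are inner-joined per day; rows enter the
scatter when either platform's p ≤ 0.05. Decoupling is summarised by the
squared Pearson correlation of the two log10-ratio columns. The proteome
summary counts proteins significantly (p ≤ 0.05) less abundant and a mean
percent change; the fold average defaults to arithmetic and is
configurable to geometric — for a multiplicative global suppression the
geometric mean is the estimator of the suppression factor and is robust
to the single strongly induced marker, which dominates the arithmetic
mean. The marker report flags the iron-limitation marker (the *sfuC*
analogue) "coupled" on days where both its mRNA and protein folds are
≥ 1.5.

## Synthetic data (`synthetic_data`)

The generator plants known effects so the pipeline's estimates can be
compared to truth.

* **Transcriptome.** Gene baselines are lognormal (log10 mean 2.5, sd
  0.4 — fluorescence in the hundreds, an order of magnitude of dynamic
  range across genes). Four programs of 50 genes each: exponential
  (3-fold in replete day 17/18 and limited day 17), stationary (3-fold in
  replete day 28), early iron stress (4-fold in limited day 18; includes
  the marker at 16-fold), late iron stress (4-fold in limited day 28).
  Program placement matches the anchor sector map, so each program's
  genes are attracted to anchors carrying that label. Measurement noise
  is multiplicative lognormal, sd 0.1 log10 units per chip value (≈26%
  CV, typical array replicate scatter).
* **Proteome.** 250 of the 2000 loci are "detected" proteins with 6
  library peptides each (masses uniform 800–3500 Da, NET uniform,
  F-scores N(7, 2), peptide base abundances lognormal around 10^6).
  Iron-limited samples are globally suppressed to 0.41× (59% decrease);
  per-protein folds scatter around that by 10^N(0, 0.15) — drawn
  *independently of the mRNA folds*, planting the decoupling, with sd
  0.15 chosen as a realistic between-condition dispersion that makes
  spurious ≥1.5× calls rare among ~250 proteins. The marker protein is
  instead induced 27-fold on both days (one scalar; the coupled
  exception). Detection dropout is Bernoulli (p = 0.9) per (peptide,
  replicate), exercising the 2-of-3 presence filter. Mass jitter is
  N(0, 1 ppm), NET jitter N(0, 0.0002) — well inside the matching
  windows. Each technical replicate carries a global lognormal intensity
  offset (sd 0.05 log10), which the MA normalisation removes *within*
  samples; the offset of the reference replicate itself remains, as in
  real data, so single-study ratios carry a shared between-sample scale
  uncertainty that averages out over repeated studies. 5% of features
  are decoys placed, by rejection sampling, outside twice every tag's
  matching window, so they can never match at the standard tolerances.

What the generator does **not** emulate: probe-level microarray effects,
raw spectra and isotopic envelopes, chromatographic peak shape,
intensity-dependent (rather than constant) run biases unless planted
explicitly, peptide ionisation efficiency differences, and correlated
(non-Bernoulli) missingness such as censoring of low-abundance peptides.
Passing tests therefore demonstrate correctness of the estimators under
the stated stochastic model, not robustness to every artefact of real
LC-MS or array data.

## Problem sizes and runtime choices

The default synthetic study is 2,000 genes, 250 proteins, noise sd 0.1.
The Monte-Carlo recovery test runs 50 independent studies (the recovered
marker folds and decoupled-protein folds are unbiased within 3 standard
errors; the marker is the unique coupled locus in ≥ 90% of seeds;
decoupled R² < 0.1 in ≥ 95%). The acceptance script reports point
estimates averaged over 10 replicate studies, a size at which the
marker-fold estimates are stable to a few percent.

## Known limitations

* Between-sample global intensity scale is not identifiable from the
  within-sample normalisation the procedure prescribes; single-study
  protein ratios inherit the reference replicates' run offsets.
* The radial layout is a visual/cluster heuristic; cluster labels depend
  on the manual anchor arrangement and sector map.
* The matching step assumes aligned mass/NET inputs; an optional global
  recalibration is not implemented beyond the documented windows.
* Fisher's method assumes independent peptide p-values; peptides of one
  protein share biological material, so combined p-values are
  anti-conservative in that respect (a property of the original
  procedure, preserved here).
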