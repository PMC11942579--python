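# Methods

## Scope and data model

`ginqc` treats a batch of herbal material as a small population sampled a few
times (typically three replicates per batch). Two observation channels feed
the same statistic:

* **Genetic** — a dominant-marker band matrix: samples × bands, entries 0/1,
  each band owned by one primer (`band_id = "<primer>:<label>"`). The band
  matrix is assumed already digitized from gels; band calling, sizing and gel
  image analysis are out of scope. `m1` is the total number of bands scored
  on the panel (92 for the bundled 8-primer reference panel), `m2` a sample's
  count of present bands.
* **Chemical** — a table of common-peak areas: samples × peaks, areas in
  arbitrary detector response units, every peak matched in every sample.

## Entropy, RSD, HWEP, MQS

Band-profile entropy is `H = −C·ln(m2/m1)` with `C = 1/ln 2` by default, so
`H` is in bits: a sample amplifying the full panel carries no information
loss (`H = 0`), one amplifying half the panel carries exactly 1 bit. `C` is
exposed in `HwepConfig` but there is no reason to change it in practice:
entropy RSD, and hence everything downstream, is invariant to `C` because the
constant cancels between numerator and denominator only when entropies share
a sign — the invariance actually exploited is that scaling all entropies in a
batch by a positive constant leaves RSD, n, and MQS unchanged (tested).

Fingerprint entropy is `Sp = −Σ aᵢ ln(aᵢ/Σa)`. The areas act both as weights
and, normalised, as the frequencies inside the logarithm, so `Sp` carries the
chromatogram's overall response scale (∼10⁴–10⁵ response units × nats for the
reference study). The sign is flipped relative to a literal reading of the
source formula so that `Sp ≥ 0`, matching the published positive values; this
is documented, not configurable. Zero-area peaks contribute 0 (the
`x ln x → 0` limit); an all-zero sample has no defined entropy and is an
error.

Within-batch fluctuation is the relative standard deviation of the
per-sample entropies, with the sample (n−1) standard deviation. Identical
values give RSD 0 even when the common value is 0 (which arises in
leave-one-primer-out folds where every remaining band is present in every
sample); the zero-mean error is reserved for genuinely indeterminate ratios.

The HWEP size maps RSD (as a fraction) to a number of 1-gram equilibrium
units:

* `table_consistent` (default): `n = 100 · (t_{α,n−1} + u_β)² · RSD²` with
  the quantile sum fixed at 10.8 (α = β = 0.05). This form reproduces the
  published genetic and chemical batch tables and is the default for both
  channels.
* `eq5_literal`: `n = K · RSD²` with `K = 25.6`, the literal simplified
  equation from the source model's derivation. It differs from the default by
  the constant factor `100·10.8²/K ≈ 455.6` and does not reproduce the
  published tables; it is retained for comparison and logs a warning when
  used.

`MQS = n × unit_mass / 1000` kg. Reports are computed at full precision;
`write_report` rounds for display only (entropy 4 dp, RSD 2 dp percent, n
2 dp, MQS 3 dp kg). On the reference inputs the display-rounded report
matches the published genetic table cell for cell, except one published MQS
value (PG05, 0.998 kg against n = 99.80) that contradicts the g→kg
conversion used by every other row; the package recomputes (0.100 kg) rather
than copies.

A note on reproduction tolerances: the published genetic table derives from
integer band counts and reproduces to <0.03% at full precision. The published
chemical tables derive from unpublished raw peak areas; recomputing from the
3-significant-figure printed entropies recovers most batches to within ±1%
but leaves residuals up to ≈4% where the printed precision is too coarse
(e.g. three values of ∼1.5×10⁵ differing in the third digit). This is an
input-precision limit, not an implementation artefact.

## Similarity and clustering

Binary similarity uses the pair counts a (1,1), b (1,0), c (0,1), d (0,0):
simple matching `(a+d)/m`, Dice `2a/(2a+b+c)`, Jaccard `a/(a+b+c)`. Dice is
the default — shared absence is weak evidence for dominant markers — and the
coefficient is recorded with every matrix. Two all-zero profiles are
identical and get similarity 1 with a warning. UPGMA runs on
`distance = 1 − similarity` (no transformation) via average linkage; sample
ids are sorted lexicographically before linkage so equal-height merges
resolve deterministically to the lexicographically first pair, making trees
bit-reproducible across platforms. Node heights are half the cophenetic
distances; the tree is ultrametric by construction and exported as Newick.

Fingerprint similarity is the cosine (congruence) coefficient of area
vectors, per sample against a reference chromatogram — by default the
cohort's arithmetic-mean vector, the convention of pharmacopoeia
fingerprint-similarity software — plus the full pairwise matrix for heatmaps.
Cosine is scale invariant, so dilution differences cancel.

Common peaks are matched greedily on relative retention time (RRT, tolerance
0.02 by default) against the first sample's peaks, nearest gaps claimed
first; a peak is common only if matched in every sample. Each sample's RRT
reference is its own largest-area peak, which makes matching self-contained
and cancels uniform retention shifts; raw-RT matching is available by flag.

## Resampling and statistics

Leave-one-unit-out cross-validation drops one primer (genetic) or one common
peak (chemical) per fold and reruns the whole entropy → RSD → n → MQS chain;
summaries are mean ± SE (sd/√folds) per batch over folds. A fold that leaves
some sample with no band or no area has undefined entropy; it is flagged,
warned about, and excluded from summaries rather than silently patched.

Group comparisons are Welch's t (default two-group), paired t, and one-way
ANOVA with Fisher's-LSD pairwise t-tests on the pooled error term plus a
compact-letter display; all-identical inputs report the degenerate p = 1.

Spearman correlation uses `ρ = 1 − 6Σd²/(n(n²−1))` on average ranks. For
n ≤ 9 the two-sided p-value enumerates all n! rank permutations and counts
`|ρ_perm| ≥ |ρ_obs|`; above that it falls back to the asymptotic t
approximation, and the method used is recorded in the result. At the
reference study's scale (n = 7 batches, ρ = 6/7) the exact p is 0.0238
(120/5040 permutations), notably larger than the asymptotic 0.014 — the
reason an exact method is the default at this scale. The genetic–chemical
correlation uses the full-data per-batch n values; correlating LOOCV means is
available by passing those summaries instead.

## Synthetic data generator

`generate_band_matrix` draws, per batch, a founder profile (each band present
with `founder_presence_prob`, all-zero founders redrawn up to a bound) and
then flips each band independently per sample with `flip_prob`. Independent
per-band flips are the simplest mechanism producing the qualitative contrast
the pipeline must resolve — homogeneous garden-ginseng-like versus
heterogeneous forest-ginseng-like batches; linkage between bands and gel
artefacts are deliberately not modelled. `generate_peak_table` multiplies
per-peak mean areas by unit-mean log-normal factors with the stated CV
(`σ² = ln(1+CV²)`), guaranteeing positivity and mapping the CV directly onto
the RSD scale; optional Gaussian retention-time jitter supports peak-matching
tests. Both generators are deterministic given the design seed.

Default study-shaped designs use 8 primers / 92 bands, 7 batches × 3
samples, founder presence 0.6, flip rates 0.01–0.15, six peaks with mean
areas of order 10⁵ and CVs 0.05–0.50 — the ranges the reference study's
similarity and RSD values imply. What passing synthetic tests shows is that
the pipeline recovers ordering (higher flip rate / CV ⇒ higher HWEP n,
verified over 200 paired replicates) and exact values under the generator's
assumptions; real gels and chromatograms add correlated errors (co-migrating
bands, baseline drift, peak overlap) that the generator does not emulate, so
synthetic recovery does not by itself validate instrument-level accuracy.

`load_reference_tables` ships the digitized reference study inputs (per-primer
band counts, per-sample band counts with batches, per-sample fingerprint
entropies for the 6-peak and 3-ginsenoside panels); these are measured
published values, not synthetic.

## Numerical choices and edge cases

* Band matrices are validated strictly: binary entries only, duplicate ids
  rejected, every sample in exactly one batch; missing calls fail by default
  (`missing="as-absent"` recodes NA to 0). All-zero band columns are legal
  but warned about.
* Problem sizes in the test suite: monotonicity checks use 200 paired
  replicates of 92-band two-batch designs and 500 replicates of 6-peak
  tables, chosen so the full suite documents distributional behaviour while
  remaining a desk-scale run.
* Exact-permutation threshold n ≤ 9 balances exactness against factorial
  growth (9! = 362 880 evaluations).
* Ties in UPGMA, in ranks (average ranks), and in LSD letters are all
  resolved deterministically as described above; no randomness is used
  outside the seeded generators.

## Known limitations

* Dominant markers cannot resolve heterozygotes; the entropy treats band
  counts, not allele frequencies, and the HWEP size is a heterogeneity index
  calibrated by the source model's constants (10.8, 25.6), not a population
  genetics estimate.
* The fingerprint channel assumes peaks are already integrated; raw
  chromatogram processing (baseline, deconvolution) is out of scope.
* Published within-batch similarity means and fold-level error bars from the
  reference study depend on its unpublished raw band matrix and peak areas
  and are treated as plausibility anchors, not reproduction targets.
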