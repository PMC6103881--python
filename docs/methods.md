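# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `polyrep`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate model

All genomic coordinates are 0-based half-open (`[start, end)`), the BED
convention, on an explicitly declared genome (ordered chromosome names and
lengths, optional pericentric mask).  `IntervalSet` normalization sorts and
union-merges *strictly overlapping* intervals but keeps book-ended intervals
distinct: adjacency is meaningful (TADs share boundaries), and collapsing it
is the explicit job of `merge_within(gap=0)`.  Peak summits are points;
"peaks within 1 kb treated as overlapping" is implemented as single-linkage
clustering of summit positions at a closed ≤ 1,000 bp bound, so clusters
chain.  Strand is ignored everywhere except TSS proximity, which uses
unsigned distance.

## The UR caller

The input is a per-probe log2(tissue / diploid control) ratio profile, one
per biological replicate, assumed LOESS-normalized upstream.

**Smoothing.** Locally weighted linear regression over genomic position with
a tricube kernel of fixed half-width *h* (default 5,000 bp), applied per
chromosome.  A fixed genomic bandwidth (rather than a point fraction) keeps
the smoothing scale constant across array designs with different probe
spacings; local *linear* fits reproduce constants and ramps exactly, which
the unit tests pin.  *h* = 5 kb is below the scale of the dips being called
(tens to hundreds of kb) and above the probe spacing of all three supported
designs.  Chromosomes with < 3 probes pass through unsmoothed with a
warning.

**Mode centering.** The peak of the smoothed log2 distribution is found by
Gaussian KDE (Silverman bandwidth, FFT evaluation on a 2,048-point grid,
leftmost tie wins) and subtracted.  The FFT KDE is used because exact KDE
evaluation is O(n·grid) and dominates runtime on full profiles; it is
deterministic for fixed input.  The mode, not the mean or median, is the
right center: underreplication puts a heavy left tail on the distribution
that would drag any moment-based center downward, while the modal probe is
a fully replicated one.

**Threshold.** The centered distribution is split at 0 and the
over-replication (positive) side taken as representative of the null; the
empirical null is the reflection {+d, −d} of the positive deviations, and
the copy-number threshold is that null's 5th percentile — a negative log2
value, −1.645 σ for Gaussian noise.  Reflection is the minimal
operationalization of "the over-replication side represents the null", is
robust to an arbitrarily heavy underreplication tail (negative values never
enter the null), and makes the Gaussian check analytic.  The percentile is
a parameter (`null_percentile`); 5 is the default.  A stricter Z ≈ −2
convention (≈ 2.3rd percentile) can be selected by setting the parameter.

**Which values feed the threshold.** By default the null is built from the
centered *raw* probe values and the threshold is then applied to the
centered *smoothed* values (`threshold_source="raw"`).  This asymmetry is
deliberate.  Smoothing both shrinks the noise (SD ≈ σ·1.19/√(2h/Δ) for
probe spacing Δ) and autocorrelates it over the bandwidth scale; if the
threshold were the 5th percentile of the *smoothed* values themselves, the
smoothed process would wander below its own 5th percentile in excursions of
mean length comparable to the bandwidth, and runs of ≥ 25 consecutive
sub-threshold probes would be frequent under the null — the run-length rule
would lose its false-positive control entirely.  With a raw-value threshold,
a null smoothed probe lies below it with probability Φ(−1.645·σ_raw/σ_smooth)
≈ 0, so the expected number of false URs is essentially zero (the null
control the test suite verifies: 0 false URs across 100 pure-null genomes).
The cost is a conservative definition of "underreplicated": the smoothed
signal must fall below a per-probe-noise-scale threshold, i.e. the *signal*
must be below ≈ −1.645 σ_probe, not merely distinguishable from zero.
`threshold_source="smooth"` is available for sensitivity analysis.

**Run calling.** Probes with centered smoothed log2 < threshold are flagged;
a single above-threshold probe breaks a run (strict "in a row").  Maximal
runs of at least `min_run` flagged probes become URs spanning the first to
one past the last flagged probe — probe-anchored, not extended to unflagged
neighbors.  `min_run` follows the array design: 25 (1M design, ~125-bp
spacing), 11 (400k, ~250 bp), 5 (180k, ~1,500 bp).  URs within 50 kb are
then merged, and the base-wise intersection of the two replicates is the
high-confidence set.  No further merging after intersection.

## UR geometry

Each UR is expanded symmetrically to twice its width (clipped at chromosome
ends, which sets `edge_truncated` rather than failing), its probes
re-smoothed onto a 10-nt grid, and:

- `min_log2` / `min_pos`: the curve minimum; **maximum fold
  underreplication** = 2^(−min_log2);
- half-min positions: walking left/right from the minimum, the first grid
  point with value ≥ min_log2/2 (on the centered scale — the only reading
  that gives a finite width for a dip returning to baseline 0); their
  distance is the **half-min width**.

The re-profiling bandwidth defaults to 2 kb, narrower than the caller's
5 kb.  The half-min width of a dip is biased upward by ≈ 0.64·h by local
linear smoothing of a V-shape (the apex attenuates by ≈ 0.32·slope·h, which
lowers the half-min level and pushes the crossings outward); at h = 2 kb
this bias is ≈ 1.3 kb, under half the 10% test tolerance for the narrowest
(60 kb) dips benchmarked, whereas at 5 kb it would exceed it.  Replicate
geometry is averaged arithmetically (widths and folds; the averaged fold is
mapped back to an effective minimum log2).

Cross-tissue specificity clusters URs by ≥ 1 bp overlap with single linkage
(the matching rule is not externally constrained; any-overlap is the
simplest and is configurable by pre-merging).  Base-pair accounting sweeps
coverage depth over the union: depth-1 bases are tissue-specific.

## Statistical tests

**Depletion test.** Observed = ORC summits inside the URs.  Null: every UR
is re-placed uniformly at random within its own chromosome, width preserved,
overlaps among placed regions permitted (the minimal random-placement
model; a peak-shuffling alternative exists via the `alternative`/placement
options).  p uses the add-one estimator (1 + #extreme)/(n_perm + 1), so it
is never 0 and its floor is 1/(n_perm+1); claims below 10⁻⁴ therefore
require n_perm ≥ 10⁵.

**Projection test.** Statistic = fraction of query-interval midpoints
(floored for odd widths) inside the reference; expected = reference coverage
fraction of the genome.  Analytic mode: binomial two-sided p by doubling the
smaller tail, capped at 1.  Permutation mode: midpoints re-placed uniformly
on the genome, two-sided add-one p.

**Placement permutation test.** Observed = number of query intervals
overlapping ≥ 1 reference interval; null placements as in the depletion
test; upper-tail (enrichment) add-one p.

**Calibration.** All three permutation tests produce uniform p-values under
their nulls (KS at α = 0.01 over 200 runs, asserted in the acceptance
tests).  Two caveats established while building the calibration harness:
(i) the doubled-tail two-sided p is *conservative* (biased toward 1) when
the overlap count is coarse — it is never anticonservative; (ii) if query
intervals are dense enough to overlap one another, set normalization merges
them, leaving repulsively spaced midpoints whose counts are underdispersed
relative to the independent-midpoint null — again a conservative bias.
Calibration is therefore demonstrated in a sparse-query, large-count regime
(2,000 midpoints on a 200-Mb space).

**Other statistics.** Jaccard = bp(∩)/bp(∪), undefined (error) when both
sets are empty.  TAD classes: `within` (UR contained in a single TAD),
`outside` (no overlap), `crosses_boundary` (anything else); the three labels
partition any UR set.  Low-density ORC domains: 150-kb windows every 75 kb
anchored at 0, trailing partial window kept, windows with ≤ 1 summit merged
when overlapping or adjacent.  ORC-free zone: nearest summit strictly left
of the UR midpoint and first summit at/right of it (half-open tie-break);
missing sides are encoded as absent, not raised.  DPR classes: not expressed
(FPKM < 3 in the focal tissue, overriding); else DPR = focal − other
percentile rank, > 40 focal-specific, [1, 40] higher-or-equal, ≤ 0
lower-or-equal; the gap (0, 1) — unreachable with integer ranks — is
assigned to higher-or-equal by documented convention.  Percentile ranks are
100·(rank−1)/n with mean ranks for ties, computed per tissue over the full
transcript table.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Probes**: jittered grid (centers every `probe_spacing` bp, uniform
  jitter ± spacing/2) rather than a Poisson process, matching the
  quasi-regularity of real tiling designs and keeping run-length semantics
  stable.  Spacings of 125/250/1,500 bp correspond to the 1M/400k/180k
  designs.
- **Null noise**: Gaussian, SD `noise_sd`, with an optional right-skew
  mixture component (`noise_skew`) to exercise the asymmetric-null logic;
  the skew of real arrays is not asserted, only parameterized.
- **Dips**: triangular by default (linear gradient to a central minimum,
  matching the V-shaped appearance of real dips and making the half-min
  width analytic at half the base width); Gaussian and flat shapes
  available.  Replicates share the probe grid and truth and differ only in
  noise draws, as biological-replicate hybridizations of one genotype do.
- **ORC / γH2Av summits**: inhomogeneous Poisson processes — a background
  rate with a reduced rate inside designated ORC-poor domains (default 8 vs
  0.5 per 100 kb), and the mirror arrangement for γH2Av (enriched inside
  URs, default 10 vs 0.5 per 100 kb, echoing the observed ~13 peaks per
  occupied UR at typical UR widths).
- **TADs**: lognormal widths (mean 100 kb, ln-SD 0.4) tiling each chromosome
  with small boundary gaps.  **Transcripts**: uniform TSS, random strand,
  per-tissue lognormal FPKM with a forced not-expressed fraction
  (default 20%).

All generators are pure functions of (config, seed) and return their truth.

**On the default noise level.** `noise_sd` defaults to **0.04 log2 units**.
This was fixed by an error-propagation analysis done at design time: the
boundary of a called dip is localized to ≈ σ_smooth/|slope|, and the
half-min crossings to ≈ √2·σ_smooth/|slope|, where σ_smooth ≈
σ·1.19/√(2h/Δ); for the benchmarked dip grid (depths 0.5–3 log2, widths
60–500 kb, 250-bp probes) the recovery tolerances (boundary within h + 2Δ,
geometry within 10%) require σ ≲ 0.05 at the shallow-wide corner, while the
narrow-dip bias analysis caps the usable bandwidth.  Real Agilent aCGH
probe-level noise is substantially higher (derivative-log-ratio spreads of
roughly 0.15–0.3), so the default represents a high-quality, effectively
pre-averaged array.  Consequently, **the passing recovery tests demonstrate
correctness of the implementation — that the estimators converge on the
right quantities — not that real single-probe arrays support boundary
localization at kilobase precision or 10% geometry errors for shallow
dips**; on noisier data the same formulas predict proportionally wider error
bars, and `noise_sd` is a free parameter for studying exactly that.

Other features of real data the generator does not emulate: dye bias and
spatial array artifacts (inputs are assumed normalized), probe-sequence
effects, copy-number structure other than dips (e.g. amplifications are
representable only via the skew component), mappability gaps, and correlated
biological variation between replicates.

## Numerical and degenerate-input choices

- Smoothing windows with fewer than two distinct positions fall back to the
  weighted mean; evaluation points with empty windows are filled by linear
  interpolation of the probe data.
- `estimate_mode` of a constant vector returns that constant; an empty
  vector errors.  `compute_threshold` with no positive values errors
  (degenerate null).
- Interval midpoints: start + width/2, floored for odd widths; a summit
  exactly at a UR midpoint belongs to the right flank.
- Stage seeds in the pipeline are derived as master_seed XOR CRC32(stage
  name), kept below 2³¹; every stochastic stage logs its seed.
- Benchmark problem sizes (e.g. 100 genomes × 5 dips for recovery, 200 runs
  × 2,000 permutations for calibration, 6-Mb chromosomes at 250-bp spacing)
  were chosen as the package's own desk-scale validation conditions; the
  reproduction script uses 30-genome/20-seed variants of the same studies
  and reports the sizes it used.

## Known limitations

- The caller's default configuration is conservative by construction (raw
  null + smoothed flags); very shallow dips (|depth| below ≈ 1.645
  σ_probe) are undetectable by design.
- The threshold convention ("5th percentile" vs "Z ≈ −2") is a genuine
  ambiguity in the method family; both are reachable via `null_percentile`,
  and results should state which was used.
- Half-min width is reported on the smoothed 10-nt grid; a probe-anchored
  variant would differ by up to one probe spacing plus the smoothing bias.
- The random-placement null preserves chromosome assignment and permits
  overlaps among placed intervals; alternatives (cross-chromosome placement,
  non-overlapping placement) would slightly change null variances.
- KS-style distance statistics between interval sets (beyond Jaccard and
  projection) are out of scope.
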