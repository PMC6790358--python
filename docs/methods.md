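# Methods

This note documents the models, algorithms and numerical choices behind
`plantmet`, the assumptions they rest on, and what the synthetic benchmark
does and does not demonstrate.

## Data model and units

Input runs are centroided MS1 scans; profile-mode data are out of scope
(the density-clustering EIC builder assumes one centroid per ion per
scan). Retention times are minutes everywhere internally (tolerances are
quoted in minutes); m/z is in Da. mzXML and mzML are both read (root
element sniffing selects the parser); output runs are written as a minimal
mzXML dialect with base64 float64 peak arrays, which round-trips through
the reader at full precision. Missing values in the component table are
written as empty cells, never 0: "not detected" and "zero abundance" are
different facts and downstream statistics treats them differently
(missing cells are dropped, not imputed).

## EIC construction by ion density

All centroids of a run are pooled, sorted by m/z, and split wherever the
gap between neighbours exceeds `mz_tol` (default 0.01 Da). Clusters with
fewer than `min_points` members (default 1% of the scan count, floor 5)
are discarded as background: an ion that elutes chromatographically leaves
a dense run of centroids at nearly constant m/z, background noise does
not. A surviving cluster wider than `2·mz_tol` is re-split at its largest
internal gap until the span invariant holds (this fires only on
pathological inputs; on realistic data gap-splitting alone produces narrow
clusters). The trace intensity vector covers the full scan grid with
zeros where no member centroid exists, so every peak-shape vector lives on
a contiguous rt window. The per-run (rather than per-scan-window)
clustering is the simplest estimator consistent with the density
principle, and is exactly the oracle the acceptance checks enumerate.

## Baseline correction

Local-minimum baseline: the rt axis is tiled with windows (default 2 min),
the minimum point of each window becomes a node, nodes are joined by
linear interpolation, the interpolant is subtracted and negatives are
clipped, twice. Two passes remove residual curvature after the first
subtraction. Properties: a constant trace maps to zero; a clean peak on a
zero baseline is preserved to ~1% because the window minima sit on the
zero floor away from the peak. The window width is a config key; 2 min is
a compromise between following drift and not eating broad peaks (window
must exceed several peak widths).

## Scale-space peak detection

The corrected trace is smoothed with Gaussian kernels of σ ∈ {1,…,10}
scan steps. Ridges start at local maxima of the smallest scale and link,
scale by scale, to the nearest maximum within ±(σ+2) steps. A ridge is
accepted if it persists ≥ `min_ridge_length` scales (default 3) and
passes the SNR gate. Two numerical choices matter:

- **SNR definition.** The noise scale is 1.4826 × MAD of the corrected
  trace outside candidate peak regions. The *signal* is measured on the
  ridge's largest-scale smoothing, above the median of that smoothed
  background — not on the raw trace. Heavy smoothing collapses noise
  bumps (amplitude shrinks like 1/√σ) but barely attenuates genuine
  peaks that are wider than the kernel, so this statistic separates the
  two far better than raw apex height; with the raw definition, iid
  noise around a positive mean passes an SNR-3 gate almost always, with
  the smoothed definition a pure-noise trace yields no peaks in ≈100% of
  trials while a peak 5× the noise floor is still found. On a noiseless
  trace the MAD is zero and the gate passes trivially.
- **Quantification identity.** Boundaries are the nearest flanking local
  minima of the lightly smoothed trace; height is the corrected intensity
  at the apex and area the sum of corrected intensities over the
  boundaries, so `area == sum(shape)` and `height == shape[apex]` hold
  exactly by construction.

Ties (two ridges claiming one apex) keep the longer ridge, then the higher
apex. Apex m/z is the member centroid recorded at (or adjacent to) the
apex scan, falling back to the trace's intensity-weighted centre.

## Retention-time alignment

The reference is the sample with the most detected peaks (ties:
lexicographic id). Peak-to-peak similarity is the Pearson correlation of
the two elution profiles, each resampled linearly to 50 points over ±2
half-widths around its own apex (zero outside its support); pairs outside
0.01 Da or 0.5 min are invalid, and a constant shape vector has
correlation 0 by convention. The matching is a standard global-alignment
DP over the two rt-ordered peak sequences — match gain = similarity, gap
gain = 0, invalid pairs cannot match — which provably maximises
accumulated similarity over all monotone matchings (verified by
exhaustive enumeration on small matrices). Matched pairs with similarity
≥ `min_match` (0.5) become warp anchors. The warp is piecewise-linear
through the anchors; any anchor pair inverted on either axis drops the
lower-similarity anchor until the map is strictly monotone; beyond the
anchor range the edge shift is held constant (identity-offset
continuation) to avoid extrapolation. Only peak rts are warped — raw
scans are never resampled; downstream stages consume corrected rts.

## NNC registration

Items (initially single peaks, later group representatives at their
member-mean rt/mz) look for candidates in other samples within 0.01 Da
and 0.1 min, ordered by |Δrt| then |Δmz|. A pair merges only when each is
the other's first candidate and their sample sets are disjoint (a
component can never hold two peaks of one sample); scanning repeats to
fixpoint with a hard cap of one sweep per input peak. Determinism: items
are processed in canonical (rt, mz, sample) order and all mutual pairs of
a sweep merge simultaneously (first-candidate uniqueness makes the pairs
disjoint), so the output is independent of input ordering. Components
partition the input exactly; ids are assigned in (mean rt, mean mz)
order.

## Screening

One-way fixed-effects ANOVA on peak heights per component, computed by
explicit sums of squares so the degenerate limits are exact: zero
between-group variance gives (F=0, p=1), zero within-group variance with
a real effect gives (F=∞, p=0). A component must be observed in ≥2
samples of ≥2 groups to be testable. No multiple-testing correction by
default (user-set α on raw p); Benjamini–Hochberg via `p_adjust: BH`.
Heights, not areas, drive both ANOVA and correlation (areas available via
`response: area`).

Robust correlation: with ≥10 complete pairs, an MCD scatter estimate
(support fraction 0.75, seeded from the config) yields robust Mahalanobis
distances; these are median-rescaled to the χ²₂ scale (the raw MCD
distance distribution is biased at small n) and only *gross* outliers —
samples beyond 5× a Bonferroni-adjusted χ²₂ cut-off — are eliminated,
never more than the contamination budget (1 − support fraction) the
estimator assumes; the Pearson correlation of the retained samples is
returned. The 5× margin matters because rescaled MCD distances of clean
data are heavy-tailed: at the bare χ² cut-off a few percent of clean
small samples lose legitimate high-leverage points and the trimmed
correlation can shift substantially, while genuine outliers sit one to
three orders of magnitude beyond the cut-off and are caught regardless.
This realises "MCD eliminates outlying samples": on outlier-free data
the value coincides with plain Pearson, a gross outlier is rejected
essentially always, and up to 20% gross contamination moves a perfect
correlation by <0.02. Below 10 pairs the MCD subset search is unstable
and plain Pearson is used; below 5 pairs the correlation is undefined
and the pair is excluded from grouping.

Meta IDs: a graph over significant components with edges where the robust
correlation ≥ 0.9 *and* the component mean rts lie within 0.1 min (the
co-elution gate is our inference — ions of one metabolite co-elute by
definition, and without the gate any two metabolites responding to the
same treatment would merge; it can be switched off). Connected components
(transitive closure, per the pairwise-assignment semantics) become
MetaGroups, numbered by mean rt.

## Ion-clustering annotation

Mass constants: isotope spacing 1.00336 Da (¹³C−¹²C), adduct offsets
relative to [M+H]⁺ of +17.02655 (NH₄−H), +21.98194 (Na−H), +37.95588 Da
(K−H); the adduct table is configurable. Isotope pairs additionally
require the isotopologue to be *weaker* than the monoisotopic peak (true
below ~90 carbons). Candidate pairs are ranked by shape similarity
rounded to 6 decimals, then by monoisotopic height, so that in an
M/M+1/M+2 ladder with float-identical similarities the true (M, M+1)
pair wins and each peak joins at most one pair.

The adaptive cut-off for an [M+H]⁺ ion is
`max(floor, min(cutoff0, sim(MH, M1H) − margin))` with cutoff0 = 0.9,
margin = 0.02, floor = 0.8: an ion whose own isotopologue — chemically
guaranteed to share its elution profile — only reaches similarity s
cannot reasonably be held to a stricter standard than s − margin, but the
threshold never exceeds the initial 0.9 and never relaxes below the
floor.

Clustering of [M+H]⁺ ions is average-linkage agglomerative under hard
gates: a merge requires every cross-pair to be within the rt tolerance
(0.02 min) and at or above *both* ions' adaptive thresholds; merges
proceed in order of decreasing mean similarity. Satellites travel with
their MH ion. Unannotated peaks are admitted afterwards as in-source
fragments where they pass every member MH's threshold and the rt gate
against the cluster consensus; a contested orphan goes to the cluster
with the higher mean similarity.

Reconciliation ANDs the two evidence channels: components confirm as one
metabolite iff their peaks co-cluster within a sample in ≥ `min_votes`
samples (default: majority) *and* they share a Meta ID; pairs with only
one channel are reported as partial evidence with the channel named.
Confirmed metabolites get ids in rt order. The derived spectrum is taken
from the single sample where the metabolite's tallest ion is highest
(averaging across warped rt axes is ill-defined); entries are (apex m/z,
height, role), mz-ascending, duplicates kept distinct.

A practical limit of shape-only deconvolution: two concentric Gaussian
peaks need a width ratio ≥ ~2 before their profile correlation falls
below 0.9, so tightly co-eluting metabolites of similar width can
co-cluster within samples. The cross-sample abundance channel is what
separates them — uncorrelated abundances mean distinct Meta IDs, and the
AND rule then refuses the merge regardless of shape.

## Synthetic benchmark

Defaults model the intended study: 2 groups × 3 samples, 20 metabolites
over a 1–10 min gradient at 0.02 min/scan (~0.8 s/scan, a typical MS1
rate; 451 scans/run), peak σ 0.03–0.08 min, [M+H]⁺ heights 2·10⁴–5·10⁵
counts with 10% lognormal CV, m/z jitter σ = 0.002 Da, per-sample
monotone sine warps up to 0.2 min, isotopologue ratios from a binomial
model with 27 carbons (rutin-like), one adduct per metabolite, 0–2
fragments at sugar-loss offsets, five noise ions per true ion (small
random single-trace Gaussians, so the density filter *and* the SNR gate
are exercised), two column-bleed traces per run, and a 50-count detector
floor. Metabolite centers are drawn with ≥0.1 min mutual spacing —
chromatographic methods are developed to resolve their analytes, and
deliberate co-elution is exercised by a dedicated scenario (two
shape-distinct families at one rt) rather than by accidental placement.
A 4-fold between-group effect is applied to a configurable fraction of
metabolites (screening calibration uses a fraction; the end-to-end
confirmation benchmark sets it to 1.0 because confirmation is gated on
screening significance). Everything is deterministic given the seed.

What the generator does **not** model: vendor-specific noise (electronic
spikes, detector saturation), profile-mode peak shapes, gradient-dependent
retention or peak-width trends, ion suppression/matrix effects, chimeric
centroids from unresolved isobars, negative mode. Passing benchmarks
therefore demonstrates algorithmic correctness under clean-but-nontrivial
conditions, not instrument-grade robustness.

## Problem sizes

The test suite and the acceptance script use: 1,000-centroid runs for the
EIC oracle, 100 random matrices ≤6×6 for the DP oracle (exhaustive
enumeration is exponential), 100 random sets of ≤30 peaks for the NNC
oracle, 50 random tables for the ANOVA oracle, 200 Monte-Carlo repeats
for power/type-I/noise-false-positive rates, and the 6-run benchmark
above for the end-to-end checks. These sizes give stable Monte-Carlo
estimates (binomial SE ≤ 1.6 percentage points at n = 200) while keeping
a full run in minutes on one core.

## Known limitations

- Gap-filling (targeted re-integration of raw traces for components
  missing in some samples) is not implemented; missingness propagates to
  the statistics as dropped cells.
- The NNC matches group representatives after the first merge round;
  peak-to-peak rematching could differ in rare tie configurations.
- Alignment warps peak lists only; tools that resample raw profiles can
  interpolate through regions without anchors, we hold the edge shift.
- Annotation is positive-mode only and does not infer molecular formulae
  from isotope patterns, nor match spectral libraries — the derived MSP
  spectra are the hand-off point to identification tools.
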