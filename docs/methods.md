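# Methods

This note documents the models, parameter choices and numerical decisions
behind `lipidmsi`, and what the synthetic phantoms do and do not establish
about real imaging data.

## Data model

A DESI-MSI section is an `MSIDataset`: a `width × height` pixel grid in
row-major order, one polarity, and a single strictly increasing m/z axis in
[100, 1200] Da shared by all pixels (continuous-mode imzML; processed-mode
files, where pixels carry private axes, are rejected rather than resampled).
Intensities are stored as float32 and m/z as float64, the common imzML
convention. Tissue masks are per-pixel labels from a fixed vocabulary
(background, muscle, liver, brain, eye, gill, adipose, other) and travel as
label CSVs or indexed PNGs with a JSON legend.

## Preprocessing

* **TIC normalization** scales each pixel to unit total ion current. The
  normalization target is arbitrary up to a global constant; unit sum makes
  idempotence trivial to verify. Zero-TIC pixels are left as zeros and
  flagged. The raw TIC vector is retained because background detection must
  happen on pre-normalization signal (after normalization every pixel looks
  equally bright).
* **Baseline correction** subtracts a rolling-minimum baseline (default
  window 5 Da, full width) per pixel and clips at zero. A window wider than
  the axis degrades to global-minimum subtraction. On sparse centroid-like
  axes an isolated peak whose window contains no other point would subtract
  itself; the default window is much wider than the phantom peak spacing, so
  every window sees off-peak points.
* **Feature picking** operates on the mean spectrum (one global feature
  list, the way imaging software treats features, rather than per-pixel peak
  lists): an axis point is a feature if it is the local maximum within
  ±0.02 Da and reaches 1% of the strongest mean peak; features are ranked by
  mean intensity, truncated to `top_n` (default 200) and reported in m/z
  order.
* **Alignment** across replicates is greedy nearest-neighbour grouping
  seeded from the most intense feature downward (ties broken toward lower
  m/z), tolerance 0.02 Da — chosen on the same absolute scale as the
  0.05 Da annotation search rather than in ppm, and exposed as a parameter.
  Each consensus feature absorbs at most one feature per replicate; the
  between-replicate deviation is reported as max pairwise Δm/z in ppm. The
  procedure is order-independent by construction (the seeding order is a
  global intensity sort, not the input order).
* **Deisotoping** removes feature B when some feature A lies 1.00336 Da
  below it (±0.01 Da) with a larger mean intensity; B is recorded with its
  parent. Intensity ordering protects genuine lipids that happen to sit one
  isotope spacing above a weaker neighbour, and the most intense feature can
  never be removed. Only M+1 satellites are modelled; M+2 is ignored.
* **Interday rescaling** multiplies a target replicate by the ratio of
  matched-ROI mean TICs, mirroring the practice of normalizing serial
  sections to the same absolute intensity after source realignment.

## Segmentation

Pixels are clustered by bisecting k-means under the correlation distance
`1 − Pearson r` — scale-free, so clusters follow lipid composition, not
tissue thickness or spray efficiency. "Distance correlation" as named by
imaging software is read as this correlation distance; Székely's distance
correlation is a dependence measure between random vectors and cannot serve
as a pixel metric for k-means. Implementation: spectra are row-standardized
to zero mean and unit norm so that squared Euclidean distance equals twice
the correlation distance, and 2-means runs on the standardized vectors with
centroids re-standardized each iteration. Each bisection splits the leaf
with the largest total within-cluster dispersion (best of 10 restarts;
restart 0 is seeded from the parent centroid and its farthest member, which
guarantees the children's summed dispersion never exceeds the parent's).
Convergence is assignment stability or 100 iterations; everything is
deterministic given the seed. Pixels with raw TIC below 5% of the median
are excluded as background before clustering. The number of leaves is a
parameter (default 8); with six planted tissues the extra leaves subdivide
muscle, which lowers the global ARI while leaving organ-level Dice
unaffected — the adipose call uses the leaf with maximal Dice against the
adipose mask label (ties to the lower leaf id), and all remaining leaves
are merged into the non-adipose contrast group.

## Validation statistics

Reproducibility uses 3×3-pixel ROIs (a 150 µm square at 50 µm pitch; a
literal reading of "150 µm²" would be smaller than a single pixel). ROIs
are sampled uniformly among fully-interior placements, greedily enforcing
disjointness. CV is `100 × SD(n−1) / mean`, computed per feature across ROI
*means* — the ROI is the unit of replication, pooling pixels would
overstate precision. One-way ANOVA (TIC between tissues) and balanced
two-way ANOVA with interaction (tissue × lipid) come from standard
fixed-effects theory (scipy / statsmodels under the package surface).
"Unpaired t-test" is realized as Welch's test: the adipose and merged
non-adipose groups differ grossly in size and variance, where the pooled
test is anticonservative; the pooled flavour stays available behind a flag.
Benjamini–Hochberg adjustment is applied within each replicate × polarity
feature family.

## Two-tier enrichment screen

Tier 1: per replicate, a Welch test per feature of adipose vs merged
non-adipose pixels (per-pixel values, not ROI means — the contrast is
between pixel populations), BH-adjusted within the replicate; a feature is
a candidate if q < 0.05 *and* its adipose mean exceeds the non-adipose mean
in at least one replicate. The direction rule makes "enriched" one-sided; a
feature higher in liver than everywhere else is not adipose-enriched no
matter how small its q. Tier 2: rank-based ROC AUC per replicate (ties
count half), passing iff AUC > 0.7 in at least `ceil(0.5 n)` replicates
(2 of 3 at the default replication). A feature is adipose-enriched iff it
passes both tiers. Reported summaries average per-replicate group means;
fold change is the ratio of those averages, rounded to two decimals for
reporting, and when reproducing printed summaries the inputs are taken at
printed precision (three significant figures) so the quotient matches the
printed value.

## Lipid chemistry

Formulas follow per-class rules in total acyl carbons c, double bonds d and
extra oxygens x (e.g. FA: C_c H_{2c−2d} O_{2+x}; TG: C_{c+3} H_{2c−2d+2}
O₆; PC: C_{c+8} H_{2c−2d+16} N O₈ P), each unit-tested against an
independent mass calculator. `PEe` is implemented as the plasmanyl
(O-alkyl) ether; the plasmenyl reading would shift the formula by one
double-bond equivalent and is not distinguishable from species-level
shorthand. Atomic masses are IUPAC monoisotopic values; adduct shifts are
electron-mass corrected (e.g. [M−H]⁻ = −1.00727646, [M+Na]⁺ = +22.98922070)
for sub-ppm accuracy at m/z 100–1200. The accurate-mass search uses
±0.05 Da against a deterministic combinatorial database (no live database
queries; the default grid spans FA/DG/TG/PC/PE/PEe/PI/PG/PS/LPC/LPE and
contains every curated species). MS² matching scores class-diagnostic
fragments — FA: H₂O and CO₂ losses; TG: neutral loss of each acyl as free
acid (plus NH₃ under ammonium); DG: acyl losses from [M+H−H₂O]⁺; PC: the
184.0733 phosphocholine head group; glycerophospholipids in negative mode:
acyl carboxylate anions — at ±5 ppm (a printed "±0.05 ppm" is physically
implausible at the stated resolving power and is treated as a typo). When a
candidate lacks an acyl composition, decompositions over a pool of common
chains are enumerated and the best-matching one is scored, reflecting that
species-level annotation does not fix sn-composition. Identification is
Level 2 (species level): same lipid, same adduct in both modalities; no
double-bond-position or sn-position claims.

## The phantom generator

The generator emulates a sagittal full-body section: a muscle body ellipse
containing brain, eye, gill band, liver and two adipose depots (visceral
blob + subepidermal ribbon), with organ centers jittered by the seed.
Default grid 64×32 (≈1300 tissue pixels) — real sections run 40–60k pixels,
but no claim here depends on scale and desk-scale grids keep studies fast;
dimensions are configurable. The default 50-lipid negative-mode panel
plants 16 adipose-enriched free/oxidized fatty acids at folds 1.5–2.8
(spanning the range reported for high-confidence adipose lipids), 14 null
phospholipids, 10 organ markers and 10 abundant shared membrane lipids, the
latter keeping the enriched share of TIC realistic (~13%) so that TIC
normalization attenuates but does not erase planted folds — exactly the
coupling a real screen faces. Per-tissue overall yield factors
(liver 1.35, brain 1.2, …) create TIC contrasts between organs; TIC
normalization removes them, so they affect raw-TIC statistics only.

Noise is multiplicative lognormal with a target within-tissue CV (default
15%, inside the <20% band observed for well-behaved features), split
equally between a smooth per-feature spatial field (piecewise constant over
8×8 tiles) and white pixel noise, plus a small additive exponential
baseline. The spatial component is essential: with purely white noise,
3×3-ROI means would average the CV down threefold and ROI-level statistics
would be unrealistically tight; biological tissue is spatially
heterogeneous at scales larger than one ROI. Per-pixel CV still converges
to the target. Each replicate after the first is multiplied by a global
scale factor drawn from [0.8, 1.25], mimicking day-to-day source drift; the
first replicate is the reference (scale 1.0). Optional M+1 satellites are
added at +1.00336 Da with relative abundance 0.0107 c / 0.9893 for c
carbons, perfectly correlated with the parent; panel masses are chosen so
no satellite collides with a planted lipid within the picking window.
Poisson shot noise and mass-calibration drift are not modelled (intensity
reports carry no count scale to calibrate against), and region geometry
makes no attempt at
anatomical realism. Consequently, passing phantom studies demonstrates the
*statistical machinery* — error control, recovery, segmentation under the
stated noise — not robustness to profile-mode peak shapes, calibration
drift, or anatomical ambiguity.

LESA extracts are simulated as site-level peak lists from adipose pixels
with spiked standards at lognormal CV 13% (the reproducibility measured for
internal standards); MS² spectra contain the precursor, all rule fragments
at exact m/z, and low-level random noise peaks.

## Numerical and degenerate-input conventions

Zero-variance vectors have correlation distance 1 to everything except an
identical zero-variance vector (0). Identical ANOVA groups give F = 0,
p = 1; all-identical values with no between-group variance are an error
(0/0). Welch with two zero-variance equal-mean groups returns p = 1.
Alignment and Dice ties break toward lower m/z / lower leaf id. All
simulations and clustering restarts derive from explicit integer seeds; two
runs with the same config produce bit-identical artifacts (checksummed in
the run manifest).

## Known limitations

Segmentation ARI is sensitive to the leaf count relative to the number of
true tissues (extra leaves split muscle); only organ-level Dice is treated
as the recovery criterion. The combinatorial database deliberately
over-generates species; ranking relies on mass accuracy plus MS² evidence,
and isobars within ±0.05 Da without distinguishing fragments remain
ambiguous, as they should at Level 2. The 653→52 feature funnel of a real
full-scale study is not reproducible without the raw sections; the package
covers it with null-calibration (false-pass fraction ≤ nominal FDR) and
parameter-recovery (sensitivity ≥ 0.9, specificity ≥ 0.95 on phantoms)
studies instead.
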