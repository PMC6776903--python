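# Methods

This note documents the models behind `hictopo`, the choices made where
the standard methods leave room, and what the synthetic validation does
and does not demonstrate about real Hi-C data.

## The synthetic contact model

Counts are independent Poisson draws around an intensity surface. For a
cis bin pair (i, j) at separation d = |i − j| bins,

    lambda(i, j) = K · d^(−alpha) · T(i, j) · P(i, j) · L(i, j)

with the per-chromosome scale K set so that pixels at separation ≥ 2
bins sum to the configured depth (each unordered pair counted once).
The factors:

- **Decay** d^(−alpha), alpha > 0 (default 1.0 — the classic
  fractal-globule-like regime). d = 0 and d = 1 pixels are generated at
  the d = 1 level but flagged for masking downstream; self- and
  adjacent-ligation signal is excluded from every analysis, as is
  standard.
- **TAD term** T: `tad_boost` (default 2.0) when i and j share a
  domain; otherwise the product of the permeabilities (default 0.2,
  each in (0, 1]) of the boundaries crossed, applied only when
  d ≤ `insulation_range` (default 1.2 Mb). The distance gate encodes
  that boundary insulation is a local phenomenon: an unbounded product
  of permeabilities would drive multi-megabase cis contacts to
  essentially zero counts, which neither matches real maps (where
  long-range cis is governed by compartments and decay) nor leaves any
  measurable signal for loop pileups at 1.5–5 Mb separations.
- **Plaid term** P = exp(gamma · c_i · c_j) with `plaid_strength`
  gamma (default 0.4) and a per-bin compartment profile c. The profile
  is a two-level ±1 block signal (blocks ~5 Mb, alternating sign). The
  two-level default is deliberate: on desk-scale chromosomes with only
  a handful of blocks, per-block magnitude variation lets a positional
  gradient — an artifact of distance normalization on short, unbalanced
  chromosomes — compete with the plaid for the first principal
  component. Compartment block edges snap to the nearest planted TAD
  boundary, as compartment transitions in real genomes coincide with
  domain boundaries; unsnapped edges create secondary insulation dips
  that displace boundary calls by 2–3 bins.
- **Loop term** L: each planted loop multiplies its pixel by the
  enrichment e (default 3.0) and the surrounding 3×3 halo by
  1 + (e − 1)/2. The halo makes the aggregate-peak centre robust at
  25 kb bins.

Trans blocks carry a constant mean modulated by the same plaid term,
scaled to `trans_depth` (default 4 × 10^5 counts per chromosome pair) —
trans contacts must carry compartment signal because the trans
eigenvector and trans saddle analyses are part of the battery.

TAD sizes and compartment blocks are drawn with sizes uniform on
[min, 2·mean − min] (TADs: mean 1 Mb, min 600 kb), so mean sizes equal
the configured values while no single block can swallow a chromosome.
The 600 kb minimum reflects the resolving power of the insulation
parameterization used throughout (480 kb square + 320 kb delta span):
boundaries packed more tightly than that produce a single merged
insulation minimum regardless of implementation, so planting them would
measure the parameterization, not the caller.

### Perturbation models

- `rnase_like(f_bb)` multiplies the plaid contribution of B–B pairs by
  f_bb ∈ (0, 1] — in cis only at separations ≥ `bb_min_dist`
  (default 2 Mb), in trans everywhere. The distance gate is essential,
  not cosmetic: in a two-state genome a *uniform* B–B attenuation is
  absorbed exactly by iterative correction (weights w_B = w_A/√f_bb
  re-equalize AA and BB), leaving only an A–B boost. Because balancing
  marginals are dominated by short-range contacts, a long-range-only
  attenuation survives correction and appears where it should: in the
  BB saddle corner and the negative tail of the trans eigenvector,
  while TAD structure is untouched.
- `actd_like(permeability_rescue, loop_retain)` moves each boundary
  permeability the given fraction of the way to 1 (1.0 erases all
  insulation) and retains the given fraction of each loop's enrichment
  above background. The compartment profile and plaid strength are
  untouched.

The study gives directions, not effect sizes, for these perturbations;
the defaults (f_bb 0.7; rescue and retain 0.5) were chosen once for
test power at desk scale.

## Analysis pipeline choices

**Balancing.** ICE with multiplicative marginal updates; convergence at
marginal CV < 10^−5 (max 200 iterations; non-convergence warns and is
flagged in metadata, never silent). Bins with zero coverage or in the
lowest 2% of nonzero coverage are masked first. Cis pixels with
|i − j| < 2 are excluded from marginals by default (`exclude_diags`
parameter; set 0 to include everything). Weights are normalized to unit
unmasked marginals, which makes balanced values — and therefore
insulation, eigenvectors and all downstream scores — invariant to a
global read-depth rescaling.

**Expected / O/E.** Expected is the plain per-diagonal mean of balanced
values per chromosome (no smoothing), so O/E has exactly unit mean per
diagonal by construction; trans O/E divides by the chromosome-pair
mean. Pixels with zero or undefined expected become NaN, never
infinite. Undefined values propagate through every stage; nothing is
imputed.

**Correlation map and eigenvector.** Pearson correlation is computed on
O/E (raw-matrix correlation conflates decay with compartments), pairwise
over mutually defined columns and excluding the row pair's own two
columns. The compartment track is the leading eigenvector of the
double-centered correlation map, scaled by √eigenvalue, per chromosome;
the sign is set per chromosome by positive correlation with a
user-supplied reference activity track (the planted profile in
synthetic runs; gene density or GC content would play this role on real
data). |r| < 0.1 against the reference leaves the sign as computed and
flags the chromosome ambiguous. The trans track eigendecomposes the
genome-wide (O/E − 1) matrix with cis blocks zeroed; a row-correlation
matrix is not defined across chromosomes when the genome has only two,
and the largest *positive* eigenvalue is taken because the
zero-diagonal block structure produces ± eigenvalue pairs of which only
the positive one carries the consistent inter-chromosomal sign
coupling.

**Insulation.** Raw score of bin i aggregates the square
rows [i−w, i−1] × columns [i+1, i+w], w = square_size/resolution —
plain mean, or mean after discarding values outside the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] for the default `iqrMean` mode (our
reading of that mode's name; it equals the plain mean whenever the
square holds no outliers). Values at or below the noise threshold
(default 0) are undefined. Normalization is log2(raw / chromosome
mean); smoothing is a centered moving mean (the simplest reading of a
"smoothing span"), half-width round(span/resolution/2). The delta
vector is the mean smoothed insulation over (i, i+s] minus [i−s, i).
Boundaries are upward zero-crossings of delta, taking the
lower-insulation bin of the crossing pair; the score is the right-side
delta maximum minus the left-side minimum within the delta span —
identical arithmetic whether a boundary is scored where it was called
or a matched locus is scored in another condition's track, which keeps
control-vs-treatment contrasts consistent. Candidates below the 1.5
threshold are dropped; candidates within the merge margin keep the
stronger (margin 0 by default, i.e. no merging). No boundary is called
where the track is undefined, in particular within the square of a
chromosome end — recovery scoring therefore restricts planted
boundaries to the callable interior.

**Saddles.** Bins ranked by eigenvector value (ties broken by bin
index for determinism) are cut into quantile groups differing in size
by at most one. Entries are defined-pixel means; corners summarize the
5 extreme groups, count-weighted. At the package's desk scale
(~80 bins at 500 kb) the 30-quantile default can leave extreme 5×5
corners without any cis or trans pixel; phenotype checks in the test
suite therefore use 10 quantiles, while the pipeline default remains
30.

**Switching.** A bin is reproducible in a condition iff both replicates
agree in sign; fractions are over bins reproducible in both conditions
and sum to one. The randomized baseline permutes treatment labels
across those bins (preserving A/B counts) 100 times — a construction of
this package; with balanced A/B proportions its expected stable
fraction is p_A² + p_B² = 0.5, which the tests verify in closed form.

**APA.** O/E submatrices (a raw-matrix mode is available) centred on
loop pixels, ±250 kb at 25 kb → 21×21. Centre window: central 3×3;
background: the lower-left (short-distance) 6×6 corner, following the
usual aggregate-peak convention; loops closer than 2·flank + 3 bins to
the diagonal, or with windows leaving the chromosome, are filtered and
counted. The z-score and log2 fold change use the 3×3 centre; the
loop-intensity score used for condition differentials is the central
pixel over the corner mean, the estimator that recovers a planted
enrichment multiplicatively (the 3×3 mean is diluted by the halo).
Log-ratio pseudocounts default to 1 count-equivalent on raw maps and
10^−4 on O/E.

**Scaling.** Geometric distance bins between 2 bins and the distance
cap; the slope is an unweighted least-squares fit of log10 mean contact
vs log10 distance over [200 kb, cap] (the lower cut excludes the masked
near-diagonal). Boundary-weakening flattens the curve below the
insulation range, so short-range comparisons use a ~1.2 Mb cap; over a
3 Mb window the effect dilutes.

**Statistics.** Rank-sum tests report the rank sum of the first sample
with mid-ranks for ties; exact enumeration iff n_x + n_y ≤ 20 with no
ties, otherwise the normal approximation with continuity and tie
correction (scipy's Mann–Whitney machinery stands behind this surface;
an independent brute-force enumeration is kept in the test suite as the
oracle). Two-sided p-values throughout; no multiple-testing correction by
default (`compare_stratified(..., adjust="bh")` adds
Benjamini–Hochberg-adjusted p-values when wanted). Site counting uses
a ≥ 1 bp overlap rule, so a site spanning a bin edge counts for both
bins. Replicate dissimilarity is 1 − Pearson r over jointly defined
bins (bounded in [0, 2]); clustering is average-linkage by default and
configurable; pairs with < 50% joint coverage are flagged
low-confidence rather than dropped.

**Pipeline.** Replicates are pooled (counts summed) per condition
before boundary and compartment calling; per-replicate eigenvectors are
still computed for reproducibility QC and the switching analysis. Every
report is stamped with the config hash, seed and package version, and
repeated runs are byte-identical. Optional stages (no loop list → no
APA; no site list → no stratification; single chromosome → no trans)
are skipped with a recorded reason, not fatal.

## Problem sizes

The default desk-scale genome is two chromosomes of 20 Mb — large
enough to hold ~19 TADs per chromosome at 40 kb bins, 4 compartment
blocks per chromosome at 500 kb, and 40 loops at 25 kb, while every
stage runs in seconds. Analysis resolutions follow the standard tiering
(compartments 500 kb, TADs 40 kb, loop pileups 25 kb); the synthetic
study simulates each resolution independently from per-resolution
truths sharing one configuration: 500 kb maps omit TADs and loops
(sub-resolution structure), 40 kb maps omit loops. Depths default to
2 × 10^6 cis counts per chromosome (10^6 for compartment-only maps),
roughly matching the per-Mb information density of a typical pooled
Hi-C library at these resolutions.

## What the synthetic validation does not show

The generator emulates Poisson sequencing noise, replicate-to-replicate
sampling variation, coverage masking and the planted structures above.
It does not emulate: restriction-fragment-level biases (GC,
mappability, fragment length) that real balancing must absorb;
structural variation or translocations; nested/hierarchical TADs;
continuous compartment strength gradients or sub-compartments;
cell-cycle or population heterogeneity; or distance-dependent noise
beyond Poisson. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic is correct and its thresholds are coherent at
desk scale — not that the biological conclusions of any real-data study
are insensitive to those unmodelled factors. Real-data use also
requires an externally supplied orientation track and imports published
loop coordinates; loop *calling* is out of scope.
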