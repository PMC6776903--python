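# hictopo

Desk-scale Hi-C topology analysis for chromatin biologists who want to
ask how a perturbation — degrading nuclear RNA, arresting transcription,
degrading an architectural protein — reshapes the two dominant layers of
genome folding: **topologically associating domains (TADs)** and **A/B
compartments**. The package implements the full downstream battery that
such studies run on binned contact matrices, together with a synthetic
contact-map generator that plants known structure, so every stage of the
pipeline can be validated against ground truth before it ever touches
real data.

## What it computes

Starting from a binned contact matrix *C* (HiC-Pro sparse-triplet text
format, or simulated):

- **Iterative correction (ICE).** Per-bin weights *w* such that the
  balanced matrix *w_i w_j C_ij* has equal marginals over unmasked bins,
  removing coverage bias including read depth.
- **Expected and O/E.** The distance decay *P(s)* (mean balanced contact
  at separation *s*, per chromosome; chromosome-pair means in trans) and
  the observed/expected matrix, plus the log–log slope of *P(s)*.
- **Insulation and TAD boundaries.** The insulation score of bin *i*
  aggregates the square of pixels crossing the diagonal at *i*
  (default 480 kb square, Tukey-fenced `iqrMean` aggregation, 160 kb
  smoothing), normalized as log2(raw / chromosome mean). Boundaries are
  upward zero-crossings of the delta vector (right-minus-left contrast
  over a 320 kb span) at insulation minima; the boundary score is the
  delta peak-to-trough contrast, thresholded at 1.5.
- **Compartments.** Per-chromosome Pearson correlation maps of cis O/E
  rows; the first principal component of the centered correlation map,
  scaled by the square root of its eigenvalue, gives the per-bin
  compartment track (A where positive, B where negative, oriented
  against a reference activity track). A trans variant eigendecomposes
  the centered trans-only O/E. Saddle plots average O/E between
  eigenvector quantile groups (default 30), with AA/BB/AB corner
  summaries; switching analysis compares reproducible labels between
  conditions against a label-permutation null.
- **Pileups and APA.** Mean submatrices around TAD boundaries (±1 Mb at
  40 kb), log2 ratio maps between conditions, and aggregate peak
  analysis around loop pixels (±250 kb at 25 kb): centre-vs-corner
  z-score, log2 fold change, and a loop-intensity score (central pixel
  over the short-range corner background) whose between-condition
  percent change quantifies loop weakening.
- **Statistics.** Wilcoxon rank-sum tests (exact for small untied
  samples), boundary-score stratification by motif-site counts (≤1 vs
  ≥2 sites per boundary bin), and replicate dissimilarity
  (1 − Pearson *r* of eigenvector tracks) with an average-linkage
  dendrogram.

The **synthetic generator** draws Poisson counts around an intensity
surface λ(i,j) = depth-scaled product of a power-law decay |i−j|^(−α), a
TAD term (within-domain boost, cross-boundary permeability below ~1.2 Mb
separation), a plaid term exp(γ·c_i·c_j) on a planted ±1 compartment
profile *c*, and focal loop enrichments with a half-strength 3×3 halo.
Two perturbation models mirror the biology under study: `rnase_like`
attenuates long-range B–B plaid contacts, `actd_like` weakens boundary
permeabilities and loop strengths. Everything planted is recorded and
reloadable, so boundary precision/recall, eigenvector sign agreement and
decay-exponent recovery can be scored exactly.

## Worked example

Simulate a two-chromosome genome (2 × 20 Mb, 40 kb bins) with ~1 Mb
TADs, apply a transcription-inhibition-like perturbation, and compare
boundary strengths at the control's boundaries:

```python
import numpy as np
import hictopo as h

bins = h.make_bins({"chr1": 20_000_000, "chr2": 20_000_000}, 40_000)
config = h.GeneratorConfig(n_loops=0)
truth = h.plant_truth(bins, config, seed=1)
actd = h.apply_perturbation(truth, "actd_like",
                            permeability_rescue=0.5, loop_retain=0.5)

def insulation(t, seed):
    counts = h.simulate_contacts(t, bins, seed)
    return h.insulation_track(h.ice_balance(counts))

ctrl, trt = insulation(truth, 2), insulation(actd, 3)
boundaries = h.call_boundaries(ctrl)
s_ctrl = h.boundary_scores_at(ctrl, boundaries)
s_trt = h.boundary_scores_at(trt, boundaries)
ok = np.isfinite(s_ctrl) & np.isfinite(s_trt)
test = h.wilcoxon_rank_sum(s_ctrl[ok], s_trt[ok])
```

Output:

```
planted boundaries: 37, called: 37
median boundary score  control: 5.18   ActD-like: 2.53
Wilcoxon rank-sum p = 2.11e-12  (n = 37)
boundary recovery vs truth: precision 1.00, recall 1.00
```

Moving each boundary permeability halfway to 1 halves the
insulation contrast (median score 5.18 → 2.53) while every planted
boundary is still called in the control — boundary *strength*, not
boundary *position*, is what the perturbation moves.

The same analyses run end-to-end from a YAML config (or pure defaults)
via the orchestrator, which pools replicates per condition, runs every
stage, and writes numeric tables plus a machine-readable summary:

```python
report = h.run_synthetic_study(h.RunConfig(
    seed=3, output_dir="out",
    generator={"replicates": 2,
               "perturbation": {"kind": "rnase_like", "f_bb": 0.5}}))
```

A `hictopo` command-line tool exposes the individual stages
(`simulate`, `insulation`, `compartments`, `saddle`, `switching`,
`pileup`, `apa`, `scaling`, `compare`, `run`); see `hictopo --help`.

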