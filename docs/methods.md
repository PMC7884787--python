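# Methods

This note records the statistical model behind `asrt`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical and design choices made where more than one reasonable option
existed.

## Replication-timing model

The observable is the per-window ratio of sequencing depth in S-phase-sorted
cells to G1-sorted cells. A locus replicating at the start of S phase is
present in two copies in nearly every S cell and one copy in G1, so its
expected S/G1 ratio (after depth normalization) approaches 2; a very late
locus stays near 1. We express replication timing (RT) on the conventional
−2 (very late) … +2 (very early) scale and, in the generator, map RT to
relative S copy number log-linearly, `g(rt) = 2^((rt+2)/4) ∈ [1, 2]`. The
log-linear form means a fixed RT difference produces the same fold-change in
expected S depth anywhere on the scale, which is the natural counterpart of
an analysis carried out on log2 ratios; with a linear map the same implanted
ΔRT would look twice as large in late regions as in early ones.

Per allele a, replicate r and window w, counts are

    G1_{arw} ~ Poisson(d_G1 · c_{aw})
    S_{arw}  ~ Poisson(d_S · g(rt_{aw} + ε_{arw}) / g(0) · c_{aw})

with depths `d` (defaults 100 reads/window each), copy number `c` (1, scaled
by `deletion_depth_ratio` inside strain deletions), and white replicate noise
ε ~ N(0, 0.25) in RT units. At depth 100 the Poisson counting noise, not ε,
dominates the per-window log-ratio variance (sd ≈ 0.20 vs 0.06 in log2
units); this is the regime the smoothing spline exists for, since counting
noise is white and smoothable while the biological landscape is not.

## Profiling choices

* **Normalization** (not uniquely determined by the assay): each sample is
  scaled to reads per million, the S/G1 ratio is taken per window, log2
  transformed, and z-scored per sample over informative autosomal windows.
  z-scoring makes profiles comparable across replicates of different depth;
  the resulting RT values are in z-units, which the ±2 display convention
  approximates but is not forced to equal.
* **Informative windows**: a window needs at least `min_g1_count` (default 1)
  G1 reads and a positive S count in every sample. Windows whose
  log(G1-allele-a / G1-allele-b), summed over replicates, lies more than 2 SD
  from the genome mean are removed — these are copy-number artefacts
  (deletions, amplifications) that would masquerade as RT differences. The
  log ratio is used because it is symmetric under allele exchange.
* **Segments**: a segment is a stretch of windows in which no run of more
  than `max_gap_windows` (10) consecutive uninformative windows occurs; the
  spline is fitted to the informative windows of a segment and evaluated
  across the whole segment span (true interpolation at interior masked
  windows, which carry values but stay non-informative). Segments with fewer
  than 15 informative windows are dropped. Treating every masked window as a
  hard segment break would, with a 2-SD filter that always masks ~5% of
  windows, fragment the genome and silently discard roughly a fifth of it to
  the 15-window rule.
* **Smoothing**: the penalized objective `p·Σ(y−f)² + (1−p)·∫f″²` with
  p = 10⁻¹⁶ quoted, as is conventional for RT profiles, in bp x-coordinates.
  Because the penalty scales with the cube of the x unit, the solver works
  in window units with `λ = (1−p)/p / w³` (λ = 10 for 100 kb windows), a
  mild smoother with an equivalent bandwidth of ~3 windows. `p_units` exposes
  the raw window-unit convention. Fits use natural cubic smoothing splines
  (`scipy.interpolate.make_smoothing_spline`), verified in the tests against
  a dense Reinsch normal-equations solve.

## Detection

At each window the six smoothed RT values are compared by a Gaussian
likelihood-ratio test of one common mean against one mean per allele. Two
variance treatments are available:

* `variance="within"` — the textbook LRT with the variance profiled out
  per window, Λ = n·ln(SS₀/SS₁). With n = 6 its χ²₁ reference is the
  F(1,4) tail in disguise: far too heavy-tailed for genome-wide thresholds
  (nominal 10⁻⁵ is really ≈ 6·10⁻⁴) and, equivalently, underpowered.
* `variance="pooled"` (default) — one replicate variance estimated from the
  within-group sums of squares of *all* informative windows (thousands of
  degrees of freedom), giving Λ = (SS₀−SS₁)/σ̂². Under Gaussian noise this
  is calibrated χ²₁ essentially exactly, which the null-calibration test
  verifies: ~1.5% of signal-free genomes produce any called region at the
  q < 0.01 / |ΔRT| > 0.5 rule.

BH-FDR q-values are computed over all informative windows per clone. Regions
seed at maximal runs of q < 0.01, extend while q ≤ 0.05 (stopping at the
first failure or at any masked window; a configurable gap tolerance defaults
to 0), merge when overlapping, and must contain a window with |ΔRT| > 0.5 on
the smoothed scale. Orientation is the sign of ΔRT at the peak window.

### Master list and genetic subtraction

The master list is the merged union of clone calls minus pure-strain
(genetic) differences. Since a missed genetic region contaminates the
epigenetic list while an over-eager mask merely drops one candidate, the
subtraction stage is sensitivity-first and uses two screens on the
pure-strain profile:

1. runs of ≥3 consecutive windows with uncorrected per-window LRT p < 0.01
   (no BH — this is nuisance masking, not discovery);
2. a region-level test per master candidate: the strain difference is
   averaged over the candidate's windows separately per replicate (replicate
   libraries are independent, so smoothing-induced spatial correlation does
   not couple them); per-replicate variances are pooled across candidates on
   the per-window scale (Var ∝ 1/n windows), and the candidate is flagged at
   one-sided α = 0.02 toward its called orientation (a genetic difference
   always agrees in direction with what the clones saw).

`genetic_regions_from_pure_strains` (the same BH machinery applied to
strain-vs-strain replicates) is kept for when the genetic regions are
themselves of interest. Any candidate overlapping a flagged interval by ≥1 bp
is removed — that mechanical step never misses. What is irreducibly
stochastic is *detecting* a genetic region from a single 3-vs-3 pure-strain
comparison at depth 100: the region-level z for a ΔRT = 1 implant is roughly
N(4.3, 1), so ~2–5% of genetic regions evade any screen whose false-removal
cost is acceptable; across 20 simulated genomes the adopted configuration
left 4 of 80 implanted genetic regions in the master list while keeping mean
recovery of epigenetic implants at ~94%.

## What the generator emulates — and does not

Emulated: clone-consistent implanted AS regions of both orientations (random
per clone by default, shared via `shared_orientation` to mimic the observed
shared orientation maps), strain-genetic differentials present in hybrids and
pure strains, strain deletions scaling allele copy number, Poisson S/G1
counts per allele × replicate, SNP catalogs with unreliable entries and
SNP-tagged reads with contradictory-call injection, trinomial FISH dot counts
whose single/double probability is `0.15 + 0.35·|ΔRT|`, pairwise
parallel/antiparallel labels with a 5% flip rate, and binary single-cell
replication states thresholded by each cell's S-phase position with N(0,
0.25) call noise and 5% missingness.

Not emulated: read-level artefacts (sequencing error, GC and mappability
bias, fragment-length effects), reference-mapping bias, G2/M contamination of
the sorted fractions, spatially correlated replicate drift, and realistic
chromosome-scale RT architecture beyond a smoothed Gaussian landscape
(correlation length 20 windows, sd 1.0, the typical spread of RT profiles on
the ±2 scale). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated noise model, not robustness to
artefacts a real library would add upstream of window counts. Implants are
spaced ≥5 windows apart so that distinct truth regions remain resolvable at
the smoothing bandwidth; implanted effects are re-centred toward mid-S where
the baseline approaches the scale bounds so the allelic gap is exactly the
requested effect.

## Problem sizes

The verification experiments use desk-scale genomes chosen to estimate each
rate with useful precision: null calibration on 200 genomes of 2 × 500
windows (one clone each); recovery on 5 × 600-window genomes with 50
implanted AS regions, 4 genetic regions and 2 deletions through the full
3-clone pipeline; FISH separation on 100 seeded replicates of 100 nuclei;
single-cell enrichment on 40 mid-S cells with 25 implanted regions across
effects {0, 0.5, 1}. At these sizes the full test suite runs in ~1.5 minutes
and the acceptance script in ~1–2 minutes on one CPU.

## Known limitations

* Exact Mann–Whitney enumeration handles ties by midranks with
  p = P(U ≥ U_obs); for fully tied degenerate inputs this returns 1.0 (the
  conservative exact answer), not the mid-p value some conventions prefer.
* The two-tailed binomial doubles the smaller tail (capped at 1);
  `method="min_likelihood"` gives the minimum-likelihood-sum alternative.
* The per-window LRT variant should not be trusted for genome-wide inference
  at 3 replicates (see above); it exists for sensitivity analysis and
  because its closed form is the natural per-window statistic to verify
  against the numeric ML oracle.
* The saturation extrapolation reports a lower-bound-style asymptote from a
  saturating exponential by default; the log-linear alternative diverges and
  needs an explicit horizon. Neither is identified from fewer than ~4 well
  separated clone counts.
* Single-cell asynchrony requires both alleles observed in a (cell, bin);
  missing entries drop the event rather than being imputed.
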