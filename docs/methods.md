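# Methods

This note records the models, defaults and numerical choices behind
`dvchrom`, in the spirit of the methods documentation of packages like
cooltools or FAN-C. It states what each procedure assumes and where the
design was genuinely open.

## Contact-matrix model and balancing

A contact matrix is binned, symmetric and stored upper-triangularly in
sparse form, with a per-bin validity mask. Low-coverage filtering masks bins
whose marginal falls below 10% of the median marginal over nonzero-coverage
bins; because the median is taken over all nonzero bins, the filter is
idempotent. Balancing solves `diag(b) · C · diag(b) · 1 = 1` on the valid
submatrix — every row of the normalized matrix sums to 1. Unit row sums
(rather than a mean-preserving scaling) make O/E, saddle and aggregate
values directly comparable across samples of different depth; any other
convention is a global rescaling. Two solvers are provided: Knight–Ruiz
(inner–outer Newton iteration with conjugate-gradient inner solves;
default for Hi-C-scale matrices) and symmetric iterative correction
(`b ← b/√s` until `max|s−1| < tol`; the default for very high-resolution
Micro-C-style matrices, where Newton-style balancing is memory-hungry).
Both converge to the same fixed point on connected matrices; a valid bin
with zero contacts makes the problem infeasible and raises immediately.

Expected contacts are the per-chromosome mean normalized value at each
distance separation, with masked pixels excluded from both numerator and
denominator — this makes the per-distance mean of every O/E matrix exactly 1,
an identity the tests assert at 1e-12. Trans expected values (one scalar per
chromosome pair) exist only to support translocation analyses; all standard
features are cis. P(s) curves pool chromosomes into log-spaced distance bins
(default ratio 1.15) and are total-sum normalized (`Σ P(s)·Δs = 1`) so that
curves from different depths align; the derivative is the central difference
of log P against log s. Whether P(s) should be count- or
probability-normalized across samples is not a settled convention; the
normalization is a flag.

## Insulation, boundaries, domains

The insulation score of bin *i* at window *w* is the mean normalized value
of the `w × w` square linking the *w* bins upstream with the *w* bins
downstream, log2-normalized to the chromosome mean of the raw scores. It is
undefined within *w* bins of a chromosome end and wherever more than half
the window pixels are masked (avoiding spurious minima at mask edges).
Boundaries sit at insulation minima where the delta vector — mean insulation
over the `delta` bins ahead minus the `delta` bins behind (default 3) —
crosses zero from negative to positive. The boundary score is
`max(delta over [i, i+delta]) − min(delta over [i−delta, i])`, a measure of
the depth of the minimum; the published pipeline defers this definition to
its insulation library's internals, so the formula here is explicit and
swappable. Boundaries below score 0.7 are dropped.

Consensus boundaries merge calls from a grid of parameter combinations
(2-kb and 5-kb resolution × windows of 4, 6, 8, 10 bins in the embryo
analysis), single-linkage clustered at the coarsest resolution, keeping
clusters supported by at least 4 of the 8 combinations; the consensus
position is the median member midpoint snapped to the finest-resolution bin
(robust to one-bin jitter across window sizes). Domains span consecutive
consensus boundaries, midpoint to midpoint, and are removed outside
10–500 kb. "Pairing" is taken as consecutive pairs only.

## Compartments

Pericentromeric heterochromatin is located from two H3K9me3 log-enrichment
tracks on 10-kb bins: bins positive in both are merged when gaps are under
25 kb, regions under 20 kb are dropped, survivors within 100 kb are merged,
and the largest remaining region per chromosome is taken (the published
analysis picks the region "clearly corresponding" to the pericentromere
without a stated rule; largest-per-chromosome is the documented, swappable
proxy). The enrichment threshold (0, log-ratio convention) is a parameter.

The compartment signal is the leading eigenvector (by eigenvalue magnitude)
of the Pearson correlation matrix of the masked per-chromosome O/E map,
sign-fixed so it correlates positively with GC content; masked and
degenerate bins carry 0. Whole chromosomes are used (no arm splitting).
Saddle plots rank bins by a reference eigenvector — zeros removed first,
quantiles cut on the remainder — and tabulate mean cis O/E per quantile
pair, with all zero-eigenvector bins collapsed into one trailing
row/column. Compartment strength is `(BB + AA) / (AB + BA)` over
`corner_size`-square corner blocks (default 1), so a planted two-state
profile with factor `exp(κ·vᵢvⱼ)` gives strength `exp(2κ)` exactly.

## Aggregates

Domain aggregates rescale each window (domain ± 50% flanks) to a fixed
pixel grid with area-overlap weights — rows of the weight matrix sum to 1,
so constants are conserved and NaNs only renormalize the local weights —
then average across domains. Loop aggregates (APA) average fixed
`(2w+1)²` windows centered on anchor-pair pixels, skipping (and counting)
pairs closer than `w+1` bins to the diagonal; loop strength is the center
pixel over the mean of the 3×3 corner block on the far-from-diagonal side,
the corner least contaminated by distance decay. Enhancer–promoter tables
record the O/E at each pair's pixel (mean over spanned pixels for multi-bin
features, making the center value resolution-independent), with a midpoint
separation floor of 10 kb for aggregate plots; the separate 5-kb
promoter-proximal exclusion used at the assignment stage is an independent
parameter because both rules exist independently in the published analysis.
Cross-condition comparisons use a two-sided Wilcoxon rank-sum test: exact
permutation (midranks, so ties are handled) when both samples have ≤ 10
observations, the tie-corrected normal approximation otherwise.

## Windowed structural similarity

Two balanced maps on the same bins are compared window by window along the
diagonal (500-kb windows, 5-kb steps in the embryo comparisons). Each
window's on-diagonal O/E blocks are log-transformed (`log2(O/E + ε)`,
ε = 1e-4) and compared with the structural similarity index computed
globally over the shared finite pixels, with `c₁ = (0.01·L)²`,
`c₂ = (0.03·L)²` and `L` the joint dynamic range; variances and covariance
are sample (ddof = 1) statistics, matching the scikit-image convention the
tests cross-check against. Windows with fewer than 10 shared pixels are
missing.

Two design choices respond to the shot-noise regime of binned contact data:

1. **Pre-smoothing.** At realistic depths (~10⁶ pairs over ~10³ bins)
   individual pixels are Poisson-dominated and even replicate maps share
   almost no pixelwise structure (ssim ≈ 0.1). The scan therefore smooths
   the log-O/E images with a small Gaussian (σ = 1 bin by default,
   NaN-aware normalized convolution) before computing ssim — the
   image-domain analogue of the local averaging inside the canonical
   windowed ssim. Replicate similarity then sits around 0.5–0.8 and
   structured differences become separable. σ = 0 disables it.
2. **SNR definition.** The published analysis names a per-window
   signal-to-noise ratio without defining it. A definition of the form
   "signal magnitude over s.d. of the pixel difference" turns out to
   *anti*-correlate with real differences (a genuine structural change
   inflates the difference s.d.), which would make the joint calling rule
   (low ssim *and* high SNR) self-contradictory. The SNR here instead
   decomposes the pixel difference `D = A − B` into a spatially coherent
   component `G(D)` (same Gaussian) and a high-frequency residual, and
   reports `sd(G(D)) / sd(D − G(D))`: windows that differ by structure
   score high, windows that differ only by counting noise sit at the
   baseline. The definition is a single function and is swappable.

Both statistics are Z-scored genome-wide over finite windows (all windows
pooled, not per chromosome); a zero-variance track yields all-zero Z-scores.
Differential regions merge overlapping/adjacent windows with ssim Z < −2
and SNR Z ≥ 1. Subtracting a replicate-pair reference track
(`delta = query − reference`; negative = query more different, matching the
published sign convention) removes systematic window-position effects; for
planted-rearrangement detection the thresholds are applied to the Z-scores
of this delta, while plain per-track Z-scores remain the default elsewhere.
The every-100th-window subsampling used for the DE-gene association keeps
only non-overlapping windows before the rank-sum comparison.

## Regulatory linking

Differential H3K27ac statistics arrive as 150-bp windows with log-fold
change and FDR per pairwise genotype contrast; the upstream window selection
and dispersion modeling (csaw/edgeR-style) are consumed, not reproduced.
Windows below the per-window FDR cut (default: the region-level 0.05) merge
across gaps ≤ 100 bp; merged runs wider than 5 kb are packed left-to-right
into regions no wider than the cap (greedy packing is used rather than
equal-count splitting because only it guarantees the width invariant when
window gaps are uneven). Region FDR is the Simes combination of member
FDRs — the default combination in the window-based differential-binding
literature — and regions must be direction-consistent. A genotype's
candidate enhancers are the span intersections of its positive regions
against both other genotypes, minus anything overlapping a promoter window
(TSS ± 500 bp; the published analysis does not state the promoter extent,
so it is a parameter).

Candidate target genes exclude flagged housekeeping genes and genes with
mean TPM < 1 across genotypes; genes absent from the table count as zero
with a warning. Assignment applies four rules in order, first hit wins:
(1) the enhancer intersects transcripts of exactly one candidate gene;
(2) closest promoter not separated from the enhancer by a boundary, where a
boundary separates when its bin lies strictly inside the open interval
between them; (3) closest promoter inside the enhancer's domain (midpoint
containment); (4) closest promoter unconditionally. Distances run from the
enhancer edge to the 1-bp TSS (0 on overlap), ties to the smaller
coordinate. "Closest promoter" is restricted to filtered candidate genes
throughout, since the filter precedes assignment.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
expected intensity
`e(i,j) = (d+s₀)^(−α) · (1+τ·[same domain]) · Π(1+λ·e^(−Δ²/2σ²)) · exp(κ·vᵢvⱼ)`
with counts `Poisson(scale · bᵢbⱼ · e(i,j))`, log-normal biases of mean 1
(σ_bias = 0.2, a typical bin-level bias spread), and `scale` set so the
expected genome-wide total equals the requested depth. Defaults: α = 1
(embryonic-fly-like mid-range decay), s₀ = one bin, τ = 1, κ = 0.4, λ = 1,
σ = 1 bin, depth = 10⁶ pairs — the conditions under which the recovery
tests below are run. Poisson (not negative-binomial) noise is used because
bin-level Hi-C counting noise is well approximated as shot noise.
Heterozygous rearrangements mix the intensity of the rearranged genome,
expressed in reference coordinates, with the wild-type intensity at a
carrier fraction *f* before sampling — the analogue of a pooled collection
in which a subset of individuals carries a balancer. An inversion reverses
bin order within the segment (producing the characteristic long-range
"bowtie" gains across breakpoints); a reciprocal translocation builds both
derivative molecules, and only same-molecule pairs interact. Feature
multipliers stay attached to reference bins; only the distance term follows
the rearranged geometry.

The regulatory generator places single-transcript genes along each
chromosome, flags 20% as housekeeping (expressed everywhere) and 15% as
below the TPM floor, and plants tissue-specific enhancers 2–15 kb from the
TSS of a chosen eligible target gene, constrained to be intergenic, outside
promoter windows, closer to the target's TSS than to any other, and with no
avoided boundary in between. Planted enhancers are tiled with significant
150-bp windows (logFC ≈ +3, FDR ≈ 10⁻⁶…10⁻³) in both contrasts against the
other genotypes (with mirrored negative rows in the reverse contrasts) on
top of null background windows; target genes get a log-normal TPM boost of
median fold 4 in the matching genotype.

What the generator does **not** emulate: restriction-fragment geometry and
ligation artifacts, copy-number variation, distance-dependent
overdispersion, nested/hierarchical domains, compartment-strength gradients
along arms, trans compartmentalization, and realistic transcript isoform
structure. Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated generative model, not end-to-end performance on
real embryo libraries.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately compact
instances — single chromosomes of 1–5 Mb at 1–5-kb bins (500–1,000 bins),
10 replicate genome pairs for rearrangement detection, 20 enhancers per
genotype on a two-chromosome 4-Mb genome — sizes at which every planted
feature is comfortably identifiable and a full run completes in minutes on
one core. All sampling flows through seeded `numpy` generators;
`scripts/acceptance.py` derives every stream from its `--seed` argument, and
fixed seeds reproduce matrices bit for bit.

## Known limitations

- KR/ICE balancing densifies the valid submatrix; fine for ≤ ~10⁴ bins,
  not for genome-wide kilobase bins (out of scope here).
- The boundary score and the ssim SNR are explicit stand-ins for published
  library internals that are not printed anywhere; both are isolated in
  single functions for substitution.
- The saddle's zero-collapse assumes zeros are removed before quantile
  cutting; with very many zero bins the quantile occupancy shrinks
  accordingly.
- `closest_feature` and enhancer assignment are O(n·m) scans — appropriate
  for hundreds of enhancers and thousands of genes, not millions.
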