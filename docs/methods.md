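# Methods

This note documents the model, the estimation procedures, the numerical
choices, and what the simulation-based tests do and do not establish.

## Signal model

Mapped reads are the 5' ends of immunoprecipitated fragments.  Each read is
elongated in its own orientation to a length L (user-supplied, default
150 bp, or inferred; below) and counted into fixed 10-bp bins; a bin counts
every elongated read overlapping it by ≥ 1 bp.  Coordinates are 0-based
half-open internally and in BED/bedGraph output; wiggle output is 1-based
fixedStep, and reported summits are 1-based.

A single binding event is modelled as a Gamma density in genomic distance,
evaluated at bin centers, truncated past the mode where the density falls
below 0.001 of its maximum, and rescaled to unit maximum.  Unit-maximum
normalization makes a fitted coefficient directly interpretable as peak
height in read-count units, and makes the learned shape invariant to
uniform rescaling of the profile.  The Gamma is evaluated at bin centers
rather than integrated over bins; at 10-bp bins the difference is
negligible relative to counting noise.  Bins before the mode are kept even
where tiny, so the kernel support is a single contiguous interval.

## Kernel learning

Training regions are plateau-aware local maxima of the binned profile at or
above a threshold (an absolute intensity or an intensity quantile; the
pipeline default is the 0.998 quantile of all bins, i.e. the top 0.2%),
accepted greedily from the strongest down with mutual exclusion within
twice the region half-width (default 2 kb); ties break to the leftmost
coordinate, and runs touching the chromosome ends never qualify.  Each
training segment has its median subtracted — the local background level —
because an unmodelled constant offset otherwise stretches the fitted Gamma
tails.

The fit alternates two steps, starting from shape 2 and scale L/4 (initial
support ≈ one fragment length):

1. every region is deconvolved with the current kernel (one binding event
   per training region: regions are selected to be isolated peaks, and
   multi-atom fits of a provisional broad kernel systematically poison the
   subsequent shape update);
2. shape and scale are updated by minimizing the total squared residual
   where each region's single placement and height are re-optimized for
   every candidate kernel (a fast correlation argmax; holding placements
   from the previous kernel fixed makes sharp-kernel candidates look
   spuriously bad, since a one-bin misalignment of a tall sharp peak costs
   more than any shape mismatch).

The objective surface is rugged — discretization makes both the truncation
length and the best placement jump — so the update uses a coarse global
grid over (shape, scale) followed by a deterministic multiplicative 3×3
pattern search, run in the (mean, sd) parametrization μ = kθ, σ = √k·θ in
which the Gamma family's stiff ridge is axis-aligned.  Only RSS-lowering
updates are accepted; iteration stops when the relative RSS change drops
below 1e-3 (default) or after 20 rounds.  The per-round report records
(shape, scale, RSS, number of regions whose fit explains ≥ 50% of the
region variance); the recorded RSS path is non-increasing by construction.
On noiseless self-generated profiles the recovered parameters are exact to
the pattern-search resolution (~0.3%); with unit-mean Poisson background
and 55 regions of height 20–60, worst-case relative error is ~1%.

## Fragment-length (read elongation) inference

On one strand, unextended reads pile up over roughly one fragment length to
one side of a point site: with read 5' starts uniform within the fragment,
the per-strand coverage is a flat-topped pattern whose full width at half
maximum equals the fragment length — the read-length half-shifts at the two
50% crossings cancel, and symmetric fragment-length jitter does not move
them.  The estimator builds per-strand coverage with L = read length (no
net elongation), learns a per-strand kernel with the machinery above (this
provides robust alignment), averages the training regions aligned at their
fitted kernel modes and normalized by fitted height (flank-median baseline
removed), and measures the FWHM of that average with sub-bin interpolation.
The two strand estimates are combined by rounded arithmetic mean; estimates
differing by more than 50% of their mean are combined with a warning.  A
forward/reverse summit-distance estimator is kept purely as an independent
cross-check.  Recovery on simulated data: 97/194/292 bp for true lengths
100/200/300.

## Genome-wide deconvolution

Each chromosome is tiled with 20-kb windows overlapping by one kernel
support, so no binding event is ever split unseen; each window owns a
half-open core interval and the cores tile the chromosome exactly.  Within
a window, sites are fitted by non-negative matching pursuit: repeatedly add
the shift maximizing the residual–kernel inner product, refit all selected
coefficients jointly by NNLS, and drop zero (and numerically negligible,
< 1e-9 of the largest) coefficients; stopping when the best new univariate
coefficient falls below `min_coef`, the relative RSS improvement falls
below 1e-4, or 200 sites are fitted.  A deterministic cyclic-replacement
polish then relocates single atoms while that strictly lowers the RSS; with
it, noiseless windows with up to three sites (placements ≥ 2 bins apart,
the practical identifiability limit of a smooth kernel at bin resolution)
reproduce the exhaustive least-squares optimum exactly.  Candidate shifts
are at bin resolution only.  The per-window default
`min_coef = max(2, 3 × median nonzero bin intensity)` suppresses fitting of
flat background; it is logged and overridable (note that the per-window
median makes calls depend weakly on window placement; supplying an explicit
`min_coef` restores exact window-decomposition invariance).  After all
windows are fitted, only candidates inside their window's core survive, and
surviving sites within one bin collapse to the larger coefficient.

## Significance

The null question for a site is: how large a coefficient can the kernel
attain on data that contain everything *except* this site?  For each site
the surrounding profile — with only the tested site's own fitted component
subtracted — is resampled: moving blocks of one kernel length are drawn
with replacement and superposed additively at uniformly random positions in
an initially empty pseudo-segment of the same length.  Block resampling
preserves the bin-to-bin correlation created by elongated reads; the
additive superposition lets background clumps stack, so the null acquires
the extreme-value tail of the observed background (plain concatenation
cannot exceed the largest single fluctuation it copies and is measurably
anti-conservative).  Each pseudo-segment is deconvolved (min_coef = 0, at
most 8 atoms, no polish — the maximum stabilizes within the first few
atoms) and the largest coefficient per replicate, zero if none, forms the
null.  The empirical p-value uses the add-one estimator
p = (1 + #{null ≥ β}) / (1 + n_boot), with floor 1/(1+n_boot) so a zero
never enters Fisher's combination.

Each site receives p-values against 5-, 10- and 15-kb windows centered on
it (windows clipped at chromosome ends that fall below twice the kernel
length yield p = 1, logged) and against one global null built from a seeded
uniform 200-kb sample of the profile, shared by all sites.  The four
p-values are combined by Fisher's method (χ², 2k df).  Bootstrap
sub-streams are keyed by (master seed, site, window), so results are
bit-identical across reruns and thread counts.  With this construction,
site-free simulations at 5 reads/kb background yield
frac(p_combined < α) ≤ 2α at α ∈ {0.01, 0.05, 0.1} over 500+ candidates
(measured ≈ 0), while 50 planted sites of ≥ 30 fragments on 2 Mb are
recovered at ≥ 95% sensitivity within 50 bp at p_combined ≤ 0.01.

When a control sample is supplied (assumed comparable in depth; no scaling
correction is applied, linear depth scaling being unreliable), the control
coverage in the site's 10-kb window is deconvolved with the same kernel.
If the largest control coefficient within half a kernel support of the site
reaches the IP coefficient, the site's corrected p-value is 1 (the pattern
is present in the control); otherwise the IP coefficient is tested against
a bootstrap null of the control-window residuals and the result is
Fisher-combined with the IP p_combined.  The correction is monotone: larger
control coefficients never decrease the corrected p-value.

No multiple-testing correction and no default threshold are applied; the
output is the comprehensive site list with all descriptors plus a
decile/threshold summary table for user thresholding.

## Simulator

The simulator implements the standard ChIP fragmentation model: per site, a
specified number of fragments with truncated-normal lengths (default
200 ± 20 bp, truncated at read length + 1) containing the site at a
uniformly random internal position; the read is the 5' 36-bp prefix of the
fragment on a fair-coin strand.  Background reads are uniform with Poisson
counts per kb (default 0.5 reads/kb in IP and control); the control is
background-only unless shared kernel-shaped artifacts are requested
(`shared_artifacts`), which exercise the control veto.  All draws come from
one seeded generator, so outputs are byte-identical given the spec.

What the simulator does *not* emulate — and therefore what passing tests do
not establish about real data: sequence content, mappability gaps, copy-
number variation, PCR duplication structure, chromatin-state–dependent
background, and broad/composite enrichment domains.  Defaults describe a
sharp transcription-factor-like factor at moderate depth.

## Default problem sizes in tests and the acceptance script

Simulated studies use 2-Mb chromosomes with 50–100 sites (1.2 Mb,
site-free, for calibration), 100 bootstrap replicates, and the defaults
above; these sizes were chosen so each experiment carries enough events for
its statistic (≥ 500 background candidates for calibration, ≥ 50 training
regions for kernel recovery) while a full verification run stays at
desk scale (minutes on one CPU).

## Known limitations

- One kernel per run: mixed sharp/broad programs (or very broad domains
  that would need enrichment-island merging) are out of scope.
- The control correction is a monotone veto-plus-Fisher rule, not a joint
  IP/control model; divergent sequencing depths are not corrected for.
- The global null deliberately includes genuine peaks, trading global power
  for honest calibration; discrimination comes mostly from the local
  windows.
- Positions are reported at bin (10-bp) resolution; sites closer than about
  two bins are not identifiable.
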