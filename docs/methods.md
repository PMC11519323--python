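# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the simulator does and does not emulate, and the
known limitations.

## Simulated contact maps

The generator builds a noise-free expected surface per intrachromosomal bin
pair (i, j) at genomic distance d as a product of four factors:

1. **Distance decay** `(d + d0)^-alpha`. Defaults `alpha = 1.0`,
   `d0 = 2 kb` (one bin). A power law with a short-range offset reproduces
   the qualitative shape of contact-decay curves — steep near the diagonal,
   scale-free beyond — with two parameters and closed forms that tests can
   invert (the log–log slope of the decay curve recovers −alpha at high
   depth).
2. **Domain factor** `beta >= 1` when both bins lie in the same planted
   domain. The WT-like and mutant-like presets differ *only* in beta
   (1.3 vs 2.5), so every recovery contrast between them isolates boundary
   strength.
3. **Loop factor** `f >= 1` on a small square footprint at each planted
   anchor pair.
4. **Compartment factor** 1 for same-label pairs and
   `(1 - gamma) + gamma * c` (`c = 0.4` fixed) for cross-label pairs of an
   alternating A/B block pattern. Block lengths are irregular (2–4 ×
   100 kb): a strictly periodic checkerboard is spectrally degenerate,
   because per-distance normalization absorbs all signal at distances
   commensurate with the period and the leading eigenvalue splits in two.
   Real compartment domains are irregular, so the simulator is too.

Counts are drawn once per unordered pair as
`Poisson(s * b_i * b_j * E_ij)` and mirrored (exact symmetry by
construction). The `b_i` are log-normal coverage biases (sigma = 0.2 by
default) and `s` scales the total expected count to the configured
sequencing depth. Everything — biases and counts — derives from the single
config seed, so a config is a complete, reproducible description of a
dataset.

**Standard layout.** The demo truth tiles a 1-Mb arm (500 × 2-kb bins) with
domains of 25–45 bins separated by 10–14-bin gaps, the first and last
domains flush with the chromosome ends. Two properties of iteratively
corrected maps motivated this geometry over a "domains floating in open
chromatin" layout:

- Balancing equalizes marginals, so it *redistributes* structural coverage
  differences: domain bins (high marginal) are deflated, gap and margin
  bins inflated. Long empty margins therefore wash out the insulation dip
  at the first and last boundaries; tiling the arm removes the margins.
- Bins near chromosome ends lose long-range partners; balancing compensates
  by inflating them, which lifts insulation scores near the ends. Keeping
  the outermost *interior* boundaries ≥ 45 bins from the ends (larger first
  and stretched last domain) moves them out of this zone.

Domain edges that coincide with chromosome ends are not insulating
boundaries and are excluded from the truth boundary list.

**What the simulator does not emulate:** interchromosomal contacts,
pericentromeric heterochromatin, nested or hierarchical domains, replicate
biological variability, restriction-fragment geometry, and mapping
artifacts beyond smooth multiplicative coverage bias. Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not performance on real libraries — in
particular, real low-mappability bins violate the multiplicative-bias
assumption in ways the log-normal biases do not probe.

## Balancing

ICE-style simultaneous correction: each round divides row/column i by
`marginal_i / mean(marginals)` over unmasked bins and multiplies the
update into the bias vector; the convergence measure `eps` is the maximum
absolute relative change of the bias vector between rounds, with the
stopping rule `eps < 1e-4` (and an explicit non-convergence error carrying
the final eps otherwise, including the disconnected case of an unmasked
all-zero row). The bias-vector form of eps is equivalent in the limit to
comparing consecutive corrected matrices and is cheaper. Bin filtering
masks zero-marginal bins always, plus bins below a marginal quantile
(default 0.02) of the nonzero marginals.

## Insulation

The raw statistic for bin i is the mean balanced contact over the square
`rows i-w..i-1 × columns i+1..i+w` (w = window / bin size, default
50 kb / 2 kb = 25) — the contacts that *cross* i with each side reaching at
most 50 kb away. The score is `log2(raw_i / arm mean of raw)`, hence
invariant to the global scale of the balanced matrix; the reference mean is
per chromosome arm because exclusions and translocation handling operate
per arm.

Validity: the full window must fit inside the arm, the bin must not overlap
the exclusion set, and at least half the window's pixels must join two
unmasked bins (the mean is taken over those pixels). The focal bin's own
row and column never enter the window, so a masked focal bin still carries
a score; invalidating it would let each masked bin punch a 2w-wide hole in
the track, and with a quantile-based filter — which preferentially masks
structurally depleted bins — that cascades into losing exactly the minima
the analysis is after.

Minima: bin i is reported when its score equals the minimum of the
centered window of `span` bins (default 10), with ties resolved to the
leftmost bin of a plateau and later members of a tie suppressed; bins
within ceil(span/2) bins of a validity edge are not called. Insulated
regions extend each sub-threshold minimum (threshold −0.25) to the maximal
contiguous run of sub-threshold bins; runs holding several minima are split
at the maximum-score bin between consecutive minima, so each region
contains exactly one.

## Domains

The per-pixel "TAD score" is the distance-normalized observed/expected
ratio, with the expected value computed per arm as the mean balanced
contact at each bin distance. Cutoffs just below and above 1 (background
0.95, border enrichment 1.05) are only coherent for a ratio statistic
centered at 1, which is what motivates this scoring; it is isolated behind
`observed_over_expected` so an alternative statistic can be swapped in.

Candidates are anchored on insulation structure: the start/end bins of
insulated regions, plus the arm ends. Because the sub-threshold run leaks a
few bins into each flanking domain before the score recovers, each
candidate edge is then snapped to the outermost position (radius 8 bins)
where the border row/column mean O/E clears the border threshold, requiring
two consecutive enriched rows to resist single-row noise. A candidate
passes when ≥ 6 interior pixels score above 0.95 and the border pixels
average ≥ 1.05; overlapping passes are resolved greedily by descending mean
interior score, discarding candidates overlapping an accepted call by more
than 50% of either length. Size limits default to 12–500 kb. The arrowhead
directional contrast is provided as an independent view of the same
structure and is tested against its defining formula.

## Loops

The distance prior pools bias-corrected counts into 40 contiguous
equal-occupancy distance groups over 4–100 kb, assigns each distance its
group mean, enforces monotone non-increase by weighted isotonic regression,
and normalizes probabilities over the modeled pairs. When the number of
groups reaches the number of distinct distances the pooling degenerates to
one group per distance.

Significance: with N the total count over modeled pairs and
`p_ij ∝ f(d_ij) b_i b_j` renormalized to sum to 1, the p-value is the
binomial upper tail `P(X >= x_ij)`, and q-values are Benjamini–Hochberg
over *all* modeled pairs, zero-count pairs included (this fixes the
multiplicity m; excluding them would bias q downward).

**Band-restricted bias refinement.** Genome-wide balancing biases encode a
compensation for chromosome-end truncation that is wrong *within* a
distance band: an end bin's deflated bias underpredicts its short-range
counts, which concentrated false calls at the arm ends (empirical FDR
~0.67 on null maps). The model therefore refines the per-bin multipliers
against the band-restricted expected counts — alternating the distance
profile and a Sinkhorn-style per-bin ratio update (square-root damped),
4 rounds by default — and significance testing uses the refined vector.
With it, the empirical FDR at q < 0.05 is ~0.03 with recall ~0.96 over the
20-seed planted-loop benchmark, and null maps yield no calls.

Loop-set comparison matches anchors within ±1 bin by default (the matching
tolerance of the shared-loop statistic is not standardized; it is a
parameter). Size classes: < 10 kb, 10–50 kb (inclusive), > 50 kb.

## Compartments

Per arm: aggregate balanced values to coarse bins (default 50 kb — arms of
this genome are short), distance-normalize, **column-center**, take the
Pearson correlation matrix across coarse bins, and report the eigenvector
of the largest eigenvalue. Column centering removes a shared
coverage/arm-end component that otherwise dominates the spectrum with a
one-signed eigenvector even when no compartments exist. Distances whose
mean aggregated value is tiny are set to the neutral ratio 1 (shared
Poisson-zero patterns masquerade as correlation).

Degeneracy guard: an arm's labels are defined only when
`lambda_1 / lambda_2 >= 3.0`. On simulations the unstructured regime tops
out near 2.3 and the structured regime starts near 5.4, so 3.0 separates
them with margin; arms failing the guard, or with fewer than 10 valid
coarse bins, are left unlabeled with a warning. The eigenvector sign is
arbitrary and is oriented positively against a user-supplied reference
activity track (gene density or an active mark); A = positive entries.
The swap fraction between two samples is the fraction of co-labeled coarse
bins with discordant labels.

## Aggregation

Pileups average O/E (not raw balanced) windows so distance decay does not
dominate; a raw mode is a matter of passing a different matrix. Rescaled
domain pileups resample each interior to a fixed bin count by nearest-bin
lookup with flanks at native resolution. Profiles are signed-distance
histograms (point features, normalized per border) or overlap-weighted
track means (signal), with uncovered steps reported as missing, not zero.
Border orientation defaults to unoriented — both transcription directions
pooled. The Mann–Whitney U test is exact for the smaller group ≤ 8 without
ties, otherwise the normal approximation with tie correction; two
identical constant samples give p = 1 by convention. Expression quintiles
are assigned ascending with ties broken by input order, sizes differing by
at most one.

## Pipeline

A single flat configuration object holds every stage parameter with the
analysis defaults (2-kb bins; insulation window 50 kb, span 10, threshold
−0.25; domain cutoffs 0.95 / 6 / 1.05; loop range 4–100 kb, q < 0.05;
balancing eps 1e-4); unknown keys are rejected and the full parameter set
is echoed into the manifest. The demo workflow simulates a WT-like and a
mutant-like sample over the same truth layout (2 Mb — long enough that the
compartment stage has material to work with), runs every stage, and writes
per-stage statistics plus SHA-256 hashes of every output file; all writers
emit fixed-precision text, so identical config + seed reproduces identical
hashes. A stage failure leaves a `<sample>.<stage>.partial` marker and an
error naming the stage.

## Problem sizes

The bundled analyses run on 0.4–2-Mb single-arm genomes at 2-kb binning
(200–1000 bins), depths 2×10^5–10^7, and 20-seed batches for the loop
error-control benchmark; the full test suite and the acceptance script each
complete in well under a minute on one CPU. These sizes were chosen so the
planted structures (25–45-bin domains, 6–92-kb loops, 200–400-kb
compartment runs) are comfortably resolvable at the analysis parameters.

## Known limitations

- The domain caller is anchored on insulation structure (plus arm ends);
  a domain whose boundaries produce no insulation signal at all will not be
  proposed. The arrowhead transform is computed but not used as an
  independent candidate source by default.
- Balancing absorbs part of the planted domain enrichment into the biases
  (domain bins have genuinely higher marginals), so post-balancing O/E
  contrasts are weaker than the planted beta; gap segments between strong
  domains acquire mild apparent enrichment and occasionally pass the
  caller at its published cutoffs.
- The loop model tests pairs independently; clustered loop pixels are not
  merged into single loop calls.
- Compartment labels are per coarse bin with no sub-compartment structure,
  and orientation requires a reference track.
- cool-container I/O is not implemented; matrices travel as bins/triplets
  TSV.
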