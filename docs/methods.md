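# Methods

## Viability normalization and Hill fitting

Raw CellTiter-Blue-style fluorescence is processed in the order the
assay implies: blank-well background subtraction, normalization to the
untreated reference (`nI = 100·I/I0`, percent of untreated), replicate
averaging (`anI`), then a nonlinear least-squares fit of the decreasing
Hill sigmoid `anI(D) = min + (max−min)/(1+(D/IC50)^H)`. Fitting is done
on the replicate-averaged pattern by default (fitting each replicate
and averaging IC50s is a deliberate non-default; the averaged pattern
is what the normalization chain produces), and the dose-0 point is
included since the sigmoid is defined there.

Numerical choices:

* **Initialization** — `min0`/`max0` from the observed extremes, `IC50_0`
  at the dose whose response is nearest the midpoint, `H0 = 1`; up to 10
  restarts jitter `IC50_0` by a factor in [0.1, 10] (seeded, default 0)
  before the fit is declared non-converged.
* **Bounds** — plateaus in [0, 200] % (instrument drift can push the top
  plateau above 100), `H ∈ (0, 20]`, `IC50 > 0`. These keep the
  decreasing branch of the sigmoid; increasing responses are out of
  scope.
* **Trust window** — a fit whose IC50 lies outside the observed dose
  range by more than a configurable factor (default 100×) keeps its
  parameters but is flagged non-converged; profile building excludes
  flagged lines with a warning.
* **Degenerate inputs** — fewer than 4 distinct non-zero doses or a flat
  response raise errors rather than returning meaningless parameters.

Per-line IC50s become a profile via min-max normalization
(`nV ∈ [0, 1]`) and ascending average ranks (rank 1 = most sensitive);
ties get average ranks so downstream rank correlation stays
well-defined. Timepoint aggregation averages the *normalized* values
(the µM scales differ across timepoints), then re-normalizes and
re-ranks; the aggregated profile's `values` are therefore unitless.

## Exact small-sample correlation screen

Transcripts are first filtered on detection calls: only those called P
or M in every cell line are screened. The screen computes Spearman's
rho (average ranks, then product-moment correlation) between each
transcript's cross-line pattern and the normalized IC50 profile, with
p-values from the **exact permutation null**: all n! permutations of
the profile's rank multiset are enumerated (ties permute the observed
tied ranks), and the one-sided p-value is the fraction of permutations
at least as concordant. At n = 5 the null has 120 permutations, the
one-sided floor is 1/120 ≈ 0.0083, and P(rho ≥ 0.9) = 5/120 ≈ 0.0417 —
so rho ≥ 0.9 is the smallest correlation passing α = 0.05 one-sided.
Two-sided selection at n = 5 would admit only |rho| = 1 (p = 2/120),
which is why one-sided is the default; a two-sided flag exists.
Above a configurable cap (default n = 8, i.e. 40320 permutations) the
t-approximation replaces enumeration with a logged notice. No
multiple-testing correction is applied by default (the screen reports
nominal p < α as a discovery filter); Benjamini–Hochberg is optional.
Pearson correlation is available as an option and reuses the same
permutation scheme on raw values.

Degenerate patterns (constant across lines) get rho = 0, p = 1 and a
flag; transcripts with missing values among the aligned lines are
dropped with a logged count. Cell-line alignment between matrix and
profile is by exact case-folded label match — no fuzzy matching.

## Gene-set overlap

For a universe of N transcripts (by default the detection-filtered
set), a K-member hit set and an n-member reference set with k shared
labels, the test statistic is the inclusive upper tail
`P(X ≥ k) = Σ_{j=k..min(K,n)} C(K,j)·C(N−K,n−j)/C(N,n)`, computed in
log space (scipy). The point probability `P(X = k)` is reported
alongside because `hgt(N,K,n,k)`-style printed values in the wild
sometimes correspond to the point mass rather than the tail; for the
overlap sizes this test targets the two agree in order of magnitude and
differ only at the second significant figure, so conclusions do not
depend on the convention. Labels outside the universe are dropped with
a logged count before testing.

## Motility statistics

Speed is total path length over tracked duration; persistence is the
directionality ratio (net displacement / path length) multiplied by
`sqrt(t_tracked / t_max)`. The square-root-time penalty down-weights
short tracks, whose directionality ratios are upward-biased. A
stationary cell (zero path length) has persistence defined as 0 with a
degenerate flag, resolving the 0/0. Gaps in tracks are handled by
taking steps between available consecutive observations, with no
interpolation. `t_max` defaults to 2880 min (a 48 h acquisition at
20 min frame intervals).

## Synthetic-data generators

The generators define the conditions every property test and the
end-to-end run operate under; all are deterministic given their seed.

* **Plates** — five cell lines with true IC50s of 5/9/14/22/30 µM, Hill
  coefficients 1.0–1.8, bottom plateaus 6–12 %, top plateau 100 %
  (viability at dose 0 is 100 % of untreated by construction); a dose
  ladder of 0 plus eight 2-fold steps up to 100 µM; 6 replicates;
  additive Gaussian noise on raw intensity (multiplicative optional)
  against a reference intensity of 10000 and background 500. Untreated
  wells are dose-0 samples of the same Hill law and define I0, so
  fitted parameters are recovered on the untreated-normalized scale
  (exact when the true top plateau is 100, the default). Real dose
  grids are compound-specific; the 2-fold default is a documented
  convention, not a claim about any particular compound.
* **Expression** — planted-positive transcripts follow the planted
  susceptibility signature's ordering (planted-negative the reverse)
  plus optional Gaussian pattern noise on top of a per-transcript
  baseline (log-intensity scale, mean 7, sd 1). Null transcripts are
  drawn exchangeably over the *sub-critical* orderings: patterns are
  redrawn while their |rho| with the signature reaches the configurable
  threshold (default 0.9, the n = 5 one-sided α = 0.05 critical value).
  This makes the planted sets exactly identifiable by the exact-p
  screen — the property the generator exists to provide — at the cost
  of realism: real data contains chance correlates at the nominal rate,
  so perfect precision on these fixtures says nothing about false
  discoveries in real screens. Detection calls are independent per
  cell: Absent with the configured probability, the remainder split
  evenly P/M (the filter treats P and M identically). The default
  universe of 22277 transcripts mirrors the size of a
  detection-filtered microarray panel; it is plumbing, not a biological
  constant.
* **Tracks** — persistent random walks: each step direction is the unit
  blend of the previous direction (weight = turning persistence in
  [0, 1)) and a fresh random direction; step length is speed × frame
  interval, with optional between-cell speed spread; per-frame dropout
  ends tracks early (never below two points, so speed stays defined).
  The walk has no confinement, collisions or division — adequate for
  testing the statistics, not for modelling crowded monolayers.

## Problem sizes

Tests and the end-to-end run use scaled fixtures chosen for tight
feedback loops: screens of 1000–2000 transcripts (the planted-recovery
guarantee is size-independent since each transcript is tested
marginally), 20 noisy-plate replications for IC50 error, and 100 cells
per persistence level. The overlap statistic is computed at the full
reported size (N = 22277) since it is closed-form.

## Known limitations

* The exact screen is marginal per transcript; correlated transcripts
  (co-regulated modules) violate any implicit independence reading of
  the selected-set size.
* With n = 5 lines the achievable p-values are a 12-point grid;
  reported p-values should be read as exact null tail masses, not as
  continuous evidence strength.
* Probe-to-gene collapsing is not performed in the screen; signature
  lookups match row labels as given.
* The Hill fit assumes a monotone decreasing response; biphasic
  (hormetic) responses will fit poorly and should be caught via the rss
  and the trust flag.
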