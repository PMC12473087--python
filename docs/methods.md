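# Methods

This note documents the models, defaults, and numerical choices behind
fmenkit, and what the synthetic benchmark does and does not demonstrate.

## Guild annotation

An OTU is matched against the guild database at the most specific rank of
its lineage (species → kingdom) that has a record with confidence at or
above the floor (`min_confidence`, default **Probable**, the common
community convention; exposed as a flag since published analyses rarely
state their filter). Composite trophic-mode labels
(e.g. *Pathotroph–Saprotroph–Symbiotroph*) are atomic categories and are
never split into components; the guild label `NULL` is a literal category.
Relative abundance of a category in a sample is
100 × (counts of its OTUs) / (total counts), so assigned categories plus
*Unassigned* sum to exactly 100%. Site-level values are unweighted means
over the site's samples (appropriate for balanced designs). Dominant
guilds are the top-*k* (default 10) by mean relative abundance, ties
broken lexicographically for determinism.

## Between-site statistics

* **t-tests** default to Welch (unequal variances); with balanced groups
  and similar standard errors, Welch and Student agree at the 2-decimal
  precision used in field reports, and a flag selects Student. Tests can
  be run from published summaries: t = (m₁−m₂)/√(SE₁²+SE₂²) with
  Welch–Satterthwaite df, or pooled variances (s_i² = n_i·SE_i²) with
  df = n₁+n₂−2. Degenerate inputs follow explicit conventions: both
  groups constant and equal → p = 1; constant but unequal → flagged
  degenerate with p = 0.
* **Wilcoxon rank-sum** uses exact enumeration over all C(n, n₁) group
  relabellings when n₁+n₂ ≤ 14 (ties handled by the ½-count U statistic;
  two-sided p = doubled smaller tail, capped at 1), otherwise the normal
  approximation with tie and continuity corrections. For continuous data
  at small n the approximation stays within 0.05 of the exact p; with
  heavy ties the exact p's discreteness can push the difference to ~0.15,
  which is inherent to the approximation, not an implementation artifact —
  the exact path is used automatically in that regime.
* **Correlation screens** report Pearson r with two-sided p per
  (category, soil variable) pair on per-pair complete cases; constant
  vectors or fewer than 3 complete pairs give missing cells with a
  warning. No multiple-testing correction is applied by default, matching
  common reporting practice for these screens; Benjamini–Hochberg columns
  are available behind a flag.
* **RDA** column-centers the response and standardizes predictors, fits
  the multivariate least-squares regression (pseudo-inverse under
  collinearity, with a logged warning), and takes the PCA of the fitted
  values; the constrained proportion is the fitted share of total
  variance, and constrained plus residual eigenvalues reconstruct the
  total to 1e-9. The response is the raw relative-abundance matrix by
  default; a Hellinger transform is available since the appropriate
  transform is study-specific. Axis significance (permutation tests) is
  out of scope.

Stars follow the usual mapping: `***` p < 0.001, `**` p < 0.01,
`*` p < 0.05, `-` otherwise; p-values are printed at 2 decimals in
table-style reports and kept at full precision in machine output.

## Network construction

Per-site preparation: restrict to the site's samples (≥ 4 required), drop
OTUs detected in fewer than `min_prevalence` samples (default: half the
samples, rounded up — 8 of 15 in the reference design; standard practice
for co-occurrence analysis and exposed as a flag), convert to relative
abundance, replace zeros by half the smallest nonzero relative abundance
in the prepared matrix, and take log10. A pairwise-complete alternative to
the half-minimum rule was considered and rejected for the default because
it makes the correlation matrix non-positive-semidefinite, which
complicates the spectral step.

**RMT threshold.** For each cutoff on the grid (default 0.30–0.99, step
0.01), entries with |r| below the cutoff are zeroed (unit diagonal kept),
rows/columns with no surviving off-diagonal entry are dropped, and the
eigenvalues of the remaining matrix are computed. Duplicate eigenvalues
are collapsed before unfolding (degenerate levels carry no spacing
information and would swamp the histogram's first bin). The cumulative
spectral density is smoothed with a cubic least-squares spline on 11
interior knots at quantiles (reduced automatically for small or clumpy
spectra); nearest-neighbour spacings of the unfolded eigenvalues are
normalized to mean 1. Goodness of fit against Poisson exp(−d) and the GOE
Wigner surmise (πd/2)·exp(−πd²/4) uses a chi-square statistic on
equal-probability bins (⌈√#spacings⌉ bins, df = bins − 1); equal-probability
binning keeps expected counts uniform, which is where the chi-square
approximation is most reliable. The chosen cutoff is the smallest grid
value where Poisson is not rejected (p > 0.05) while GOE is rejected;
if no such value exists the best Poisson fit is used with a logged
warning. Cutoffs leaving fewer than 20 nodes are skipped — NNSD
statistics are meaningless below that.

Calibration: on 500×500 GOE matrices the NNSD test passes the Wigner fit
and rejects Poisson in ≥ 9 of 10 seeds, and on planted 5-block correlation
data (within-block |r| ≈ 0.9, between-block |r| ≈ 0.3, n = 200) the chosen
cutoff falls strictly between the two correlation levels. Note that with
*mutually independent* blocks at n = 200 the between-block sample
correlations never reach 0.30, so the Poisson regime already holds at the
grid start and the "transition" is at the boundary; the calibration
construction therefore includes a weak global factor so the transition is
interior and actually exercised.

**Graph.** An edge joins i and j iff |r_ij| ≥ cutoff; its sign is the
correlation sign. Absolute-value thresholding is used (both signs appear
in thresholded networks, which implies the cutoff applies to |r|).
Isolated OTUs are excluded. Topology is computed on the unweighted simple
graph — the sign is a display/counting attribute only. Average path
distance is the mean geodesic over connected pairs; disconnected pairs
are excluded rather than infinite, so sparse networks still report a
finite value. The degree power-law R² is the coefficient of determination
of the log₁₀P(k)–log₁₀k least-squares fit over observed degrees, and is
undefined (reported missing) with fewer than 3 distinct degrees.

## Modules and node roles

Module detection is greedy agglomerative modularity maximization with a
deterministic tie-break (lexicographically smallest representative pair),
run to completion with the best partition retained, followed by a
deterministic local refinement: single-node moves (including splitting
off to a singleton) and pairwise swaps are applied while any increases Q.
The refinement matters: plain greedy agglomeration can stop more than
0.05 below the optimum even on 7-node graphs (a known weakness of
merge-only schemes); with refinement the achieved Q is within 0.05 of the
exhaustive-enumeration optimum across random ≤ 8-node suites. Modularity
is Q = Σ_c [e_c/m − (d_c/2m)²]. Module ids are numbered 1..m by
decreasing size.

Zi uses the population standard deviation of within-module degrees, with
Zi = 0 in zero-spread modules (the standard within-module degree
convention plus degenerate-module safety). Pi = 1 − Σₛ(k_is/k_i)²; role
thresholds are Zi = 2.5 and Pi = 0.62. Percentages in the role census are
rounded to 2 decimals; full precision is retained internally.

## Module summaries and soil correlation

A module's representative signal is its **eigengene**: the first right
singular vector (sample space) of the member OTUs' z-scored log
abundances, sign-oriented so the mean correlation with member profiles is
non-negative (positive first element on exact zero), standardized to zero
mean and unit variance — the established module-summary convention; a
standardized mean-profile alternative is available behind a flag.
Singleton modules return the member's profile with a warning. Hierarchies
use average linkage on d = 1 − r (d ∈ [0, 2], heights monotone).
Module–soil screens correlate eigengenes with the soil variables of the
same per-site samples used to build that site's network.

## Synthetic community generator

The generator emulates the reference study design: 2 sites × 15 samples,
~2900 OTUs of which 60% resolve against a bundled toy guild database
spanning all 7 composite trophic modes, 6 planted correlation modules of
25 OTUs each, and 13 soil variables coupled to module factors. Per-module
latent factors f_m ~ N(0,1) per sample drive members' log10 abundances
(base + loading·f_m + noise; defaults loading 0.85, noise sd 0.30);
counts come from exponentiating, applying a lognormal per-sample depth
multiplier (sd 0.15), rounding, and zeroing below a detection floor —
preserving correlation structure while yielding sparse integer tables.
Module members draw higher baselines (log10 base N(2.0, 0.4)) than
background OTUs (N(0.8, 1.0)), so module OTUs are prevalent and the
background exercises the prevalence filter. Soil variables are
z = Σ_m c_vm·f_m + N(0,1), normalized and rescaled onto field-realistic
units with site-level offsets; with the planted |c| = 0.9 couplings this
yields a population factor–soil correlation of 0.9/√1.81 ≈ 0.67. The
exactly-60% assigned fraction is met by construction (module OTUs are
annotated first so network nodes carry trophic modes). The taxonomy pool
is a plausible but synthetic stand-in, not a curated reference, and the
guild pool is smaller than a real database's ~81 observed guilds.

Recovery benchmarks run at 1 site × 30 samples with 600 OTUs and 15 OTUs
per module. The module fraction matters: when module members dominate
per-sample totals (e.g. 150 of 300 OTUs), the relative-abundance
(log-ratio) conversion leaks every module's factor into each eigengene
through the shared total, attenuating factor and soil correlations. The
benchmark keeps module members a small fraction of the community
(90/600 = 15%), consistent with the default configuration's 150/2900 ≈ 5%.
Under these conditions module detection recovers the planted partition
with median adjusted Rand index ≥ 0.8 (typically 1.0) over 10 seeds, and
planted |0.9| soil couplings are recovered with the correct sign and
p < 0.05 in ≥ 9 of 10 seeds.

**What passing does and does not show.** The generator produces
log-normal, factor-driven abundances with independent Gaussian noise. It
does not emulate compositional count noise (multinomial sampling),
phylogenetic correlation, overdispersion, batch effects, or guild-level
abundance structure; recovery on it demonstrates that the pipeline's
inference chain is correct and well-calibrated, not that real rhizosphere
data meet its assumptions.

## Problem sizes and determinism

The acceptance script analyses an 800-OTU community at the default
2 × 15 design and runs 5 recovery replicates and 10 GOE calibration
draws — sizes chosen so a single-CPU run completes in well under a
minute per stage while keeping the spectral statistics meaningful. All
randomness flows through one seed; identical (config, seed) pairs give
byte-identical outputs, and the pipeline manifest records the seed and a
checksum per output file.
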