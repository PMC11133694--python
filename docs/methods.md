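# Methods

This note records the modelling and numerical choices behind energyscape:
what is computed, under which assumptions, and which decisions were open
and how they were settled.

## Model and fitting

The pairwise maximum-entropy model assigns each joint ±1 activity pattern
of N networks the energy `E(V) = −h·σ − ½ σᵀJσ` (J symmetric, zero
diagonal) and probability `P(V) ∝ e^{−E(V)}`.  The energy is a statistical
index of occurrence frequency, not a metabolic quantity.  All computations
enumerate the `2^N` patterns exactly; the implementation caps N at 20 and
is intended for N around 9 (512 patterns).  No pseudo-likelihood or
sampling-based fitting is provided: exact enumeration is the point of the
small-N regime.

Binarization thresholds each network at its mean over the group's
concatenated time series (subject-major order).  Values exactly equal to
the mean map to −1 — the inactive side — so the rule is deterministic;
thresholds are group-level, matching the one-model-per-group design.  A
per-cohort thresholding variant is deliberately not offered.  Pattern
indices use network 1 as the least-significant bit; the all-inactive
pattern is index 0.  This convention is shared by every module and by all
written tables.

Fitting runs plain gradient ascent on the moment mismatch,
`h ← h + ε(⟨σ⟩ − ⟨σ⟩_m)` and `J ← J + ε(⟨σσ⟩ − ⟨σσ⟩_m)`, starting from the
closed-form independent fit `h = atanh⟨σ⟩, J = 0` (which also defines the
D₁ reference model).  Defaults: learning rate 0.1, tolerance 1e−5 on the
maximum absolute moment gap, 50 000 iterations cap.  The learning rate is
halved only after 25 consecutive iterations of gap growth; transient
oscillation of the gap is normal near convergence and must not trigger
decay (halving on any single increase collapses the step size and stalls
the fit — observed, hence the window).  A tenfold gap growth over a
100-iteration window raises a convergence error naming the learning rate.
Fit accuracy uses base-2 KL divergences; empirical-zero patterns
contribute nothing to either divergence (0·log 0 = 0), and R is reported
missing with a warning if D₁ = 0.

## Landscape

Local minima require energy strictly below all N single-flip neighbours; a
landscape whose energies are exactly tied everywhere has no strict minima
and is reported as a degenerate failure rather than guessed.  Steepest
descent moves to the lowest-energy strictly-lower neighbour.  Ties among
equally lowest neighbours are broken by flipping the lowest-index network.
This rule was chosen over "smallest pattern index" deliberately: both are
deterministic, but only the flip-order rule respects the inversion
symmetry of a symmetric double well, whose two saddle patterns then split
one per basin (sizes 0.5/0.5) instead of both falling into the
lower-indexed well.  Ties have measure zero for generic parameters, so the
rule only matters for hand-constructed symmetric landscapes.

The disconnectivity tree follows the threshold-sweep definition: patterns
with energy ≥ E_th are removed and E_th descends through the sorted unique
energy values; two minima's branch height is the threshold at which no
surviving path connects them.  The implementation realises the sweep
bottom-up as a union-find pass over patterns in ascending energy order —
the recorded merge energies are exactly the minimax-path saddle energies,
and the equivalence is asserted against a brute-force threshold-sweep
oracle on small landscapes in the test suite.  Newick export encodes
branch lengths as parent-threshold minus child energy.

Brain states are groups of minima.  An explicit mapping is honoured
verbatim (in the emulated study design, six minima map to three states,
with the all-active minimum forming the third state on its own — the
study text is internally inconsistent on this point and the all-active
reading is used).  Because a hierarchical grouping from a figure is not
reproducible in general, a k-cut mode removes the k−1 highest internal
nodes and labels each remaining subtree a state; states are numbered by
their deepest minimum's energy so labels are stable across similar
landscapes.

## Dynamics measures

Each time point maps through its basin's minimum to a state; runs never
cross subject boundaries.  Appearance frequency is time points in state
over T; mean duration is the mean maximal-run length (time points; the
repetition time, default 3 s, is metadata for conversion to seconds); mean
energy averages the *visited patterns'* energies over the state's time
points, not the minimum's energy — time-point-level averaging is the
reading that generalises to simulation.  Unvisited states report frequency
0 and missing duration/energy; missing values are dropped (not zero-filled)
in group tests.

Transitions are read off the run-length-compressed sequence.  A triple of
runs (A, C, B) with A ≠ B, C distinct from both, and dwell(C) ≤ d_max
(default 1 time point) counts once as an indirect transition A→B and
suppresses its two constituent direct steps; remaining adjacent run pairs
are direct transitions.  Triples are resolved greedily left to right.
This is the minimal operationalisation of "indirect transition through an
intermediate state" under which direct + indirect counts equal the total,
so the reported frequencies (count / total transitions) are exhaustive;
d_max is configurable and the definition is a documented choice, not a
claim about any other implementation.  In/out frequency of a state counts
transitions with that state as source or target over total transitions;
the brief intermediate of an indirect transition is neither.

## Simulation

The Metropolis kernel proposes one of N neighbours uniformly and accepts
with `min(1, e^{E_cur − E_prop})`; rejections consume a time step (dwell
times need a defined clock).  The kernel satisfies detailed balance with
the enumerated Boltzmann law — asserted exactly on the explicit `2^N × 2^N`
matrix for small N — so long walks sample `P(V)`; the default walk length
is 10⁵ steps with a uniform random start, with no burn-in discard by
default.  Group comparison of simulated dynamics uses count tables
(time points per state, runs per state, transition counts per pair, in/out
counts) under chi-square tests with post-hoc adjusted standardized
residuals, since frequencies themselves are not chi-square testable.

## Group statistics

Two-sample comparisons use the pooled-variance Student t (the printed
summary statistics of the emulated study's demographic table recompute to
within 1% under this form at n = 30/30; the Welch form is available by
flag).  The summary-form t is the same formula evaluated from means/SDs.
Multiple testing uses Bonferroni within explicitly declared families —
per measure type across its 3 states or 3 state pairs — because family
sizes are a reporting convention, not a statistic.  Chi-square tests are
Pearson's, with adjusted standardized residuals
`(O − E)/√(E(1 − row/n)(1 − col/n))` and two-sided normal p values
Bonferroni-corrected across cells.  Behavior correlations are Pearson's r
per group, computed only for measures that survived the family-corrected
group comparison.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
two groups of S = 30 subjects, N = 9 networks, T = 140 time points each.
Per subject a ±1 pattern sequence is drawn from the group's Boltzmann law
by the Metropolis kernel started from a stationary draw, so the marginal
law is exact; an optional self-repeat probability (persistence) lengthens
dwell times without changing the stationary law.  A thinning factor
(default 40 elementary moves per observed time point) models a sampling
interval that is long relative to the underlying dynamics — one 3-s volume
spans many elementary pattern moves.  Without thinning the single-flip
kernel produces only ~1–5 state transitions per subject per scan, which
would make every transition measure degenerate; at thin = 40 subjects show
~25–40 transitions and mean dwell times around 5 volumes (~15 s), in the
range reported for resting-state brain states.  Persistence defaults to 0
because the thinned kernel already supplies realistic temporal structure.

Continuous signals are `pattern × snr + unit Gaussian noise` per network
and time point with zero baseline, so group-mean thresholding is the
correct decoder: at snr = 10 binarization recovers ≥ 99% of generating
values; the default snr = 1 leaves a realistic ~16% bit-error rate.
Behavior scores are `intercept + slope × (subject's planted measure) +
noise`, with the measure evaluated on the noise-free generating sequence.

Random ground truths draw h and the upper triangle of J i.i.d. normal
(defaults: field scale 0.2, coupling scale 0.4, under which the median
N = 9 landscape has six local minima).  For planted-difference
experiments a structured three-well model is provided instead: three
blocks of three networks with intra-block coupling +0.3, inter-block
−0.3 and baseline −0.7 (plus a 0.01 per-block tilt to break the exact
three-fold degeneracy).  Its three minima — one per block — have balanced
occupancies and balanced pairwise transition rates, which random
landscapes at this scale do not: they typically concentrate transitions
on one dominant state pair, and any planted change is then statistically
confounded with that pair.  The planted group difference adds +0.6 to the
two bridge couplings (0,3) and (1,4) joining blocks 1 and 2; a pilot grid
showed this is the strongest perturbation that leaves the three minima
intact (stronger or wider perturbations re-stabilise the block-1+2
co-activation pattern as a fourth minimum), and it shifts the relative
transition frequency of the corresponding state pair as the dominant
transition effect.

What passing the synthetic suite does and does not show: the generator
shares the analysis's own model family (Boltzmann patterns, linear
behavior link, Gaussian sensor noise).  Passing demonstrates that the
pipeline recovers what it assumes — parameters from moments, planted
dynamics differences, calibrated error rates — not that real fMRI obeys
the pairwise model, is stationary within scan, or has Gaussian noise;
hemodynamics, ICA mixing and preprocessing are all outside the emulation.

## Calibration and sensitivity experiments

The statistical-validity experiments run on the generating state
sequences labelled through the ground-truth landscape, isolating the
t-test + Bonferroni stage from fitting noise (the full fit pipeline is
exercised separately end to end).  Null calibration: 500 two-group
cohorts from the identical three-well truth; each Bonferroni family's
familywise rejection count is required to stay within a binomial
tolerance of nominal 5% (97.5th binomial percentile, corrected for the
seven families tested).  Sensitivity: 100 cohorts with the planted bridge;
detection means the planted pair's total-transition-frequency comparison
has the smallest p among the three pair comparisons.  The comparison is
restricted to the transition family because a coupling perturbation
changes the energy function itself, so state mean-energy comparisons are
always the globally most significant — as in the study design this
emulates, where mean-energy differences carry the largest test statistics.

Problem sizes used throughout the suite (20 recovery seeds at N = 3–6,
50 oracle landscapes at N ≤ 4, two 10⁶-step walks at N = 9, 500 null and
100 planted cohorts at full study scale) were chosen as the smallest sizes
at which each property is sharply distinguishable from its failure mode.

## Known limitations

- Exact enumeration limits N (hard cap 20, practical ~14); there is no
  approximate mode for larger network sets, by design.
- The k-cut state grouping reproduces a hierarchical grouping only up to
  the tree's actual structure; landscapes whose fitted minima differ
  between groups yield group-specific states that are comparable only by
  their energy-ordered labels.
- The indirect-transition rule is one defensible reading of a brief
  excursion; other readings (longer dwell windows, path-based definitions)
  would change the direct/indirect split, though not the total.
- Basin-size chi-square tests treat the `2^N` patterns as units, which is
  a descriptive comparison of landscape partitions, not an inferential
  statement about subjects.
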