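# Methods

## Problem and model

A local alignment score `S(x, y)` of a query `x` and subject `y` is only
interpretable through its null distribution `P(S = s)`; the p-value of an
observed score is the tail sum `P(S ≥ s)`.  For two random i.i.d. protein
sequences with a position-independent matrix, asymptotic extreme-value
theory gives the Gumbel form with parameters (λ, K).  No such theory exists
for bipartite (transmembrane-aware) scoring, for a fixed query, or for
queries drawn from a topology HMM — the three null models this package
implements:

* **RQGS** — query and subject both i.i.d. from a background composition
  (bundled default: the average Swiss-Prot composition, overridable by a
  two-column frequency file);
* **FQPS** — fixed query, i.i.d. subject; the scoring may use a
  helix-specific matrix on annotated query rows;
* **HMM** — query drawn from a transmembrane-topology HMM, subject i.i.d.;
  the distribution is resolved jointly with the topology class `n_TM`, the
  number of maximal helix-core runs in the query's Viterbi path.

All three factorize as `p(x, y) = f_query(x) · f_subject(y)`.

## Sampler

The estimator is importance sampling from `q(x, y) ∝ w(S(x, y), n_TM) ·
p(x, y)`, realized by a Metropolis-Hastings chain over the space of
fixed-length sequence pairs.  One of the two sequences is chosen with
probability 1/2 (subject always, in FQPS), then one of five elementary
moves: substitution (probability 1/2) or insertion/deletion with
left/right shift (1/8 each).  Every move replaces exactly one symbol and
has a same-probability inverse at the same position, so with replacement
symbols drawn from the background composition the proposal ratio cancels
the null-probability ratio *exactly* (checked float-exactly in the tests)
and the acceptance reduces to `min{1, w(s', n')/w(s, n)}`.  For HMM queries
the replacement symbol is drawn uniformly and the forward probability of
the mutated query enters the acceptance explicitly; subject-side moves
leave the class and query probability unchanged and skip the Viterbi
recomputation (the dominant cost in HMM mode).

Boundary rule: a proposal whose (score, class) falls outside the active
window is rejected and the current bin re-counted — the standard
flat-histogram convention.  A proposal that redraws the current symbol is a
legal self-move (accepted no-op); both choices preserve detailed balance,
which the tests verify on an enumerable 16-configuration space to 1e-12.

## Weight estimation and production

Wang-Landau iteration: after every update the visited bin's log-weight is
*decremented* by log φ and its histogram incremented; when every window bin
of every class exceeds 0.6 of the class mean (checked every 1000 updates,
both knobs configurable; a round-trip count criterion is available as an
alternative), the histogram is zeroed and `φ ← √φ`.  The schedule runs
from `φ = e^0.1` down through the first level at or below `φ = e^0.0002`
— 10 levels under the default halving of log φ.  One direction convention
deserves a note: flattening requires visited bins to become *less*
attractive, so the sampling weight is divided by φ; the multiplicative
variant describes the reciprocal density-of-states estimate, not the
sampling weight.

Because the adapting weights violate detailed balance, all reported
numbers come from a subsequent fixed-weight (φ = 1) production run,
recording `(s, n_TM)` every k-th update (default `k = L_Q + L_S`; the
calibration recipes use smaller k and let the blocking analysis absorb the
residual correlation).  The estimate is `P(s, n) ∝ counts(s, n)/w(s, n)`,
normalized in log space — the weights span many tens of decades, so linear
arithmetic is never used.

Round trips (window-edge to window-edge and back) are logged as the mixing
diagnostic; warm starts carry `−log P` estimates from a neighbouring
calibration (or a bulk sample) onto a new window, with linear continuation
of the log-weights beyond the source range.  Warm starting changes only
the effort, never the converged estimate — importance reweighting is
unbiased for any fixed weights — and the tests check exactly that.

Initial configurations are built by greedy hill-climbing from a null draw
(accept only moves that reduce the distance to the window), which for
realistic schemes starts inside or below the window and ascends.

## Errors and the modified Gumbel fit

Per-bin errors use Flyvbjerg-Petersen blocking of the per-sample bin
indicator series: pairwise averaging doubles the block size per level, and
the plateau is read as the mean of the last three levels still holding 32
blocks.  The closed-form checks (i.i.d. Gaussian, AR(1) with ρ = 0.9)
bound the plateau within 20-25%.

The tail summary fits

    log P(S = s) = log λ − λ(s − s₀) − λ₂ (s − s₀)²

by weighted least squares on the log scale (σ = relative bin error; bins
above 50% relative error are excluded).  The model is an exact
reparametrization of a quadratic polynomial, so the seed comes from a
weighted polyfit and the optimizer merely polishes it; covariance is
reported with absolute sigma.  The amplitude is derived as
`K = exp(λ s₀)/(L_Q L_S)`, the unique choice that matches the Gumbel tail
`c·λ·e^{−λ(s−s₀)}` with `c = K L_Q L_S`.  A nested pure-Gumbel fit
(λ₂ ≡ 0) is available for ranking comparisons and can never have lower
total χ² than the free fit; a free fit whose unconstrained optimum has
λ₂ < 0 is returned as that boundary fit, keeping λ₂ ≥ 0 by construction.

The law does not describe the high-probability flank around the mode, so
calibration fits drop bins from the left until the reduced χ² is
acceptable (candidate lower bounds 23, 26, 30, 34, 38; accept at
χ²/dof ≤ 1.5).  This mirrors standard practice of fitting only where the
parametric form holds; the chosen window is reported with the fit.

p-values are tail sums of the estimate inside its window, analytically
continued with the fitted pmf beyond it; E-values use the linear
convention `E = N·p` (indistinguishable from `1 − (1−p)^N` at the small p
where E-values matter).  Fit parameters for unsimulated subject lengths
are piecewise-linearly interpolated in `L_S` (λ, λ₂, K; s₀ recomputed),
with extrapolation beyond 20% of the covered range flagged.

## Transmembrane-topology HMM layout

The HMM follows the classical transmembrane architecture: a cycle of
cytoplasmic loop → cap → 25-state helix core → cap → short *or* long
non-cytoplasmic loop → mirrored helix back.  Loops are 10+10 ladders with
a self-looping globular state in the middle; caps are fixed-length-5
chains; helix-core lengths 5–25 are produced by the entry distribution
over 21 core entry points.  Emissions are tied in 7 groups (helix core,
cytoplasmic-side caps, non-cytoplasmic-side caps, the three loop types,
globular); the two helix directions share all parameters.

Free parameters, one simplex constraint per distribution:

| block | count |
| --- | --- |
| 7 emission groups × (20 − 1) | 133 |
| core entry/length distribution (21 outcomes) | 20 |
| 3 loops × (10 in-ladder + 1 globular self-loop + 9 out-ladder branches) | 60 |
| short- vs long-loop branch | 1 |
| initial distribution over the 3 loop entries | 2 |
| **total** | **216** |

The last out-ladder state is forced to exit (the ladder caps the tail
length), hence 9 rather than 10 out-branches per loop.  The count is
computed by the introspection helper from the assembled architecture's
parameter groups, not stated as a constant.  The original trained
parameter values are not redistributable; the builder ships synthetic
stand-in values (hydrophobic-tilted helix emissions, aromatic-tilted caps,
positively-charged cytoplasmic loops, near-Gaussian core length around 21)
and accepts a user parameter table with the same structure.  Topology
*prediction* quality is out of scope — the stand-in exists so that the
sampler, the class-resolved estimator and the parameter accounting are
fully exercisable.

## Synthetic data and toy universes

Stochastic components are validated against exhaustive enumeration on toy
universes (alphabet ≤ 3 symbols, sequences ≤ 6, ≤ 10⁶ configurations):
exact score/class pmfs, optimal alignments maximized over every
non-crossing pair set, and the explicit chain transition matrix.  The toy
scoring (+2/−1, gaps 2 + l, tilted two-letter background) preserves the
essential structure of the real setting — negative expected score,
affine gaps, integer bins — but none of the scale: toy score windows span
single decades of probability, not sixty, so toy agreement validates
correctness of the estimator, while the behaviour at depth is checked by
the scaled-down calibrations below.

## Problem sizes of the shipped calibrations

The reference calibrations of the classical model (BLOSUM62, gaps 12 + l,
query length 348) run, per subject length: 30 000 simple-sampling pairs
(bulk map and warm start), a round-trip-driven Wang-Landau refinement
(φ from e^0.1 to e^0.006, ≥ 1 round trip per level, ≤ 3×10⁵ updates per
level) over the window [23, 150], and a 30 000-sample production run with
thinning 15.  This reaches `P(S = 150) ≈ 10⁻¹⁵⁻¹⁶` in a few minutes of
chain time and reproduces published λ values at equal and dissimilar
lengths to within a few percent.  The full window [23, 500] (probabilities
to 10⁻⁶⁵) uses the identical code path and is a matter of chain time
(order hours), best approached through successive warm-started windows.
λ₂ estimated on [23, 150] comes out at 1–4·10⁻⁴ — the curvature genuinely
decreases with window depth, so matching the published fourth-decimal λ₂
requires the full window; λ is already stable at [23, 150].

## Known limitations

* The modified Gumbel form is heuristic; no claim is made about the true
  asymptotic law, and fits are only reported where χ² says the form holds.
* The per-bin blocking errors treat bins independently when propagated
  into the fit; bins from one chain are correlated, so reported parameter
  errors are mild underestimates — the acceptance tolerances are set by
  cross-run spread, not by single-run error bars.
* HMM-mode sampling recomputes a full forward and Viterbi pass per query
  move; at biological lengths with the 133-state layout this dominates the
  cost, and per-class windows with many classes need correspondingly more
  production samples.
* The i.i.d. subject is the only subject model; correlated subject models
  would need their own proposal cancellation analysis.
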