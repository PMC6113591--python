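# Methods

## Community model

The dynamics couple N microbial host populations and N virus populations
(densities in cells/ml and virions/ml, rates per day, time reported in
hours):

    dH_i/dt = r_i H_i (1 − Σ_i′ a_ii′ H_i′ / K) − H_i Σ_j M_ij φ_ij V_j
    dV_j/dt = V_j Σ_i M_ij φ_ij β_ij H_i − m_j V_j

M is the boolean infection network; φ_ij β_ij weights it into the
"effective" network M̃ that drives viral growth.  The model is deterministic:
no demographic noise, no measurement error, no environmental forcing.

## Interaction networks

Networks are square (N hosts × N viruses) boolean matrices with no empty
row or column — every population interacts with at least one partner.

* **Maximally nested** networks are staircases: each row's interactions are
  a prefix of the columns with non-increasing row degrees, built from the
  strict staircase (N, N−1, …, 1) and repaired to the requested fill
  (surplus ones fill the top rows; deficits are taken from the bottom).
  Fill is 0.55.  Nestedness is measured by NODF ∈ [0, 100]: the mean over
  all row and column pairs of the fraction of the lower-degree member's
  interactions shared with the higher-degree member, zero for equal degrees.
* **Maximally modular** networks are block-diagonal with k equal dense
  blocks (k = 2, 5, 10 at N = 10, 25, 50).  A block-diagonal matrix cannot
  exceed fill 1/k, so the modular gradients use full blocks at fill 1/k
  (0.5 at N = 10, 0.2 at N = 25, 0.1 at N = 50).  Modularity is Barber's
  bipartite Q_b maximized by BRIM (alternating row/column assignment) with
  8 random restarts and an adaptive module count (scan upward, stop after
  three counts without improvement), normalized by the Q_b of an ideal
  equal-block matrix at the same fill (1 − 1/k).
* **Gradients**: ten networks per structure and size, with target metric
  values evenly spaced from the maximal network's value down to 50 % of it.
  Degradation is by fill-preserving rewiring: swap a random interacting pair
  with a random noninteracting pair, reject swaps that would empty a row or
  column, re-measure after every accepted swap, stop at the first
  configuration at or below target (tolerance 1 % of the metric maximum).
  Candidate pairs are drawn without replacement within a sweep; the pool
  refreshes after each accepted swap.  Unbiased swapping equilibrates near
  the random-matrix metric level, which can sit just above the farthest
  target, so after a patience budget (three times the number of ones)
  without a new minimum, metric-increasing swaps are reverted.  During
  modularity-guided rewiring the metric is evaluated with 3 BRIM restarts
  (the final reported value uses the full evaluator); NODF is exact.

## Trait construction

All sampled parameters are uniform over their ranges: H\* ∈ [10³, 10⁴]
cells/ml, V\* ∈ [10⁶, 10⁷] virions/ml, φ ∈ [10⁻⁷, 10⁻⁶] ml/day (per pair),
β ∈ [10, 100] virions/cell (per pair), H⁰\* ∈ [10³, 10⁶] cells/ml, with
K = 10⁶ cells/ml fixed.  The competition matrix starts at a = I and, row by
row, draws random partners k ≠ i with a_ik ~ U(0,1) until the weighted sum
Σ a_ii′ H⁰\*_i′ would exceed K, then clips the last coefficient so the sum
equals K exactly — the virus-free community sits exactly at carrying
capacity.  If a row exhausts all partners without reaching K (possible when
the H⁰\* draws are small), the H⁰\* vector is resampled and all rows redone;
the constraint couples rows through the shared H⁰\*, so a per-row repair
would invalidate rows already finished.  With a single host the constraint
forces H⁰\* = K.  Finally m and r are solved from the equilibrium
conditions, making (H\*, V\*) an exact fixed point (residuals at machine
precision; the suite enforces < 10⁻⁶ relative).  Stability of the fixed
point is deliberately **not** enforced.

## Dynamics, sampling, variability

Initial conditions are H\*_i (1 ± δ), V\*_j (1 ± δ) with independent random
signs.  Integration uses LSODA on **log-transformed densities**
(d ln y/dt = per-capita rate) with rtol 10⁻⁸ and atol 10⁻¹⁰: positivity is
exact by construction and the relative-tolerance semantics survive
trajectories that span many decades.  Linear-space integration with a fixed
absolute tolerance produced spurious nonpositive states on the strongly
fluctuating communities.  The stored grid is uniform at 0.25 h over
[0, 300 h]; sampling frequencies (0.5, 2, 4 h) are multiples of it, so
samples are exact grid values.  Samples run from t = frequency in steps of
the frequency ("200 h, or 100 samples" at the 2-h default — sampling from
t = 0 would give 101), and are log₁₀-transformed.  The simulation horizon
is 1.5× the sampling window so delayed correlations can sample viruses up
to 100 h past the last host sample without re-simulation.

The coefficient of variation of a trajectory is the sample (n−1) standard
deviation over the mean of the **raw** densities on the stored grid
restricted to [0, 200 h].

A property of this construction worth stating plainly: the coexistence
fixed points are typically weakly **unstable** (largest Jacobian eigenvalue
real part ≈ +0.05…+0.5 per day, growing with N, driven by the asymmetric
pairwise-sampled φ and β coupling).  Over the 200-h window an initial ±δ
perturbation therefore amplifies several-fold before nonlinear saturation,
and the ensemble-mean CVs come out near 1.0 (hosts) and 0.27 (viruses) at
δ = 0.3 rather than the ~0.12/0.04 a marginally damped transient would
give.  The orderings that the benchmark's conclusions rest on are
unaffected and are tested: CV increases with δ, does not scale with N
(ensemble means within a factor of two across sizes), and hosts fluctuate
roughly three times more than viruses.

## Inference methods

* **Standard correlation** (Eq.-style per pair on log₁₀ samples): Pearson;
  Spearman as Pearson on ranks; Kendall as tie-corrected tau-b.  A constant
  series yields coefficient 0 with a warning (no evidence of association)
  rather than NaN, keeping the scoring pipeline total.
* **Time-delayed correlation**: virus series shifted later by τ on the
  sampling lattice (grid step = frequency — samples only exist there),
  τ ∈ [0, 100 h]; the sample count per coefficient stays fixed; the delayed
  virus mean is recomputed per delay.  Per pair, the delay maximizing |r|
  wins; ties go to the smallest τ.
* **Local similarity**: both series are rank-transformed to normal scores
  (rank k → standard normal quantile at k/(S+1), average ranks for ties).
  For each offset |d| ≤ 3 samples, the maximal positive and maximal
  negative contiguous product-run is found by a prefix-sum scan; the signed
  run of largest magnitude, divided by the full series length S, is the LS
  score.  The sign convention (signed value of the max-magnitude run) makes
  LS comparable to correlation coefficients in the threshold sweep; the
  normalization by S (not interval length) is deliberate.  Offsets scan
  0, +1, −1, +2, … with strict improvement, so ties resolve to the smallest
  |offset|.
* **Compositional correlation**: hosts and viruses are normalized
  *separately* (each pool sums to one per sample time) and then pooled into
  one (N_H + N_V)-component table.  Basis variances solve the log-ratio
  variance system under the sparsity approximation (matrix diag(p−2) + 1);
  basis correlations ρ = (w_i² + w_j² − t_ij)/(2 w_i w_j) are clamped to
  [−1, 1]; the most-correlated pair above 0.1 is excluded and the system
  re-solved, 10 iterations.  The data are strictly positive, so no
  pseudo-count machinery is involved and the estimate is deterministic.
  Only the host × virus block is scored.

## Scoring

Thresholds are the distinct observed score values plus sentinels beyond
both extremes — the exact empirical ROC for any score range (LS scores are
not confined to [−1, 1]).  Prediction is "score ≥ c".  AUC is the
trapezoidal integral of TPR against FPR; with ties this equals the
midrank Mann–Whitney form exactly, and the suite checks both computations
against each other (and against scikit-learn) to 10⁻¹².

## Experiment orchestration

Per-community random streams derive from the master seed through
`numpy.random.SeedSequence` with fixed role offsets (network generation,
trait sampling, simulation), so any community is reproducible in isolation
and two runs with the same master seed are identical.  The default method
list is (pearson, delayed_pearson, spearman, elsa, sparcc); kendall and the
delayed rank variants are available by configuration.  Per-community
failures are logged, skipped, and surfaced in the result object (the CLI
exits nonzero).  The full default sweep and the test suite run in minutes
on one CPU; the dominant cost is the N = 50 communities.

## Known limitations

* The dynamics are deterministic transients of an ODE; nothing here speaks
  to measurement noise, stochastic demography, or environmental forcing,
  all of which would plausibly make correlation-based inference *worse*.
* The trait construction guarantees feasibility (a positive coexistence
  equilibrium) but not stability; the simulated variability is therefore an
  emergent property of the sampled communities, not a tuned quantity.
* Rectangular networks are representable but untested beyond square ones;
  gradient targets below ~50 % of the structural maximum may be
  unreachable by degree-preserving rewiring.
* Normalized modularity uses the ideal-equal-block maximum 1 − 1/k with
  k = round(1/fill); for fills far from 1/k this normalization is a
  convention, not a theorem.
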