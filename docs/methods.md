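# Methods

## The decomposition problem

All quantities are computed on finite trivariate pmfs `p(y, b, a)` with
plug-in probabilities, in bits, with the convention that zero-probability
cells contribute nothing (support-restricted sums, never epsilon
flooring). A partial information decomposition supplies the single degree
of freedom the classical equations leave open: fixing any one of UnqB,
UnqA, Shd or Syn determines the rest through

    I(Y;B) = UnqB + Shd,  I(Y;A) = UnqA + Shd,
    I(Y;B|A) = UnqB + Syn,  I(Y;A|B) = UnqA + Syn.

Every estimator here computes its defining quantity and assembles the
remaining components from these identities, so the consistency residuals
(checked by `check_consistency` and the test suite at 1e-6) hold to
rounding, and the unique information asymmetry is method-independent by
construction.

## The five estimators

**broja.** Synergy is the observed joint mutual information in excess of
`min I_q(Y;B,A)` over joint pmfs `q` preserving the `(Y,B)` and `(Y,A)`
marginals. For fixed output value the feasible set is a transportation
polytope (row sums `p(y,b)`, column sums `p(y,a)`), so we solve the convex
program by alternating minimization of `KL(q ‖ p_Y ⊗ r)`: an exact
I-projection of the reference product measure onto each slice's
transportation polytope (Sinkhorn scaling to 1e-13 marginal feasibility),
alternated with the closed-form update `r ← Σ_y q`. Both steps are exact
coordinate minimizations of a jointly convex functional over convex sets,
so the objective decreases monotonically to the global minimum
(Csiszár–Tusnády). Stopping extrapolates the geometric tail of objective
decrements to an estimated remaining gap (default tolerance 1e-9 on the
objective); a final pure-Sinkhorn polish re-projects onto the marginal
constraints so the reported objective is attained at a feasible point —
the synergy estimate can then only err low, which keeps all four
components nonnegative to rounding. Multiplier scale is re-gauged into the
reference measure each step (per-slice balancing plus per-row/column
max-normalization and unit total mass) to prevent over/underflow; cells
decaying below 1e-250 are cleared as exact boundary zeros. Instances whose
optimum lies on the polytope boundary can converge sublinearly; after the
100,000-outer-step cap an estimated gap up to 1e-5 bit is accepted with a
warning in `solver_info` (an error above that), which is three orders of
magnitude below the 0.1 % scale of the reported tables.

**dep.** On the lattice of maximum-entropy models constrained by subsets
of the three pairwise marginals, UnqB is the least increase in `I(Y;B)`
across edges that add the `B–Y` constraint. The candidate values reduce to
`I(Y;B)`, `I_ci(Y;B|A)` with `ci = p(y)p(b|y)p(a|y)` (closed form), and
`I_m(Y;B|A)` with `m` the full pairwise maxent (iterative proportional
fitting). Each candidate for B and its mirror for A differ by exactly
`I(Y;B) − I(Y;A)`, so the minimum does too and the decomposition is
consistent whichever edge binds; writing the candidates as conditional
mutual informations under the respective models keeps them nonnegative
under finite IPF error, and the two independently minimized uniques are
symmetrized through the consistency identity (removing IPF noise of order
the fit residual).

**ccs.** Redundancy sums, over the support of the pairwise
maximum-entropy distribution, the local co-information
`i(y;b) + i(y;a) − i(y;(b,a))` of realisations where the local
informations from B, from A, and the co-information itself share one
sign — a common change in surprisal. Evaluation is entirely on the maxent
model (probabilities and weights).

**pm.** Local mutual information is written `i(y;s) = h(s) − h(s|y)`,
separating the informative specificity `h(s) = −log2 p(s)` from the
misinformative ambiguity `h(s|y)`. Shared information averages
`min(h(b), h(a)) − min(h(b|y), h(a|y))` over the observed joint
distribution; exact ties take the common value. Synergy may exceed the
joint mutual information (observed, and deliberately not clipped).

**sx.** The local shared term of `(y, b, a)` is
`log2 p(y | {B=b} ∪ {A=a}) / p(y)`, the information carried by the event
that at least one input takes its realized value; union probabilities come
from inclusion–exclusion. Averaged over the observed distribution.

## Maximum-entropy fits

IPF cycles multiplicative scalings toward the three pairwise marginals
from a uniform start; the limit is the I-projection onto the intersection,
i.e. the pairwise maxent. Full-support targets converge linearly to the
1e-10 residual criterion within tens of sweeps. Targets whose maxent lies
on the simplex boundary — deterministic gates and the
uniform-over-observed-cells grid distributions this package analyses —
converge as ~1/sweeps, so after the 50,000-sweep cap residuals up to 1e-4
are accepted with a warning flag; the induced error on any derived
information measure is of the residual's order, well below reporting
precision. Larger residuals raise.

## Paired-condition pipeline

Trials are admitted per unit only for (basal, apical) amplitude
combinations present under both conditions; under the default
`drop-combination` policy a combination that evoked no APs under either
condition is dropped from both (the `drop-trial` alternative drops only
the silent trials). This guarantees matched input distributions, so
within-unit component differences cannot be artifacts of differing inputs.
Admitted trials are cut into non-overlapping 120 ms windows (the window
length is configurable; a scan utility can select the JMI-maximizing
window); per window the AP count and mean basal/apical signals are
computed, inputs are binned into equiprobable quantile bins (default
quartiles; edge ties go to the lower bin; the bin count reduces when fewer
distinct values exist) and counts map to categories 0 / 1 / 2+, giving a
4 × 4 × 3 pmf per unit and condition. Components are normalized by each
distribution's joint mutual information before comparison.

Differences (treated − control) are tested per method and component with
the exact two-sided Wilcoxon signed-rank test: zeros dropped, mid-ranks
for ties, and the null distribution of the signed-rank sum enumerated
exactly by convolution over doubled ranks (n ≤ 25); the two-sided p-value
is the null mass at least as far from the mean as observed. Bonferroni
correction is `min(mP, 1)` with `m` defaulting to the number of tests
performed.

## AP-grid pipeline

A spike-count surface over basal × apical input counts becomes a
trivariate distribution by placing probability `1/n` on each of the `n`
observed combinations within a chosen range pair (output categories 0 /
1–2 / 3–4). Nested range scans decompose every subsystem and normalize by
its own joint mutual information; subsets carrying no information are
recorded as missing with a reason. Range strength is ordered by the upper
endpoint. The UIA bifurcation detector reports, per apical range, the
first basal range at which the UIA is nonnegative after having been
negative, with a 1e-9 sign tolerance against floating-point flips.

The four cooperative-context-sensitivity criteria are qualitative; to make
them reproducible they are operationalized with explicit thresholds,
always reported with the result: CCS1 — the output varies with basal input
at zero apical input; CCS2 — no APs at zero basal input; CCS3 — some
scanned subset has normalized UnqB ≥ 0.20, |UnqA| ≤ 0.05 and
Shd + Syn ≥ 0.10; CCS4 — total transmission about the drive
(UnqB + Shd + Syn) grows through the weak-basal regime (ranges below the
grid's basal-alone firing threshold) and Shd and Syn do not grow beyond
it, judged with a 0.02 monotonicity tolerance.

## Synthetic generators

The generators emulate the statistical structure of the two study designs,
not their biophysics.

**Paired trials.** Per window the drive is
`r = w_b·b + g_eff·f(a)·b + ε`, with `f` a saturating sigmoid (apical
input alone cannot fire the cell), `ε` Gaussian (sd 0.35), and
`g_eff = g` under control or `g × inhibition_factor` under treatment —
dendritic inhibition scales down apical amplification. Counts are the
thresholded, discretized drive, capped at 4. Defaults: 15 units, a 7-level
0–1500 pA amplitude grid per input presented factorially once per
condition (matched inputs by construction), 40 windows of 120 ms per
trial, gain 1.0, inhibition factor 0.3, per-unit ±20 % gain jitter, one
RNG seed for everything. What this does *not* emulate: temporal spike
patterning and bursts, current-waveform kinetics, per-neuron differences
in trial counts or amplitude grids, recording noise. Passing tests
therefore show the pipeline recovers the constructed direction of effects
(positive UIA, larger under inhibition; reduced synergy), not that real
recordings would yield those numbers.

**AP grid.** A deterministic two-threshold surface: graded basal-alone
drive from 160 basal inputs (one extra AP per 50), binary apical enabling
from 110 apical inputs, a weak-basal amplification ramp (slope 0.5 per 100
inputs) active only in the presence of apical input, and nothing below a
20-input basal floor regardless of apical input. These choices make the
basal-alone threshold, the apical-enabled firing of weak basal input, and
a UIA sign change one grid spacing below the basal-alone threshold
(exposed as `GridGenParams.uia_switch_level`, recovered by the scan within
±1 spacing for every apical range) properties of the construction. The
surface is noise-free; counts cap at 4.

## Numerical conventions and limitations

- Input pmfs are accepted when their mass is within 1e-9 of one and then
  renormalized exactly; negative cells beyond −1e-12 are rejected.
- Normalization by a zero joint mutual information is an error, not a
  0/0 convention.
- Alphabet ordering is preserved from input and never affects any measure
  (tested by permutation).
- Only the bivariate-input case is implemented; the shared component is
  not split into source and mechanistic parts (for the grid subsets the
  inputs are marginally independent, so shared information is entirely
  mechanistic).
- Problem sizes: the test and acceptance workloads use systems up to
  31 × 21 × 3 (651-cell support) and consistency batches of 1000 random
  systems up to 5 × 5 × 4, chosen to exercise every code path at
  interactive runtimes on a single core.
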