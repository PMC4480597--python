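# Methods

## Model family

Four empirical descriptions of how an apparent substitution rate decays
with its measurement timescale `t` (node age, in Myr internally):
vertically-translated exponential (VEX, `r = αe^{−βt} + k`), simple
exponential (EX), vertically-translated power law (VPL,
`r = αt^{−β} + k`), and simple power law (PL).  They are empirical
top-down fits, not mechanistic models: no likelihood is defined, so model
comparison uses cross-validation rather than information criteria.

Integrating `r` from 0 with `s(0) = 0` gives the cumulative substitutions
`s(t)` and the average rate `r̄(t) = s(t)/t`.  The power-law kinds need
`β < 1` for the integral to converge, so β is constrained to
`(1e−6, 1 − 1e−6)`; the exponential kinds only need `β > 0`.  `k ≥ 0` is
the long-term rate asymptote.  EX saturates at `s = α/β`: larger `s` is
unreachable at any finite time, which matters when inverting (below).

Units: `t` is carried in Myr or years; conversion is exact (rates scale
by 10⁶, exponential β inversely with the unit, power-law α by
`c^{1−β}`).  Fitting is done on the Myr scale for conditioning; reported
rates are converted to substitutions/site/year.

## Inversion

Predicting a date from substitutions requires `t = s⁻¹`.  PL and EX have
closed forms; for the offset kinds `s(t)` is increasing and concave
through the origin, so the public `invert_time` uses an expanding
geometric bracket plus bisection (tolerance well below
`1e−10 + 1e−8·t`), while the fitting objective uses a safeguarded Newton
iteration started at an upper bound of the root (the smaller of the
offset-only root `s/k` and the offset-free closed-form root): the first
step lands below the root and the iteration then converges monotonically.
Both paths are cross-checked against each other and against a Brent
solve in the tests.

## Fitting

Both criteria are least-squares: `LSE_r̄` minimises residuals of the
average rate, `LSE_t` of the predicted time.  Parameters are optimised in
transformed space (log α, log β or logit-scaled power-law β, log k with a
floor of 1e−30) so the positivity constraints are implicit.  Each fit
runs 20 multi-starts (seeded Latin hypercube, log-uniform over
[1e−12, 1e3] per parameter) of L-BFGS-B with analytic gradients —
obtained for `LSE_t` by implicit differentiation of the inverse curve —
followed by a Nelder-Mead polish of the best optimum.  For `LSE_t` under
EX, points with `s ≥ α/β` receive the finite, violation-increasing
penalty residual `t_max·sβ/α` so the objective stays continuous and
optimisers can leave the infeasible region.  Adjusted
`R̄² = 1 − (1−R²)(n−1)/(n−p−1)` is reported when `n > p + 1` and
suppressed otherwise (three-point calibration fits).  Ensemble summaries
use central 2.5/97.5 percentiles.

## Resampling design

Node data are a posterior sample of node-to-tip substitutions `s` per
internal node plus, for host-dated nodes, a calibration median and 95 %
interval in Myr.  The prior sd is the wider half-interval divided by
1.96.  Joint age draws are sampled top-down: each parent from its normal
prior, each child by rejection from its normal truncated above at the
parent's drawn value (cap 1,000 attempts per node per row, then a
simulation-failure error; draws truncated below at 1e−6 Myr).  This
enforces child-younger-than-parent exactly per draw; note its law differs
from whole-row rejection sampling, which tilts the *parent's* marginal
upward — the child's conditional law is identical, and that is what the
tests verify.  Each resampled rate set pairs one joint age vector with
one posterior index drawn uniformly and shared across nodes, so the `s`
values within a set come from one coherent posterior tree sample;
`r̄ = s/(t·10⁶)` in substitutions/site/year.

## Cross-validation and model comparison

One LOOCV round = one resampled set: each node held out once, the model
refitted to the rest under `LSE_t` (fold fits warm-start from the
full-round optimum and skip the polish), the held-out age predicted from
its `s`.  Rounds are blocks; per-round MSE_OOS (Myr scale) feeds a
tie-corrected Friedman test and two-sided pairwise Wilcoxon signed-rank
tests (exact null for ≤ 25 rounds, normal approximation with continuity
correction above) with Bonferroni factor 6.  Folds whose fit fails or
whose held-out `s` exceeds an EX fit's saturation bound yield no
prediction; rounds missing any prediction are dropped from the rank tests
and counted.

## Synthetic data

The generator emulates the statistical shape of a strict-clock
virus–host co-speciation dataset: a 14-taxon pectinate ultrametric tree
whose 13 internal-node heights follow the chosen true model; the
"fv-like" age preset places the 11 dated nodes at 0.96, 2.17, 8.30,
11.50, 19.05, 31.56, 44.3, 62.1, 87.18, 88.7 and 98.9 Myr (three of these
log-interpolated between their neighbours) and two undated nodes at 23.4
and 40.81 Myr.  The default truth is PL with β = 0.55 and α set so the
30-Myr average rate is 1e−8 substitutions/site/year — the long-term
foamy-virus scale.  `s` draws are log-normal about the closed-form truth
with a per-draw tree-wide factor whose sigma grows linearly with depth
(CV `= cv₀(1 + t/t_max)`, default cv₀ = 0.05): posterior node heights
under a strict clock move together within one tree sample, and this
shared factor both mimics that correlation and guarantees the
parent-above-child ordering of `s` in every draw.  What it does *not*
emulate: independent per-node posterior wiggle, topology uncertainty,
alignment or substitution-model error — so passing tests show the
statistical machinery is sound, not that real posteriors are this tame.
Calibration priors are centred on the true ages with a default 95 %
half-width of 15 % of the median.  Ground truth travels in a separate
record and never reaches fitting code.

## Problem sizes and numerical choices

Defaults follow the study design (15,000 assembled rate sets, 1,500
fitted/validated rounds, 100 randomization nulls); tests and the
acceptance script scale the heavy simulations down as their own design
choice: 200 replicates for stochastic parameter recovery, 200 LOOCV
rounds for model selection, 500 repetitions for randomization-test
calibration, 1,000 draws for the calculus and inversion oracles.
Convergence: L-BFGS-B `ftol 1e−15`/`gtol 1e−12`, Newton inversion to
relative 1e−14, bisection 80 halvings.  Degenerate inputs: zero-sd priors
are point masses; a fully tied score matrix gives Friedman statistic 0
and p = 1; all-zero Wilcoxon differences give p = 1.

## Known limitations

Node-wise data are phylogenetically non-independent (shared ancestry);
the analysis accepts this as the original design does.  The EX bound
makes its date predictions undefined for large `s`; such replicates are
reported as missing rather than imputed.  Three-point calibration
schemes cannot carry the three-parameter kinds (exact interpolation, no
error signal), which are therefore refused without an explicit override.
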