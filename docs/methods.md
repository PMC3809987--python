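# Methods

`chronopl` implements penalized-likelihood (PL) divergence dating on fixed
tree topologies, the maximum-likelihood branch-length estimation that feeds
it, and the resampling experiments that expose how undersampling a clade
biases its estimated ages. Everything is testable against synthetic data
with known ground truth; this note records the models, the numerical
choices, and what the synthetic benchmark does and does not emulate.

## The dating model

The input is a *phylogram*: a rooted binary tree whose branch lengths `b_k`
are expected substitutions per site, estimated from an alignment of `L`
sites. Each branch carries an expected substitution count `x_k = b_k · L`
(kept as a real number; an r8s-style integer-rounding variant is available
via `PLConfig(integer_counts=True)`). Writing `t_k` for the branch duration
implied by node ages (extant leaves at age 0, ages increasing rootward) and
`r_k` for the branch rate in substitutions/site/MY, PL maximizes

    sum_k [ x_k log(r_k L t_k) − r_k L t_k ]  −  λ · Φ(r)

over ages and rates, subject to parent-older-than-child ordering and any
calibration bounds. The first term treats `x_k` as a Poisson observation
with mean `r_k L t_k`; `Φ` penalizes rate changes between adjacent
branches — squared differences of log rates by default (the logarithmic
penalty), or of raw rates (`penalty_kind="additive"`) — plus the variance
of rates among the root's child branches, which have no parent branch to
be compared with. Large λ forces a near-clock solution; small λ lets each
branch fit its own rate. The default λ = 0.9 is the package's standard
working value; a 0.5–2 sweep is the conventional sensitivity range, and
`cross_validate` scores a λ grid by leave-one-terminal-branch-out
prediction of terminal substitution counts (terminals attached directly to
the root are skipped — their attachment age does not survive pruning).

Calibrations name a clade by a taxon set; the constraint applies to the
MRCA of whichever members are present in the tree being dated, which
generalizes cleanly to subsampled trees. A calibration reduced to fewer
than two surviving members is dropped for that tree. Minimum, maximum and
fixed ages are plain box bounds on the node age; at least one maximum or
fixed age is required or the time scale is unbounded. A min+max window on
the root is the usual design. Note an intrinsic identifiability limit:
when the data are exactly clocklike, rescaling all ages by `c` and rates
by `1/c` leaves the objective unchanged, so a window-only calibration
bounds but does not pin the absolute scale. The optimizer's unperturbed
start sits at the window midpoint, which is also the natural point
estimate in that flat direction.

## The optimizer

For fixed ages the conditional problem in `u = log rate` is strictly
concave (Poisson log-likelihood plus a quadratic or convex penalty), so it
is solved exactly by damped Newton with backtracking — the penalty Hessian
is assembled explicitly and is constant for the log penalty. The ages are
then optimized against the *profiled* objective `F(ages) = max_u obj` with
the envelope gradient, using SLSQP under the linear ordering constraints
and per-node age bounds (calibration bounds are first propagated through
the tree: a node's effective minimum includes its descendants' minima, its
effective maximum its ancestors' maxima; infeasibility is reported before
any optimization). Profiling the rates out removes the near-flat
age/rate rescaling ridge that makes joint quasi-Newton schemes crawl.

Multiple restarts guard against local optima: restart 0 starts from a
clock-scaled solution (node depth proportional to mean path length to its
leaves, root at its window midpoint — exact for clocklike data), restart 1
from a topology-rank solution (node height in edges, robust when extreme
rate variation distorts path lengths), and further restarts jitter these.
The best objective wins; near-ties (relative 1e-9) break toward the lower
penalty, then the earlier restart, which keeps results deterministic.
Fitted ages essentially on a calibration bound (within 5e-6 of it, scaled)
are snapped onto the bound when that preserves the age ordering, so active
constraints are reported exactly.

Numerical guards: terminal branches of length zero are floored at 1e-9
substitutions/site before `x_k` is formed (avoids `log 0`); internal
zero-count branches are allowed and their rates run to the 1e-12
substitutions/site/MY floor; the ordering margin is 1e-7 of the root's
upper bound; the per-restart SLSQP stops on an objective change below
`PLConfig.objective_tol` (default 1e-6).

## Branch-length estimation

`estimate_branch_lengths` is cyclic one-dimensional optimization under
GTR+Γ+I: per sweep, a depth-first traversal optimizes each branch by
bounded Brent (bounds [1e-9, 10] substitutions/site) against cached
inside/outside conditional likelihoods, so each scalar optimization costs
O(patterns) independent of tree size. A proposed length is accepted only
if it does not lower the likelihood, and near-ties break toward the
smaller length, so the per-sweep likelihood is monotone. Site patterns are
compressed; gaps, `N` and IUPAC ambiguity codes contribute a partial
likelihood of 1 for each compatible state; per-node rescaling prevents
underflow. The rate mixture is the invariant class (rate 0, weight
`p_inv`) plus K = 4 discrete-gamma categories (category means by default,
medians as a documented switch), normalized so the mixture mean is 1 —
branch lengths are expected substitutions per site *overall*. With
`fix_model_params=False` the gamma shape, invariant fraction and the five
free exchangeabilities are re-optimized between sweeps by bounded scalar
search; base frequencies stay fixed (optionally set to empirical counts).
The model is deliberately unpartitioned.

## The synthetic generator

Chronograms are pure-birth (Yule) trees rescaled to an exact root age.
Branch rates come from one of three clocks: strict; iid lognormal with the
log-mean shifted by −σ²/2 so the expectation equals `mean_rate`; or an
autocorrelated lognormal random walk, `log r_child ~ Normal(log r_parent,
σ² t)` with branches off the root started at `mean_rate`. σ = 0 reduces
every model to the strict clock. Sequences evolve site-independently under
the same GTR+Γ+I machinery used for inference (root states from the
stationary frequencies; each site permanently invariant with probability
`p_inv` or assigned one gamma category). Calibration sets mirror a
fossil table: a root min/max window at 0.8–1.2 of the true root age, and
internal minimum ages drawn as Uniform(0.6, 0.95) multiples of the true
node age — fossil minima always understate the true age, so on clean data
they are typically inactive. All randomness flows from one integer seed.

## The packaged benchmark

`make_benchmark(seed)` builds a synthetic analogue of a focal lizard
radiation dated from ~1.6 kb of mtDNA: 48 taxa — a 40-taxon focal clade
(crown 48 MYA) with a 2-taxon sister clade (crown 28.8 MYA) joined at
62.4 MYA, below a ladder of 6 successively deeper outgroups up to a root
at 180 MYA; autocorrelated rates (mean 0.005 substitutions/site/MY,
σ = 0.4 per √MY); 1,500 bp of GTR+Γ+I sequence with strong transition
bias, AT-rich composition, α = 0.5 and 30% invariant sites. The
subsampling scheme deletes {0, 30, 37} of the 40 focal taxa, 10 replicates
per level; deletion sets are drawn independently per replicate; the
deletion-0 level is deterministic and run once. Branch lengths are
re-estimated per replicate from the restricted alignment with model
parameters held at the generating values; the 3 deepest outgroups are then
removed (they only anchor the branch-length fit, mirroring outgroup
removal before dating to avoid inflating the ingroup rate), and dating
uses calibrations generated from the outgroup-pruned true chronogram
(full: root window + 10 internal minima; or root-only; or root + one
shallow minimum). PL uses λ = 0.9, 2 restarts, and an objective tolerance
of 1e-3 — age differences far below the ~1 MY resolution the experiment
reads out. Branch-length sweeps stop at a 1e-2 log-likelihood gain or 10
sweeps.

What the benchmark emulates: deep saturated mtDNA-like divergences,
heavy-tailed among-branch rate variation, fossil minima concentrated
outside-and-below the focal crown, and the paired comparisons (same
replicate streams under different calibration sets; branch-length fits
computed once and shared). What it does not: partitioned models, alignment
curation, topology error (the true topology is always supplied), or
fossil misplacement. Two consequences deserve emphasis. First, σ = 0.4
per √MY compounds to enormous rate variation across a 180 MY tree (the
log-rate standard deviation root-to-tip exceeds 5), so absolute ages from
any single fit are strongly distorted even at full sampling — the
experiments therefore read out *differences* between sampling levels and
calibration schemes, not absolute accuracy. Second, under heavy deletion
some of the randomly placed internal minima lose their clade members and
drop out, so the younger-ages effect at the heaviest level combines
rate-smoothing/branch-length error with calibration attrition; the
strict-clock control (no rate variation, truthful root) shows no
systematic shift, confirming estimation error as the necessary
ingredient.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to give each check statistical teeth at interactive
runtimes: enumeration oracles at 4 taxa × 6 sites (exhaustive state sums),
branch-length recovery at 5 taxa × 1,000 sites, exact-data dating recovery
at 30 taxa, grid oracles with 50 points per free age on 4-taxon problems,
and the full benchmark at 48 taxa × 1,500 bp × 10 replicates × 10 seeds.

## Known limitations

- Ages are only as identified as the calibrations make them; with a
  window-only root and clocklike data the absolute scale is a flat
  direction (reported at the window midpoint by initialization).
- The optimizer is a local scheme with designed restarts, not a global
  solver; the grid-oracle tests bound how much can be left on the table
  for small problems.
- Cross-validation refits once per terminal per λ and is quadratic-ish in
  tree size; it is intended for modest trees.
- `crown_age` under non-monophyletic survivors returns the MRCA age, which
  may subtend non-members; this is the natural generalization when
  subsampling breaks a named clade.
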