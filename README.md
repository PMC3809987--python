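# chronopl

Penalized-likelihood divergence dating on fixed phylogenies, and the
resampling experiments that show why undersampled clades date too young.

Molecular phylogenies measure branch lengths in substitutions per site;
turning them into absolute ages (a *chronogram*, in millions of years)
requires separating rate from time under fossil calibrations. When a large
clade is represented by only a few of its species — routine in multilocus
supermatrix studies — its estimated crown age shrinks systematically, and
so do the ages of neighboring clades whose sampling never changed.
`chronopl` packages the machinery needed to study this at desk scale:

- **`treeio`** — a rooted-tree data model with Newick I/O, MRCA queries,
  distance-preserving pruning, crown ages and ultrametricity checks.
- **`simulate`** — ground-truth generators: Yule chronograms, strict /
  iid-lognormal / autocorrelated-lognormal branch rates, GTR+Γ+I sequence
  evolution, and fossil-style calibration sets (a root min/max window plus
  internal minimum ages that always understate the truth).
- **`likelihood`** — Felsenstein-pruning GTR+Γ+I likelihood on a fixed
  topology, ML branch lengths by cyclic bounded scalar optimization with
  cached inside/outside partials, and the alignment-column bootstrap.
- **`dating`** — the core: penalized likelihood. With substitution counts
  `x_k = b_k L`, durations `t_k` and rates `r_k`, it maximizes
  `Σ_k [x_k log(r_k L t_k) − r_k L t_k] − λ Φ(r)` subject to calibration
  bounds, where `Φ` is a roughness penalty on rate changes between
  adjacent branches (logarithmic by default) and λ is the smoothing
  parameter (default 0.9; `cross_validate` scores a λ grid). Plus
  PROFILE-style per-clade age summaries over tree sets.
- **`experiments`** — clade-targeted taxon deletion with re-estimated
  branch lengths, calibration-count sweeps on shared replicate streams,
  bootstrap age profiles, percent-younger bias metrics, and TSV report
  tables, all exactly reproducible from one seed.

## Worked example

Simulate a 20-taxon tree with drifting rates, re-estimate branch lengths
from 1,200 bp of sequence, then date under a fixed root plus ten
fossil-style minimum ages:

```python
import numpy as np
from chronopl import (
    Calibration, CalibrationSet, CladeSpec, PLConfig, PLProblem, RateModel,
    SubstitutionModel, assign_rates, crown_age, estimate_branch_lengths,
    fit_pl, make_calibration_set, simulate_alignment, simulate_chronogram,
    to_phylogram,
)

truth = simulate_chronogram(n_taxa=20, root_age=90.0, seed=7)
rates = assign_rates(truth, RateModel("autocorrelated_lognormal", 0.008, 0.15), seed=8)
phylogram = to_phylogram(truth, rates)
model = SubstitutionModel(
    exchangeabilities=(2, 10, 2, 1, 20, 1),
    base_freqs=(0.35, 0.30, 0.10, 0.25),
    gamma_shape=0.5, p_inv=0.2,
)
aln = simulate_alignment(phylogram, model, n_sites=1200, seed=9)
fit = estimate_branch_lengths(aln, phylogram, model)
print(f"branch-length fit: logL = {fit.log_likelihood:.2f}, "
      f"{fit.n_sweeps} sweeps, converged = {fit.converged}")

cals = CalibrationSet(
    [Calibration(CladeSpec("root", truth.tree.leaf_names), fixed_age=90.0)]
    + [c for c in make_calibration_set(truth, "full", seed=10) if c.max_age is None]
)
sol = fit_pl(PLProblem(fit.tree, cals, PLConfig(smoothing=0.9, num_sites=1200)))
print(f"PL fit: objective = {sol.objective:.2f}, converged = {sol.converged}, "
      f"{len(sol.active_constraints)} active calibrations")

errs = [abs(sol.chronogram.ages[n] - a) for n, a in truth.ages.items() if a > 0]
print(f"node-age error vs truth: mean {np.mean(errs):.1f} MY, max {np.max(errs):.1f} MY")
```

prints

```
branch-length fit: logL = -7126.23, 8 sweeps, converged = True
PL fit: objective = 24371.53, converged = True, 5 active calibrations
node-age error vs truth: mean 4.7 MY, max 20.4 MY
```

The branch-length stage reports the final log-likelihood of the GTR+Γ+I
fit and that the per-sweep gain dropped below tolerance. The dating stage
reports the penalized objective and that five calibrations ended exactly
on their bounds (active). The mean node-age error of ~5 MY on a 90 MY tree
reflects the injected rate autocorrelation — with a strict clock the same
pipeline recovers ages to well under 1%.

The undersampling experiment itself is one call (or
`chronopl subsample --seed 1 --out-dir out/` on the command line): it
deletes taxa from the focal clade, re-estimates branch lengths, strips
distant outgroups, dates, and tabulates mean ± SD crown ages per deletion
level, with N/A cells where fewer than two clade members survived.

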