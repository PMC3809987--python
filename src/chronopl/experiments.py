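"""Resampling experiments: clade-targeted taxon deletion, calibration-count
schemes, bootstrap node-age profiling, bias metrics and report tables.

The central experiment deletes taxa at random from one large clade of a
fixed topology, re-estimates branch lengths from the restricted alignment,
removes distant outgroups, dates the tree by penalized likelihood, and
summarizes focal-clade crown ages across replicates.  Undersampled clades
systematically date younger; ``percent_change`` quantifies the shift.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dating import (
    PLConfig,
    PLProblem,
    PLSolution,
    ProfileSummary,
    fit_pl,
    profile,
)
from .likelihood import bootstrap_alignment, estimate_branch_lengths
from .simulate import (
    Alignment,
    CalibrationSet,
    RateModel,
    SubstitutionModel,
    assign_rates,
    make_calibration_set,
    simulate_alignment,
    simulate_nested_chronogram,
    to_phylogram,
)
from .treeio import Chronogram, CladeSpec, Tree, prune_taxa

__all__ = [
    "SubsamplingScheme",
    "ExperimentResult",
    "run_subsampling",
    "run_calibration_experiment",
    "percent_change",
    "bootstrap_profile",
    "report",
    "read_report",
    "Benchmark",
    "make_benchmark",
]

logger = logging.getLogger("chronopl")


@dataclass(frozen=True)
class SubsamplingScheme:
    """How to subsample: which clade, how many to delete, how often."""

    target_clade: CladeSpec
    deletion_counts: tuple
    replicates: int = 25
    seed: int = 0
    outgroups_to_drop: tuple = ()
    calibration_strategy: str = "full"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        size = len(self.target_clade.taxa)
        for d in self.deletion_counts:
            if d < 0 or d >= size:
                raise ValueError(
                    f"deletion count {d} invalid for a clade of {size} taxa"
                )


@dataclass
class ExperimentResult:
    """Profile summaries per deletion count plus run provenance."""

    scheme: SubsamplingScheme
    strategy: str
    summaries: dict[int, ProfileSummary]
    clade_names: list[str]
    provenance: dict = field(default_factory=dict)

    def mean_age(self, deletion_count: int, clade_name: str) -> float | None:
        return self.summaries[deletion_count][clade_name].mean

    def to_table(self) -> pd.DataFrame:
        rows = []
        for d in sorted(self.summaries):
            row: dict = {"deleted": "None" if d == 0 else str(d)}
            for name in self.clade_names:
                r = self.summaries[d][name]
                row[name] = (
                    "N/A*"
                    if r.mean is None
                    else f"{r.mean:.17g} (SD = {r.sd:.17g})"
                )
            rows.append(row)
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Replicate streams (branch-length fits are the expensive, shared stage)
# ----------------------------------------------------------------------

def _fit_replicates(
    aln: Alignment,
    topology: Tree,
    model: SubstitutionModel,
    scheme: SubsamplingScheme,
    fix_model_params: bool = True,
    bl_tol: float = 1e-3,
    max_sweeps: int = 12,
) -> dict[tuple[int, int], Tree]:
    """Per (deletion_count, replicate): prune, restrict, re-estimate branch
    lengths, drop outgroups.  Deletion 0 is deterministic and run once.

    The returned trees are phylograms ready for dating (outgroups already
    removed; their information went into the branch-length fit).
    """
    target = sorted(scheme.target_clade.taxa)
    missing = set(target) - set(topology.leaf_names)
    if missing:
        raise ValueError(f"target clade taxa not in topology: {sorted(missing)}")
    rng = np.random.default_rng(scheme.seed)
    fits: dict[tuple[int, int], Tree] = {}
    for d in scheme.deletion_counts:
        n_reps = 1 if d == 0 else scheme.replicates
        for rep in range(n_reps):
            deleted = (
                set() if d == 0 else set(rng.choice(target, size=d, replace=False))
            )
            pruned = prune_taxa(topology, deleted) if deleted else topology
            sub_aln = aln.subset(pruned.leaf_names)
            fit = estimate_branch_lengths(
                sub_aln,
                pruned,
                model,
                fix_model_params=fix_model_params,
                tol=bl_tol,
                max_sweeps=max_sweeps,
            )
            dated_tree = (
                prune_taxa(fit.tree, set(scheme.outgroups_to_drop))
                if scheme.outgroups_to_drop
                else fit.tree
            )
            fits[(d, rep)] = dated_tree
            logger.info(
                "BL fit d=%d rep=%d: logL=%.2f sweeps=%d converged=%s",
                d, rep, fit.log_likelihood, fit.n_sweeps, fit.converged,
            )
    return fits


def _date_replicates(
    fits: dict[tuple[int, int], Tree],
    calibrations: CalibrationSet,
    plcfg: PLConfig,
    focal_clades: list[CladeSpec],
    deletion_counts,
) -> dict[int, ProfileSummary]:
    summaries: dict[int, ProfileSummary] = {}
    for d in deletion_counts:
        solutions: list[PLSolution] = []
        for (dd, rep), tree in sorted(fits.items()):
            if dd != d:
                continue
            cals = calibrations.restrict(set(tree.leaf_names))
            sol = fit_pl(PLProblem(tree, cals, plcfg))
            if not sol.converged:
                logger.warning("PL fit d=%d rep=%d flagged non-converged", d, rep)
            solutions.append(sol)
        summaries[d] = profile(solutions, focal_clades)
    return summaries


def run_subsampling(
    aln: Alignment,
    topology: Tree,
    model: SubstitutionModel,
    scheme: SubsamplingScheme,
    focal_clades: list[CladeSpec],
    plcfg: PLConfig,
    calibrations: CalibrationSet,
    fix_model_params: bool = True,
    bl_tol: float = 1e-3,
    max_sweeps: int = 12,
    _fits: dict | None = None,
) -> ExperimentResult:
    """The taxon-deletion experiment, end-to-end deterministic per seed.

    Per replicate: delete ``d`` taxa uniformly without replacement from the
    target clade, prune the topology, restrict the alignment, re-estimate
    branch lengths, drop the listed outgroups, date by penalized
    likelihood, and record focal crown ages.  Clades left with fewer than
    two sampled taxa contribute N/A cells, never errors.
    """
    fits = (
        _fits
        if _fits is not None
        else _fit_replicates(
            aln, topology, model, scheme, fix_model_params, bl_tol, max_sweeps
        )
    )
    summaries = _date_replicates(
        fits, calibrations, plcfg, focal_clades, scheme.deletion_counts
    )
    prov = {
        "seed": scheme.seed,
        "replicates": scheme.replicates,
        "deletion_counts": list(scheme.deletion_counts),
        "smoothing": plcfg.smoothing,
        "penalty": plcfg.penalty_kind,
        "num_sites": plcfg.num_sites,
        "restarts": plcfg.restarts,
        "calibration_strategy": scheme.calibration_strategy,
        "outgroups_dropped": list(scheme.outgroups_to_drop),
        "n_calibrations": len(calibrations),
    }
    return ExperimentResult(
        scheme, scheme.calibration_strategy, summaries,
        [c.name for c in focal_clades], prov,
    )


def run_calibration_experiment(
    aln: Alignment,
    topology: Tree,
    model: SubstitutionModel,
    base_scheme: SubsamplingScheme,
    strategies: list[str],
    focal_clades: list[CladeSpec],
    plcfg: PLConfig,
    calibration_sets: dict[str, CalibrationSet],
    fix_model_params: bool = True,
    bl_tol: float = 1e-3,
    max_sweeps: int = 12,
    shared_fits: dict | None = None,
) -> dict[str, ExperimentResult]:
    """Date identical replicate streams under different calibration sets.

    Branch-length fits are computed once and reused for every strategy, so
    differences between results are attributable to calibrations alone.
    """
    fits = (
        shared_fits
        if shared_fits is not None
        else _fit_replicates(
            aln, topology, model, base_scheme, fix_model_params, bl_tol, max_sweeps
        )
    )
    out: dict[str, ExperimentResult] = {}
    for strat in strategies:
        res = run_subsampling(
            aln, topology, model,
            SubsamplingScheme(
                base_scheme.target_clade,
                base_scheme.deletion_counts,
                base_scheme.replicates,
                base_scheme.seed,
                base_scheme.outgroups_to_drop,
                strat,
            ),
            focal_clades, plcfg, calibration_sets[strat], _fits=fits,
        )
        out[strat] = res
    return out


def percent_change(age_full: float, age_sub: float) -> float:
    """Percent younger: 100 * (age_full - age_sub) / age_full."""
    if age_full <= 0:
        raise ValueError("age_full must be positive")
    return 100.0 * (age_full - age_sub) / age_full


def bootstrap_profile(
    aln: Alignment,
    topology: Tree,
    model: SubstitutionModel,
    calibrations: CalibrationSet,
    plcfg: PLConfig,
    n_reps: int,
    seed,
    clades: list[CladeSpec],
    fix_model_params: bool = True,
    bl_tol: float = 1e-3,
    max_sweeps: int = 12,
    outgroups_to_drop: tuple = (),
) -> ProfileSummary:
    """Node-age confidence via alignment-column bootstrap.

    Per replicate: resample columns, re-estimate branch lengths on the
    fixed topology, date by penalized likelihood; then mean/SD crown ages
    per clade.  Replicates whose dating fit fails to converge are dropped
    with a warning (``n_valid`` reflects the drops).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    solutions = []
    for rep in range(n_reps):
        boot = bootstrap_alignment(aln, rng)
        fit = estimate_branch_lengths(
            boot, topology, model,
            fix_model_params=fix_model_params, tol=bl_tol, max_sweeps=max_sweeps,
        )
        tree = (
            prune_taxa(fit.tree, set(outgroups_to_drop))
            if outgroups_to_drop
            else fit.tree
        )
        cals = calibrations.restrict(set(tree.leaf_names))
        sol = fit_pl(PLProblem(tree, cals, plcfg))
        if not sol.converged:
            logger.warning("bootstrap replicate %d dropped (no convergence)", rep)
            continue
        solutions.append(sol)
    return profile(solutions, clades)


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------

_FOOTNOTE = (
    "* Divergence times could not be calculated: fewer than two taxa of the "
    "clade were sampled in every replicate."
)


def report(results: list[ExperimentResult], path) -> list[str]:
    """Write one TSV per result (rows = deletion counts, columns = focal
    clades, cells ``mean (SD = s)`` with N/A* for empty cells) plus a
    machine-readable JSON manifest.  Returns the written file paths."""
    import os

    os.makedirs(path, exist_ok=True)
    written = []
    if not results:
        p = os.path.join(path, "table_1.tsv")
        with open(p, "w") as fh:
            fh.write("deleted\n")
        return [p]
    manifest = {}
    for i, res in enumerate(results, start=1):
        p = os.path.join(path, f"table_{i}.tsv")
        table = res.to_table()
        has_na = table.apply(lambda col: col.astype(str).eq("N/A*")).any().any()
        with open(p, "w") as fh:
            fh.write(table.to_csv(sep="\t", index=False))
            if has_na:
                fh.write(f"# {_FOOTNOTE}\n")
        written.append(p)
        manifest[f"table_{i}"] = res.provenance | {"strategy": res.strategy}
    mp = os.path.join(path, "manifest.json")
    from . import __version__

    manifest["versions"] = {"chronopl": __version__}
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mp)
    return written


_CELL_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*\(SD = ([0-9.eE+-]+)\)\s*$")


def read_report(path) -> pd.DataFrame:
    """Parse a report TSV back into tidy (deleted, clade, mean, sd) rows."""
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        fields = line.split("\t")
        deleted = fields[0]
        for name, cell in zip(header[1:], fields[1:]):
            if cell == "N/A*":
                mean = sd = None
            else:
                m = _CELL_RE.match(cell)
                if not m:
                    raise ValueError(f"unparseable cell {cell!r}")
                mean, sd = float(m.group(1)), float(m.group(2))
            rows.append({"deleted": deleted, "clade": name, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# The packaged synthetic benchmark
# ----------------------------------------------------------------------

@dataclass
class Benchmark:
    """A fully synthetic analogue of the empirical study system.

    48 taxa: a 40-taxon focal radiation (the deletion target), a 2-taxon
    sister clade whose sampling is never altered, and 6 successively deeper
    outgroup lineages of which the 3 deepest are removed before dating
    (they only anchor branch-length estimation).  Sequences are 1,500 bp of
    GTR+Gamma+I mtDNA-like data evolved under an autocorrelated lognormal
    clock; calibrations are generated from the true chronogram restricted
    to the taxa that survive outgroup removal.
    """

    truth: Chronogram
    clades: dict[str, CladeSpec]
    phylogram: Tree
    alignment: Alignment
    model: SubstitutionModel
    calibration_sets: dict[str, CalibrationSet]
    scheme: SubsamplingScheme
    plcfg: PLConfig
    focal_clades: list[CladeSpec]


# mtDNA-like defaults: strong transition bias, AT-rich, strong among-site
# rate variation with a substantial invariant fraction
BENCHMARK_MODEL = SubstitutionModel(
    exchangeabilities=(2.0, 10.0, 2.0, 1.0, 20.0, 1.0),
    base_freqs=(0.35, 0.30, 0.10, 0.25),
    gamma_shape=0.5,
    n_rate_categories=4,
    p_inv=0.3,
)


def make_benchmark(
    seed: int,
    n_ingroup: int = 40,
    n_sites: int = 1500,
    sigma: float = 0.4,
    mean_rate: float = 0.005,
    root_age: float = 180.0,
    ingroup_crown_age: float = 48.0,
    deletion_counts: tuple = (0, 30, 37),
    replicates: int = 10,
    restarts: int = 2,
) -> Benchmark:
    """Build the packaged undersampling benchmark for one seed.

    All randomness (tree shape, rates, sequences, calibration placement,
    deletion sets) derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    s_tree, s_rates, s_aln, s_cal, s_scheme = rng.integers(0, 2**31 - 1, size=5)
    chron, clades = simulate_nested_chronogram(
        n_ingroup,
        8,
        root_age,
        ingroup_crown_age,
        int(s_tree),
        n_sister=2,
    )
    rates = assign_rates(
        chron, RateModel("autocorrelated_lognormal", mean_rate, sigma), int(s_rates)
    )
    phylo = to_phylogram(chron, rates)
    aln = simulate_alignment(phylo, BENCHMARK_MODEL, n_sites, int(s_aln))
    drop = ("out1", "out2", "out3")
    truth_after_drop = chron.pruned(set(drop))
    calibration_sets = {
        strat: make_calibration_set(truth_after_drop, strat, int(s_cal))
        for strat in ("full", "root_only", "root_plus_shallow")
    }
    scheme = SubsamplingScheme(
        target_clade=clades["ingroup"],
        deletion_counts=tuple(deletion_counts),
        replicates=replicates,
        seed=int(s_scheme),
        outgroups_to_drop=drop,
        calibration_strategy="full",
    )
    plcfg = PLConfig(
        smoothing=0.9, num_sites=n_sites, restarts=restarts, seed=int(s_scheme),
        max_iter=300,
    )
    focal = [clades["ingroup"], clades["sister"], clades["ingroup_plus_sister"]]
    return Benchmark(
        chron, clades, phylo, aln, BENCHMARK_MODEL,
        calibration_sets, scheme, plcfg, focal,
    )
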