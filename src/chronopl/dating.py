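"""Penalized-likelihood divergence dating under calibration constraints.

The method treats the expected substitution count on branch k,
x_k = b_k * L, as a Poisson observation with mean r_k * t_k, where r_k is
the branch substitution rate and t_k the branch duration implied by node
ages.  Node ages and rates jointly maximize

    sum_k [ x_k log(r_k t_k) - r_k t_k ]  -  lambda * Phi(rates)

subject to parent-older-than-child ordering and any calibration bounds
(min / max / fixed ages on named clades).  Phi is a roughness penalty on
rate changes between adjacent branches — squared differences of log rates
(the logarithmic penalty) or of raw rates — plus the variance of the rates
on the root's child branches.  Large lambda forces a near-clock solution;
small lambda lets every branch pick its own rate.

Optimization is a projected quasi-Newton scheme (SLSQP) over node ages and
log rates with analytic gradients, restarted from seeded perturbations of
a clock-scaled initial solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .simulate import CalibrationSet
from .treeio import Chronogram, CladeSpec, Tree, crown_age, mrca, prune_taxa

__all__ = [
    "PLConfig",
    "PLProblem",
    "PLSolution",
    "ProfileSummary",
    "InfeasibleCalibrationError",
    "pl_objective",
    "penalty",
    "fit_pl",
    "cross_validate",
    "profile",
]

RATE_FLOOR = 1e-12
TERMINAL_LENGTH_FLOOR = 1e-9  # substitutions/site; guards log(0) on zero tips


class InfeasibleCalibrationError(ValueError):
    """Calibration bounds admit no age assignment on this topology."""


@dataclass(frozen=True)
class PLConfig:
    """Settings for a penalized-likelihood fit.

    smoothing
        the penalty weight lambda (> 0); 0.9 is the default working value.
    penalty_kind
        "log" (squared differences of log rates) or "additive" (raw rates).
    num_sites
        alignment length L used to convert branch lengths to expected
        substitution counts x_k = b_k * L.
    integer_counts
        round x_k to integers (the r8s-style variant); off by default to
        keep the objective smooth.
    restarts
        number of seeded initializations; the first is unperturbed.
    """

    smoothing: float = 0.9
    penalty_kind: str = "log"
    num_sites: int = 1500
    objective_tol: float = 1e-6
    age_tol: float = 1e-4
    restarts: int = 5
    seed: int = 0
    integer_counts: bool = False
    max_iter: int = 400

    def __post_init__(self):
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive (use a tiny value for ~none)")
        if self.penalty_kind not in ("log", "additive"):
            raise ValueError("penalty_kind must be 'log' or 'additive'")
        if self.num_sites < 1:
            raise ValueError("num_sites must be >= 1")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


class PLProblem:
    """A dating problem: phylogram + substitution counts + calibrations."""

    def __init__(self, phylogram: Tree, calibrations: CalibrationSet, config: PLConfig):
        self.phylogram = phylogram
        self.calibrations = calibrations
        self.config = config
        self.x: dict[int, float] = {}
        for nid in phylogram.branches():
            b = phylogram.nodes[nid].length or 0.0
            if phylogram.nodes[nid].is_leaf:
                b = max(b, TERMINAL_LENGTH_FLOOR)
            xk = b * config.num_sites
            if config.integer_counts:
                xk = float(round(xk))
            self.x[nid] = xk

    def node_bounds(self) -> dict[int, tuple[float, float]]:
        """Per-node (lb, ub) from calibrations mapped to MRCA nodes."""
        tree = self.phylogram
        present = set(tree.leaf_names)
        bounds: dict[int, tuple[float, float]] = {}
        for cal in self.calibrations:
            members = cal.clade.taxa & present
            if len(members) < 2:
                continue
            nid = mrca(tree, members)
            lb, ub = bounds.get(nid, (0.0, math.inf))
            if cal.fixed_age is not None:
                lb, ub = max(lb, cal.fixed_age), min(ub, cal.fixed_age)
            if cal.min_age is not None:
                lb = max(lb, cal.min_age)
            if cal.max_age is not None:
                ub = min(ub, cal.max_age)
            if lb > ub:
                raise InfeasibleCalibrationError(
                    f"conflicting bounds on node {nid} ({cal.clade.name}): "
                    f"min {lb} > max {ub}"
                )
            bounds[nid] = (lb, ub)
        return bounds


# ----------------------------------------------------------------------
# Penalty and objective (public, dict-based)
# ----------------------------------------------------------------------

def penalty(rates: dict[int, float], tree: Tree, kind: str = "log") -> float:
    """Rate-roughness penalty Phi.

    Sum over branches whose parent is a non-root branch of the squared
    rate difference to the parent branch, plus the (population) variance
    of rates among the root's child branches.  ``kind="log"`` applies the
    transform on log rates, ``"additive"`` on raw rates.
    """
    if any(r <= 0 for r in rates.values()):
        raise ValueError("rates must be positive")
    f = (lambda r: math.log(r)) if kind == "log" else (lambda r: r)
    total = 0.0
    root = tree.root
    for nid in tree.branches():
        parent = tree.nodes[nid].parent
        if parent != root:
            total += (f(rates[nid]) - f(rates[parent])) ** 2
    root_vals = [f(rates[c]) for c in tree.nodes[root].children]
    total += float(np.var(root_vals))
    return total


def pl_objective(
    problem: PLProblem, ages: dict[int, float], rates: dict[int, float]
) -> float:
    """Evaluate the penalized Poisson log-likelihood at given ages/rates.

    Rates are substitutions/site/MY; the Poisson mean on branch k is
    r_k * L * t_k.  Branches with x_k = 0 contribute only -r_k L t_k
    (the 0*log(0) term is 0).  Raises ``ValueError`` on non-positive
    branch durations.
    """
    tree = problem.phylogram
    L = problem.config.num_sites
    lik = 0.0
    for nid in tree.branches():
        node = tree.nodes[nid]
        t = ages[node.parent] - (0.0 if node.is_leaf else ages[nid])
        if t <= 0:
            raise ValueError(f"non-positive duration on branch to node {nid}")
        mu = rates[nid] * L * t  # expected substitution count on the branch
        x = problem.x[nid]
        lik += (x * math.log(mu) if x > 0 else 0.0) - mu
    return lik - problem.config.smoothing * penalty(
        rates, tree, problem.config.penalty_kind
    )


# ----------------------------------------------------------------------
# Solution containers
# ----------------------------------------------------------------------

@dataclass
class PLSolution:
    """A fitted chronogram with per-branch rates (substitutions/site/MY,
    keyed by child node id) and optimizer diagnostics."""

    chronogram: Chronogram
    rates: dict[int, float]
    objective: float
    penalty_value: float
    converged: bool
    active_constraints: list[str] = field(default_factory=list)
    restart_objectives: list[float] = field(default_factory=list)

    def age_table(self) -> pd.DataFrame:
        """Per-node ages with any active calibration constraints."""
        rows = []
        active = {a.split(":")[0] for a in self.active_constraints}
        for nid in self.chronogram.tree.postorder():
            node = self.chronogram.tree.nodes[nid]
            if node.is_leaf:
                continue
            rows.append(
                {
                    "node": nid,
                    "age_mya": self.chronogram.ages[nid],
                    "active_constraints": ";".join(
                        a for a in self.active_constraints if a.startswith(f"{nid}:")
                    ),
                }
            )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Vectorized objective machinery
# ----------------------------------------------------------------------

class _Indexed:
    """Array view of a PLProblem for fast objective/gradient evaluation.

    Variable vector layout: [internal node ages..., log rates per branch].
    """

    def __init__(self, problem: PLProblem):
        tree = problem.phylogram
        self.tree = tree
        self.internals = [
            nid for nid in tree.postorder() if not tree.nodes[nid].is_leaf
        ]
        self.age_index = {nid: i for i, nid in enumerate(self.internals)}
        self.branch_nodes = tree.branches()
        self.branch_index = {nid: i for i, nid in enumerate(self.branch_nodes)}
        self.n_ages = len(self.internals)
        self.n_branches = len(self.branch_nodes)
        self.x = np.array([problem.x[nid] for nid in self.branch_nodes])
        self.parent_age_idx = np.array(
            [self.age_index[tree.nodes[nid].parent] for nid in self.branch_nodes]
        )
        self.child_age_idx = np.array(
            [
                self.age_index.get(nid, -1)  # -1: leaf (age 0)
                for nid in self.branch_nodes
            ]
        )
        # penalty structure: branch pairs (k, parent-branch of k)
        root = tree.root
        pairs = [
            (self.branch_index[nid], self.branch_index[tree.nodes[nid].parent])
            for nid in self.branch_nodes
            if tree.nodes[nid].parent != root
        ]
        self.pen_child = np.array([p[0] for p in pairs], dtype=int)
        self.pen_parent = np.array([p[1] for p in pairs], dtype=int)
        self.root_children = np.array(
            [self.branch_index[c] for c in tree.nodes[root].children]
        )
        self.lam = problem.config.smoothing
        self.log_penalty = problem.config.penalty_kind == "log"
        # internal rates are counts/MY = L * (subs/site/MY); the additive
        # penalty must act on the per-site scale to match the public one
        self.L = float(problem.config.num_sites)
        # box on log(counts-scale rate): per-site rates in [1e-12, 1e6]
        self.u_lo = math.log(RATE_FLOOR * self.L)
        self.u_hi = math.log(1e6 * self.L)

    def durations(self, ages: np.ndarray) -> np.ndarray:
        child = np.where(self.child_age_idx >= 0, ages[self.child_age_idx], 0.0)
        return ages[self.parent_age_idx] - child

    def penalty_and_grad(self, u: np.ndarray) -> tuple[float, np.ndarray]:
        """Phi and dPhi/du at log rates u (additive kind uses r = e^u)."""
        v = u if self.log_penalty else np.exp(u) / self.L
        grad_v = np.zeros_like(v)
        diff = v[self.pen_child] - v[self.pen_parent]
        phi = float(diff @ diff)
        np.add.at(grad_v, self.pen_child, 2.0 * diff)
        np.add.at(grad_v, self.pen_parent, -2.0 * diff)
        rc = v[self.root_children]
        m = len(rc)
        phi += float(np.var(rc))
        grad_v[self.root_children] += (2.0 / m) * (rc - rc.mean())
        grad_u = grad_v if self.log_penalty else grad_v * np.exp(u) / self.L
        return phi, grad_u

    def penalty_hessian(self, u: np.ndarray) -> np.ndarray:
        """d2 Phi / du2 (constant for the log kind)."""
        n = self.n_branches
        h_v = np.zeros((n, n))
        c, p = self.pen_child, self.pen_parent
        np.add.at(h_v, (c, c), 2.0)
        np.add.at(h_v, (p, p), 2.0)
        np.add.at(h_v, (c, p), -2.0)
        np.add.at(h_v, (p, c), -2.0)
        rc = self.root_children
        m = len(rc)
        h_v[np.ix_(rc, rc)] += (2.0 / m) * (np.eye(m) - 1.0 / m)
        if self.log_penalty:
            return h_v
        v = np.exp(u) / self.L
        # chain rule: H_u = diag(v) H_v diag(v) + diag(dPhi/dv * v)
        diff = v[c] - v[p]
        grad_v = np.zeros(n)
        np.add.at(grad_v, c, 2.0 * diff)
        np.add.at(grad_v, p, -2.0 * diff)
        grad_v[rc] += (2.0 / m) * (v[rc] - v[rc].mean())
        return h_v * np.outer(v, v) + np.diag(grad_v * v)

    def neg_objective(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ages = theta[: self.n_ages]
        u = theta[self.n_ages :]
        t = self.durations(ages)
        if np.any(t <= 0):
            # outside the feasible region (SLSQP can probe here): return a
            # large finite value with a gradient pushing back to feasibility
            bad = t <= 0
            val = 1e12 + float((-t[bad]).sum()) * 1e10
            grad = np.zeros_like(theta)
            g = np.where(bad, -1e10, 0.0)
            np.add.at(grad, self.parent_age_idx, g)
            mask = self.child_age_idx >= 0
            np.add.at(grad, self.child_age_idx[mask], -g[mask])
            return val, grad
        r = np.exp(u)
        rt = r * t
        with np.errstate(divide="ignore"):
            lik = float(np.where(self.x > 0, self.x * np.log(rt), 0.0).sum() - rt.sum())
        phi, dphi_du = self.penalty_and_grad(u)
        obj = lik - self.lam * phi

        grad = np.zeros_like(theta)
        # d/du: x - r t - lam dPhi/du
        grad_u = self.x - rt - self.lam * dphi_du
        # d/dt: x/t - r  -> scatter to parent (+) and internal child (-)
        dt = np.where(self.x > 0, self.x / t, 0.0) - r
        np.add.at(grad, self.parent_age_idx, dt)
        mask = self.child_age_idx >= 0
        np.add.at(grad, self.child_age_idx[mask], -dt[mask])
        grad[self.n_ages :] = grad_u
        return -obj, -grad


def _effective_bounds(
    idx: _Indexed, node_bounds: dict[int, tuple[float, float]], margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate calibration bounds through the tree; raise if infeasible."""
    tree = idx.tree
    lb = np.zeros(idx.n_ages)
    ub = np.full(idx.n_ages, math.inf)
    for nid, (lo, hi) in node_bounds.items():
        i = idx.age_index[nid]
        lb[i] = max(lb[i], lo)
        ub[i] = min(ub[i], hi)
    # root must be bounded above for identifiability
    root_i = idx.age_index[tree.root]
    if not math.isfinite(ub[root_i]):
        finite = ub[np.isfinite(ub)]
        if finite.size == 0:
            raise InfeasibleCalibrationError(
                "no calibration carries a maximum or fixed age"
            )
        ub[root_i] = float(finite.max()) * 100.0
    # children lower bounds push parents up (postorder)
    for nid in tree.postorder():
        if tree.nodes[nid].is_leaf or nid == tree.root:
            continue
        i = idx.age_index[nid]
        p = idx.age_index[tree.nodes[nid].parent]
        lb[p] = max(lb[p], lb[i] + margin)
    # parent upper bounds cap children (preorder)
    for nid in tree.preorder():
        if tree.nodes[nid].is_leaf or nid == tree.root:
            continue
        i = idx.age_index[nid]
        p = idx.age_index[tree.nodes[nid].parent]
        ub[i] = min(ub[i], ub[p] - margin)
    lb = np.maximum(lb, margin)
    if np.any(lb > ub + 1e-12):
        bad = int(np.argmax(lb - ub))
        raise InfeasibleCalibrationError(
            f"calibrations infeasible at node {idx.internals[bad]}: "
            f"min path bound {lb[bad]:.6g} exceeds max {ub[bad]:.6g}"
        )
    return lb, ub


def _clock_initial_ages(idx: _Indexed, lb: np.ndarray, ub: np.ndarray, margin: float) -> np.ndarray:
    """Clock-scaled initial ages: node depth proportional to mean path
    length to its leaves, root at the midpoint of its feasible window."""
    tree = idx.tree
    mean_depth: dict[int, float] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            mean_depth[nid] = 0.0
        else:
            mean_depth[nid] = float(
                np.mean(
                    [mean_depth[c] + (tree.nodes[c].length or 0.0) for c in node.children]
                )
            )
    root_i = idx.age_index[tree.root]
    a0 = (lb[root_i] + ub[root_i]) / 2.0
    if not math.isfinite(a0):
        a0 = lb[root_i] * 2.0 + 1.0
    root_depth = max(mean_depth[tree.root], 1e-300)
    ages = np.array(
        [a0 * mean_depth[nid] / root_depth for nid in idx.internals]
    )
    return _repair_ages(idx, ages, lb, ub, margin)


def _repair_ages(
    idx: _Indexed, ages: np.ndarray, lb: np.ndarray, ub: np.ndarray, margin: float
) -> np.ndarray:
    """Project ages into the feasible region (bounds + ordering)."""
    tree = idx.tree
    ages = ages.copy()
    for _ in range(3):
        for nid in tree.postorder():  # raise above children and own lb
            if tree.nodes[nid].is_leaf:
                continue
            i = idx.age_index[nid]
            child_max = 0.0
            for c in tree.nodes[nid].children:
                if not tree.nodes[c].is_leaf:
                    child_max = max(child_max, ages[idx.age_index[c]])
            ages[i] = max(ages[i], lb[i], child_max + margin)
        for nid in tree.preorder():  # cap below parents and own ub
            if tree.nodes[nid].is_leaf or nid == tree.root:
                continue
            i = idx.age_index[nid]
            p = idx.age_index[tree.nodes[nid].parent]
            ages[i] = min(ages[i], ub[i], ages[p] - margin)
        i_root = idx.age_index[tree.root]
        ages[i_root] = min(ages[i_root], ub[i_root])
    return ages


def _rates_newton(idx: _Indexed, ages: np.ndarray, u0: np.ndarray) -> np.ndarray:
    """Exact Newton ascent on the concave rates subproblem (ages fixed).

    The conditional objective in u = log(counts-scale rate) is
    sum_k [x_k u_k - e^{u_k} t_k] - lam Phi(u): its Hessian is
    -diag(e^u t) - lam * H_Phi, negative definite, so damped Newton with
    backtracking converges globally.
    """
    t = idx.durations(ages)
    u = np.clip(u0, idx.u_lo, idx.u_hi)

    def value_grad(u):
        rt = np.exp(u) * t
        phi, dphi = idx.penalty_and_grad(u)
        val = float((idx.x * u - rt).sum()) - idx.lam * phi
        grad = idx.x - rt - idx.lam * dphi
        return val, grad, rt

    val, grad, rt = value_grad(u)
    for _ in range(60):
        h = -np.diag(rt) - idx.lam * idx.penalty_hessian(u)
        try:
            step = np.linalg.solve(h, -grad)
        except np.linalg.LinAlgError:
            step = grad / (rt + 1.0)
        alpha = 1.0
        for _ in range(30):
            u_new = np.clip(u + alpha * step, idx.u_lo, idx.u_hi)
            new_val, new_grad, new_rt = value_grad(u_new)
            if new_val >= val:
                break
            alpha *= 0.5
        if new_val < val:
            break
        moved = new_val - val
        u, val, grad, rt = u_new, new_val, new_grad, new_rt
        if np.abs(grad).max() < 1e-9 * (1.0 + np.abs(idx.x).max()) or moved < 1e-12 * (
            1.0 + abs(val)
        ):
            break
    return u


def _rank_initial_ages(
    idx: _Indexed, lb: np.ndarray, ub: np.ndarray, margin: float
) -> np.ndarray:
    """Topology-only initial ages: node height (longest leafward path in
    edges) scaled so the root sits at the midpoint of its window.  Immune
    to branch-length pathologies under extreme rate variation."""
    tree = idx.tree
    height: dict[int, int] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        height[nid] = 0 if node.is_leaf else 1 + max(height[c] for c in node.children)
    root_i = idx.age_index[tree.root]
    a0 = (lb[root_i] + ub[root_i]) / 2.0
    if not math.isfinite(a0):
        a0 = lb[root_i] * 2.0 + 1.0
    ages = np.array(
        [a0 * height[nid] / height[tree.root] for nid in idx.internals]
    )
    return _repair_ages(idx, ages, lb, ub, margin)


def fit_pl(problem: PLProblem) -> PLSolution:
    """Maximize the penalized likelihood over node ages and branch rates.

    Requires a binary phylogram.  The optimizer profiles the rates out:
    for any candidate age vector the concave conditional rates problem is
    solved exactly by damped Newton, and a projected quasi-Newton scheme
    (SLSQP, with the envelope gradient) maximizes the resulting profiled
    objective over node ages under ordering and calibration constraints.
    Runs ``config.restarts`` seeded initializations — the first from an
    unperturbed clock-scaled (mean-path-length) solution, the second from
    a topology-rank solution, the rest jittered — and returns the best by
    objective, breaking near-ties (relative 1e-9) toward the lower
    penalty, then the earlier restart.  Infeasible calibrations raise
    :class:`InfeasibleCalibrationError` before any optimization;
    non-convergence is flagged on the solution.
    """
    tree = problem.phylogram
    if not tree.is_binary():
        raise ValueError("penalized-likelihood dating requires a binary tree")
    cfg = problem.config
    idx = _Indexed(problem)
    node_bounds = problem.node_bounds()
    root_i_guess = max(
        (hi for _, hi in node_bounds.values() if math.isfinite(hi)), default=100.0
    )
    margin = 1e-7 * root_i_guess
    lb, ub = _effective_bounds(idx, node_bounds, margin)

    base_ages = _clock_initial_ages(idx, lb, ub, margin)
    total_x = float(idx.x.sum())
    mean_rate = max(total_x / max(idx.durations(base_ages).sum(), 1e-300), RATE_FLOOR)
    base_u = np.full(idx.n_branches, math.log(mean_rate))

    rows = []
    for k, nid in enumerate(idx.branch_nodes):
        if idx.child_age_idx[k] >= 0:
            row = np.zeros(idx.n_ages)
            row[idx.parent_age_idx[k]] = 1.0
            row[idx.child_age_idx[k]] = -1.0
            rows.append(row)
    G = np.array(rows) if rows else np.zeros((0, idx.n_ages))

    def objective(ages, u):
        return -idx.neg_objective(np.concatenate([ages, u]))[0]

    rank_ages = _rank_initial_ages(idx, lb, ub, margin)
    constraints = (
        [{"type": "ineq", "fun": lambda a: G @ a - margin, "jac": lambda a: G}]
        if len(G)
        else []
    )
    age_bounds = [(float(l), float(h)) for l, h in zip(lb, ub)]

    rng = np.random.default_rng(cfg.seed)
    best = None
    restart_objs = []
    for restart in range(cfg.restarts):
        if restart == 0:
            ages0 = base_ages
        elif restart == 1:
            ages0 = rank_ages
        else:
            base = base_ages if restart % 2 == 0 else rank_ages
            jitter = rng.uniform(0.8, 1.2, size=idx.n_ages)
            ages0 = _repair_ages(idx, base * jitter, lb, ub, margin)
        state = {"u": np.clip(base_u, idx.u_lo, idx.u_hi)}

        def profiled(a):
            u = _rates_newton(idx, a, state["u"])
            state["u"] = u
            val, grad = idx.neg_objective(np.concatenate([a, u]))
            return val, grad[: idx.n_ages]

        res = minimize(
            profiled,
            ages0,
            jac=True,
            method="SLSQP",
            bounds=age_bounds,
            constraints=constraints,
            options={"maxiter": cfg.max_iter, "ftol": cfg.objective_tol},
        )
        ages = _repair_ages(idx, np.clip(res.x, lb, ub), lb, ub, margin)
        u = _rates_newton(idx, ages, state["u"])
        obj = objective(ages, u)
        phi, _ = idx.penalty_and_grad(u)
        restart_objs.append(obj)
        cand = (obj, phi, restart, ages.copy(), u.copy(), bool(res.success))
        if best is None:
            best = cand
        else:
            tie = abs(obj - best[0]) <= 1e-9 * (1.0 + abs(best[0]))
            if (not tie and obj > best[0]) or (tie and phi < best[1] - 1e-12):
                best = cand

    obj, phi, _, ages_vec, u_vec, converged_opt = best
    theta = np.concatenate([ages_vec, u_vec])
    ages_vec = ages_vec.copy()
    # snap ages sitting essentially on a calibration bound onto it exactly
    snap_tol = 5e-6 * (1.0 + root_i_guess)
    snapped = ages_vec.copy()
    for nid, (lo, hi) in node_bounds.items():
        i = idx.age_index[nid]
        if abs(snapped[i] - lo) < snap_tol:
            snapped[i] = lo
        elif math.isfinite(hi) and abs(snapped[i] - hi) < snap_tol:
            snapped[i] = hi
    if _ordering_ok(idx, snapped):
        ages_vec = snapped

    rates = {
        nid: float(np.exp(theta[idx.n_ages + k])) / idx.L
        for k, nid in enumerate(idx.branch_nodes)
    }
    ages = {nid: float(ages_vec[i]) for nid, i in idx.age_index.items()}
    for leaf in tree.leaves():
        ages[leaf] = 0.0

    active = []
    within_bounds = True
    for nid, (lo, hi) in node_bounds.items():
        a = ages[nid]
        if a < lo - 1e-6 or a > hi + 1e-6:
            within_bounds = False
        if abs(a - lo) <= 1e-6:
            active.append(f"{nid}:min={lo:.8g}")
        if math.isfinite(hi) and abs(a - hi) <= 1e-6:
            active.append(f"{nid}:max={hi:.8g}")

    chron_tree = tree.copy()
    for nid in chron_tree.branches():
        chron_tree.nodes[nid].length = None
    chron = Chronogram(chron_tree, ages, validate=False)
    objective = pl_objective(problem, ages, rates)
    return PLSolution(
        chronogram=chron,
        rates=rates,
        objective=objective,
        penalty_value=penalty(rates, tree, cfg.penalty_kind),
        converged=converged_opt and within_bounds,
        active_constraints=active,
        restart_objectives=restart_objs,
    )


def _ordering_ok(idx: _Indexed, ages: np.ndarray) -> bool:
    child = np.where(idx.child_age_idx >= 0, ages[idx.child_age_idx], 0.0)
    return bool(np.all(ages[idx.parent_age_idx] - child > 0))


# ----------------------------------------------------------------------
# Cross-validation of the smoothing parameter
# ----------------------------------------------------------------------

def cross_validate(
    problem: PLProblem, lambda_grid: list[float]
) -> dict[float, float]:
    """Leave-one-terminal-branch-out cross-validation score per lambda.

    Each terminal branch is pruned in turn, the reduced problem refit, and
    the pruned terminal's substitution count predicted as
    r_hat_parent * t_hat, where r_hat_parent is the fitted rate of the
    branch the terminal attached to and t_hat the (apportioned) age of its
    attachment point.  The score is the chi-square-style sum
    (x_obs - x_pred)^2 / x_pred.  Terminals attached directly to the root
    are skipped — their attachment age does not survive pruning.
    """
    tree = problem.phylogram
    if tree.n_leaves < 4:
        raise ValueError("cross-validation needs at least 4 leaves")
    cfg = problem.config
    scores = {float(lam): 0.0 for lam in lambda_grid}
    for leaf in tree.leaves():
        node = tree.nodes[leaf]
        p = node.parent
        if p == tree.root:
            continue
        name = node.label
        sibling = next(c for c in tree.nodes[p].children if c != leaf)
        sib_taxa = tree.clade_leaves(sibling)
        g = tree.nodes[p].parent
        g_taxa = tree.clade_leaves(g) - {name}
        b_upper = tree.nodes[p].length or 0.0   # g -> p
        b_lower = tree.nodes[sibling].length or 0.0  # p -> sibling
        x_obs = problem.x[leaf]

        pruned = prune_taxa(tree, {name})
        survivors = set(pruned.leaf_names)
        cals = problem.calibrations.restrict(survivors)
        for lam in lambda_grid:
            sub_cfg = PLConfig(
                smoothing=float(lam),
                penalty_kind=cfg.penalty_kind,
                num_sites=cfg.num_sites,
                objective_tol=cfg.objective_tol,
                age_tol=cfg.age_tol,
                restarts=cfg.restarts,
                seed=cfg.seed,
                integer_counts=cfg.integer_counts,
                max_iter=cfg.max_iter,
            )
            sol = fit_pl(PLProblem(pruned, cals, sub_cfg))
            chron = sol.chronogram
            if len(sib_taxa) >= 2:
                s_node = mrca(chron.tree, sib_taxa)
                age_s = chron.ages[s_node]
            else:
                s_node = chron.tree.leaf_by_name()[next(iter(sib_taxa))]
                age_s = 0.0
            age_g = chron.ages[mrca(chron.tree, g_taxa)]
            frac = b_lower / max(b_lower + b_upper, 1e-300)
            t_hat = age_s + (age_g - age_s) * frac
            r_hat = sol.rates[s_node]  # subs/site/MY
            x_pred = max(r_hat * cfg.num_sites * t_hat, 1e-12)
            scores[float(lam)] += (x_obs - x_pred) ** 2 / x_pred
    return scores


# ----------------------------------------------------------------------
# PROFILE-style summaries
# ----------------------------------------------------------------------

@dataclass
class ProfileRow:
    mean: float | None
    sd: float | None
    n_valid: int
    n_total: int


class ProfileSummary:
    """Per-clade mean/SD of crown ages over a set of dated trees.

    Trees in which a clade keeps fewer than two sampled members contribute
    nothing to that clade (its ``n_valid`` drops); a clade with no valid
    trees reports N/A (``mean is None``).
    """

    def __init__(self, rows: dict[str, ProfileRow]):
        self.rows = rows

    def __getitem__(self, name: str) -> ProfileRow:
        return self.rows[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clade": name,
                    "mean_age": r.mean,
                    "sd_age": r.sd,
                    "n_valid": r.n_valid,
                    "n_total": r.n_total,
                }
                for name, r in self.rows.items()
            ]
        )


def profile(solutions: list, clades: list[CladeSpec]) -> ProfileSummary:
    """Crown-age mean and sample SD (n-1 denominator) per clade.

    ``solutions`` may mix :class:`PLSolution` and :class:`Chronogram`
    objects.  A clade observed in exactly one tree reports SD 0.
    """
    if not solutions:
        raise ValueError("need at least one dated tree")
    chrons = [
        s.chronogram if isinstance(s, PLSolution) else s for s in solutions
    ]
    rows: dict[str, ProfileRow] = {}
    for clade in clades:
        ages = [a for c in chrons if (a := crown_age(c, clade)) is not None]
        n_valid = len(ages)
        if n_valid == 0:
            rows[clade.name] = ProfileRow(None, None, 0, len(chrons))
        else:
            mean = float(np.mean(ages))
            sd = 0.0 if n_valid == 1 else float(np.std(ages, ddof=1))
            rows[clade.name] = ProfileRow(mean, sd, n_valid, len(chrons))
    return ProfileSummary(rows)
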