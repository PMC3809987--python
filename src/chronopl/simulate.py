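"""Synthetic data with known ground truth.

Generates (i) pure-birth chronograms, (ii) per-branch substitution rates
under strict, iid-lognormal or autocorrelated-lognormal clocks, (iii)
phylograms (b_k = r_k * t_k), (iv) GTR+Gamma+I alignments evolved on a
phylogram, and (v) fossil-shaped calibration sets: one root min/max window
plus internal minimum-age constraints that always sit below the true node
age, emulating how fossils only bound clade ages from below.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import Chronogram, CladeSpec, Tree

__all__ = [
    "RateModel",
    "SubstitutionModel",
    "Alignment",
    "Calibration",
    "CalibrationSet",
    "simulate_chronogram",
    "simulate_nested_chronogram",
    "assign_rates",
    "to_phylogram",
    "simulate_alignment",
    "make_calibration_set",
]

# nucleotide order used everywhere
NUC = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUC)}

# IUPAC ambiguity -> state mask (1 = compatible)
AMBIG = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1), "X": (1, 1, 1, 1),
}


def _child_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# ----------------------------------------------------------------------
# Models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RateModel:
    """Per-branch substitution-rate process.

    kind
        ``strict`` (one rate), ``iid_lognormal`` (independent lognormal per
        branch, mean preserved) or ``autocorrelated_lognormal`` (geometric
        Brownian walk of log-rate along the tree; variance grows as
        sigma^2 * branch duration).
    mean_rate
        substitutions/site/MY (> 0).
    sigma
        log-scale SD (per sqrt(MY) for the autocorrelated kind); 0 reduces
        every kind to the strict clock.
    """

    kind: str = "strict"
    mean_rate: float = 0.005
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("strict", "iid_lognormal", "autocorrelated_lognormal"):
            raise ValueError(f"unknown rate model kind {self.kind!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Gamma+I.

    ``exchangeabilities`` are the six upper-triangle rates in order
    AC, AG, AT, CG, CT, GT with GT fixed to 1 for identifiability.
    The rate matrix is scaled so that the expected substitution rate at
    stationarity is 1 *including* the invariant class, i.e. branch lengths
    are expected substitutions per site overall.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    p_inv: float = 0.0
    gamma_category: str = "mean"  # or "median"

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(x <= 0 for x in self.exchangeabilities):
            raise ValueError("need 6 positive exchangeabilities")
        if len(self.base_freqs) != 4 or any(f <= 0 for f in self.base_freqs):
            raise ValueError("need 4 positive base frequencies")
        if abs(sum(self.base_freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR generator Q (rows sum to 0, mean rate 1 overall)."""
        pi = np.asarray(self.base_freqs, float)
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        pairs = [(0, 1, ac), (0, 2, ag), (0, 3, at), (1, 2, cg), (1, 3, ct), (2, 3, gt)]
        for i, j, x in pairs:
            s[i, j] = s[j, i] = x
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the invariant + discrete-gamma mixture.

        Gamma category rates are normalised so the whole mixture has mean 1:
        the K variable categories carry rate ``g_k / (1 - p_inv)`` with
        ``mean(g_k) = 1``, the invariant class carries rate 0.
        """
        k = self.n_rate_categories
        a = self.gamma_shape
        if k == 1:
            g = np.array([1.0])
        elif self.gamma_category == "median":
            g = gamma_dist.ppf((np.arange(k) + 0.5) / k, a, scale=1.0 / a)
            g = g / g.mean()
        else:  # mean of each equal-probability category
            cuts = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
            upper = gammainc(a + 1, np.append(cuts * a, np.inf))
            lower = np.append(0.0, upper[:-1])
            g = k * (upper - lower)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], g / (1.0 - self.p_inv)])
            weights = np.concatenate(
                [[self.p_inv], np.full(k, (1.0 - self.p_inv) / k)]
            )
        else:
            rates = g
            weights = np.full(k, 1.0 / k)
        return rates, weights


# ----------------------------------------------------------------------
# Alignment container
# ----------------------------------------------------------------------

class Alignment:
    """Equal-length sequences over {A,C,G,T,-,N,...} with pattern support."""

    def __init__(self, taxa: list[str], sequences: list[str]):
        if len(taxa) != len(sequences):
            raise ValueError("taxa/sequence count mismatch")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        self.taxa = list(taxa)
        self.sequences = [s.upper() for s in sequences]

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.taxa)

    def subset(self, taxa: list[str]) -> "Alignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return Alignment(list(taxa), [self.sequences[idx[t]] for t in taxa])

    def columns(self) -> np.ndarray:
        """Character matrix of shape (n_taxa, n_sites)."""
        return np.array([list(s) for s in self.sequences])

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their counts (columns of the matrix)."""
        mat = self.columns()
        uniq, counts = np.unique(mat, axis=1, return_counts=True)
        return uniq, counts

    # ---- I/O (delegates format handling to Biopython) ----------------

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n" for t, s in zip(self.taxa, self.sequences))

    def to_phylip(self) -> str:
        """Relaxed PHYLIP: full names, whitespace separated."""
        width = max(len(t) for t in self.taxa) + 2
        head = f" {len(self.taxa)} {self.n_sites}\n"
        rows = "".join(
            f"{t:<{width}}{s}\n" for t, s in zip(self.taxa, self.sequences)
        )
        return head + rows

    def write(self, path, fmt: str = "fasta") -> None:
        text = self.to_fasta() if fmt == "fasta" else self.to_phylip()
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def read(cls, source, fmt: str = "fasta") -> "Alignment":
        from Bio import AlignIO

        bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        if hasattr(source, "read"):
            handle = source
        else:
            handle = open(source)
        try:
            aln = AlignIO.read(handle, bio_fmt)
        finally:
            if handle is not source:
                handle.close()
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    @classmethod
    def from_string(cls, text: str, fmt: str = "fasta") -> "Alignment":
        return cls.read(io.StringIO(text), fmt)


# ----------------------------------------------------------------------
# Calibrations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """A min / max / fixed age bound (MYA) on a clade's MRCA."""

    clade: CladeSpec
    min_age: float | None = None
    max_age: float | None = None
    fixed_age: float | None = None

    def __post_init__(self):
        if self.min_age is None and self.max_age is None and self.fixed_age is None:
            raise ValueError("calibration carries no bound")
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError("min_age exceeds max_age")


class CalibrationSet:
    """An ordered collection of calibrations.

    Penalized-likelihood dating is only identifiable when at least one
    entry carries a maximum or fixed age (otherwise ages can grow without
    bound); that is enforced here.
    """

    def __init__(self, calibrations: list[Calibration]):
        if not calibrations:
            raise ValueError("empty calibration set")
        if not any(c.max_age is not None or c.fixed_age is not None for c in calibrations):
            raise ValueError("need at least one max or fixed age calibration")
        self.calibrations = list(calibrations)

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)

    def restrict(self, surviving_taxa: set[str]) -> "CalibrationSet":
        """Drop calibrations whose clade keeps < 2 members after pruning."""
        kept = [
            c for c in self.calibrations if len(c.clade.taxa & surviving_taxa) >= 2
        ]
        return CalibrationSet(kept)

    # ---- structured-config round trip --------------------------------

    def to_yaml(self) -> str:
        import yaml

        entries = []
        for c in self.calibrations:
            e: dict = {"name": c.clade.name, "taxa": sorted(c.clade.taxa)}
            for k in ("min_age", "max_age", "fixed_age"):
                v = getattr(c, k)
                if v is not None:
                    e[k] = float(v)
            entries.append(e)
        return yaml.safe_dump({"calibrations": entries}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CalibrationSet":
        import yaml

        data = yaml.safe_load(text)
        cals = [
            Calibration(
                CladeSpec(e["name"], e["taxa"]),
                min_age=e.get("min_age"),
                max_age=e.get("max_age"),
                fixed_age=e.get("fixed_age"),
            )
            for e in data["calibrations"]
        ]
        return cls(cals)


# ----------------------------------------------------------------------
# Chronogram simulation
# ----------------------------------------------------------------------

def simulate_chronogram(n_taxa: int, root_age: float, seed) -> Chronogram:
    """Pure-birth (Yule) chronogram with ``n_taxa`` extant leaves, node
    times rescaled so the root sits exactly at ``root_age`` MYA."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    return _yule(n_taxa, root_age, _child_rng(seed))


def _yule(n_taxa: int, root_age: float, rng: np.random.Generator) -> Chronogram:
    tree = Tree()
    root = tree.add_node()
    # event times measured forward from the root (t=0)
    event_time = {root: 0.0}
    c1 = tree.add_node(root)
    c2 = tree.add_node(root)
    active = [c1, c2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        nid = active.pop(rng.integers(len(active)))
        event_time[nid] = t
        active.append(tree.add_node(nid))
        active.append(tree.add_node(nid))
    present = t + rng.exponential(1.0 / len(active))
    scale = root_age / present
    ages = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            ages[nid] = 0.0
        else:
            ages[nid] = (present - event_time[nid]) * scale
    for i, nid in enumerate(sorted(tree.leaves())):
        tree.nodes[nid].label = f"t{i + 1}"
    return Chronogram(tree, ages)


def simulate_nested_chronogram(
    n_ingroup: int,
    n_outgroup: int,
    root_age: float,
    ingroup_crown_age: float,
    seed,
    stem_fraction: float = 1.3,
    n_sister: int = 0,
    sister_crown_fraction: float = 0.6,
) -> tuple[Chronogram, dict[str, CladeSpec]]:
    """A chronogram with a monophyletic focal ingroup subtended by a ladder
    of successively deeper outgroup lineages (the usual shape of a focal
    radiation plus sparse outgroups).

    The ingroup is a Yule tree rescaled to ``ingroup_crown_age``; the
    ladder divergences are evenly spaced between the ingroup stem
    (``stem_fraction * ingroup_crown_age``) and the root.  With
    ``n_sister >= 2``, that many of the outgroup taxa instead form a small
    Yule clade (crown ``sister_crown_fraction * ingroup_crown_age``) that
    is the ingroup's immediate sister — a focal clade whose sampling is
    untouched by subsampling experiments.

    Returns the chronogram and named clade specs: ``ingroup``, and when a
    sister clade exists, ``sister`` and ``ingroup_plus_sister``.
    """
    if n_sister == 1 or n_sister < 0:
        raise ValueError("n_sister must be 0 or >= 2")
    n_ladder = n_outgroup - n_sister
    if n_ladder < 1:
        raise ValueError("need at least one ladder outgroup")
    stem_age = stem_fraction * ingroup_crown_age
    if not ingroup_crown_age < stem_age < root_age:
        raise ValueError("require ingroup_crown_age < stem age < root_age")
    rng = _child_rng(seed)
    inner = _yule(n_ingroup, ingroup_crown_age, rng)
    sister = (
        _yule(n_sister, sister_crown_fraction * ingroup_crown_age, rng)
        if n_sister
        else None
    )

    tree = Tree()
    ages: dict[int, float] = {}
    spine_ages = np.linspace(root_age, stem_age, n_ladder + 1)[:-1]
    parent = None
    for i, a in enumerate(spine_ages):
        nid = tree.add_node(parent)
        ages[nid] = float(a)
        leaf = tree.add_node(nid, label=f"out{i + 1}")
        ages[leaf] = 0.0
        parent = nid

    def graft(sub: Chronogram, under: int | None, prefix: str) -> int:
        mapping: dict[int, int] = {}
        for old in sub.tree.preorder():
            onode = sub.tree.nodes[old]
            par = under if onode.parent is None else mapping[onode.parent]
            label = f"{prefix}{onode.label[1:]}" if onode.is_leaf else None
            new = tree.add_node(par, label=label)
            mapping[old] = new
            ages[new] = sub.ages[old]
        return mapping[sub.tree.root]

    if sister is not None:
        join = tree.add_node(parent)
        ages[join] = stem_age
        graft(sister, join, "sis")
        graft(inner, join, "in")
    else:
        graft(inner, parent, "in")

    ingroup_taxa = frozenset(f"in{i + 1}" for i in range(n_ingroup))
    clades = {"ingroup": CladeSpec("ingroup", ingroup_taxa)}
    if sister is not None:
        sister_taxa = frozenset(f"sis{i + 1}" for i in range(n_sister))
        clades["sister"] = CladeSpec("sister", sister_taxa)
        clades["ingroup_plus_sister"] = CladeSpec(
            "ingroup_plus_sister", ingroup_taxa | sister_taxa
        )
    return Chronogram(tree, ages), clades


# ----------------------------------------------------------------------
# Rates and phylograms
# ----------------------------------------------------------------------

def assign_rates(chron: Chronogram, model: RateModel, seed) -> dict[int, float]:
    """Per-branch rates r_k keyed by child node id.

    strict: every branch at ``mean_rate``.  iid_lognormal: independent
    lognormals with expectation ``mean_rate`` (log-mean shifted by
    -sigma^2/2).  autocorrelated_lognormal: log-rate random walk along the
    tree, Var[log r_child | log r_parent] = sigma^2 * t_branch, with the
    branches off the root started at ``mean_rate``.
    """
    rng = _child_rng(seed)
    tree = chron.tree
    rates: dict[int, float] = {}
    mu = np.log(model.mean_rate)
    if model.kind == "strict" or model.sigma == 0.0:
        return {nid: model.mean_rate for nid in tree.branches()}
    if model.kind == "iid_lognormal":
        for nid in tree.branches():
            rates[nid] = float(
                np.exp(rng.normal(mu - model.sigma**2 / 2.0, model.sigma))
            )
        return rates
    # autocorrelated random walk, parent rate at the root = mean_rate
    log_rate_at = {tree.root: mu}
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        t = chron.duration(nid)
        lr = rng.normal(log_rate_at[tree.nodes[nid].parent], model.sigma * np.sqrt(max(t, 0.0)))
        log_rate_at[nid] = lr
        rates[nid] = float(np.exp(lr))
    return rates


def to_phylogram(chron: Chronogram, rates: dict[int, float]) -> Tree:
    """Tree with branch lengths b_k = r_k * t_k (substitutions/site)."""
    branch_ids = set(chron.tree.branches())
    if set(rates) != branch_ids:
        raise ValueError("rates must cover exactly the non-root branches")
    if any(r <= 0 for r in rates.values()):
        raise ValueError("rates must be positive")
    t = chron.tree.copy()
    for nid in branch_ids:
        t.nodes[nid].length = rates[nid] * chron.duration(nid)
    t.nodes[t.root].length = None
    return t


# ----------------------------------------------------------------------
# Sequence simulation
# ----------------------------------------------------------------------

def simulate_alignment(
    phylo: Tree, model: SubstitutionModel, n_sites: int, seed
) -> Alignment:
    """Evolve ``n_sites`` nucleotide sites down ``phylo`` under GTR+Gamma+I.

    Each site is independently invariant (probability ``p_inv``) or drawn
    from one of the discrete-gamma categories; root states come from the
    stationary frequencies.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = _child_rng(seed)
    from .likelihood import GTREigen  # local import to avoid a cycle

    eig = GTREigen(model)
    rates, weights = model.category_rates()
    cat = rng.choice(len(rates), size=n_sites, p=weights)
    pi = np.asarray(model.base_freqs)
    states = {phylo.root: rng.choice(4, size=n_sites, p=pi)}
    for nid in phylo.preorder():
        if nid == phylo.root:
            continue
        node = phylo.nodes[nid]
        b = node.length or 0.0
        parent_states = states[node.parent]
        child = np.empty(n_sites, dtype=np.int64)
        for c, rate in enumerate(rates):
            mask = cat == c
            if not mask.any():
                continue
            p = eig.transition_matrix(b * rate)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[nid] = child
    nuc = np.array(list(NUC))
    taxa, seqs = [], []
    for leaf in phylo.leaves():
        taxa.append(phylo.nodes[leaf].label)
        seqs.append("".join(nuc[states[leaf]]))
    return Alignment(taxa, seqs)


# ----------------------------------------------------------------------
# Calibration-set generation
# ----------------------------------------------------------------------

def make_calibration_set(
    chron: Chronogram,
    strategy: str = "full",
    seed=0,
    n_internal: int = 10,
    min_fraction: tuple[float, float] = (0.6, 0.95),
    root_window: tuple[float, float] = (0.8, 1.2),
) -> CalibrationSet:
    """Generate a fossil-shaped calibration set from a true chronogram.

    full
        a root min/max window (``root_window`` x true root age) plus
        ``n_internal`` randomly chosen internal nodes, each given a minimum
        age that is a Uniform ``min_fraction`` multiple of its true age —
        fossil minima always underestimate the true age.
    root_only
        just the root window.
    root_plus_shallow
        the root window plus one minimum-age calibration on a node from the
        youngest quartile of internal node ages.
    """
    if strategy not in ("full", "root_only", "root_plus_shallow"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = _child_rng(seed)
    tree = chron.tree
    root = tree.root
    internals = [
        nid
        for nid in tree.postorder()
        if not tree.nodes[nid].is_leaf and nid != root
    ]
    true_root = chron.root_age
    root_cal = Calibration(
        CladeSpec("root", tree.clade_leaves(root)),
        min_age=root_window[0] * true_root,
        max_age=root_window[1] * true_root,
    )
    cals = [root_cal]
    if strategy == "full":
        if len(internals) < n_internal:
            raise ValueError(
                f"need >= {n_internal} non-root internal nodes, have {len(internals)}"
            )
        chosen = rng.choice(len(internals), size=n_internal, replace=False)
        for i, idx in enumerate(sorted(chosen)):
            nid = internals[idx]
            u = rng.uniform(*min_fraction)
            cals.append(
                Calibration(
                    CladeSpec(f"fossil_{i + 1}", tree.clade_leaves(nid)),
                    min_age=u * chron.ages[nid],
                )
            )
    elif strategy == "root_plus_shallow":
        ages = np.array([chron.ages[n] for n in internals])
        cutoff = np.quantile(ages, 0.25)
        shallow = [n for n, a in zip(internals, ages) if a <= cutoff]
        nid = shallow[rng.integers(len(shallow))]
        u = rng.uniform(*min_fraction)
        cals.append(
            Calibration(
                CladeSpec("shallow_fossil", tree.clade_leaves(nid)),
                min_age=u * chron.ages[nid],
            )
        )
    return CalibrationSet(cals)
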