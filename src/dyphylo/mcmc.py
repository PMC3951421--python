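"""Metropolis-Hastings MCMC over clock trees and substitution parameters.

A single chain explores rooted (by default strict-clock, ultrametric) trees
under the two-state gamma model, with optional monophyly constraints and an
outgroup, producing a posterior trace of trees and parameters.

Priors
------
* topology: uniform over rooted topologies satisfying the constraints
  (enforced by rejecting violating proposals);
* node ages: root age fixed at 1 (the tree-height/rate non-identifiability is
  resolved by fixing height); each remaining internal age is, a priori, a
  uniform fraction of its parent's age ("cascade" prior, properly normalized
  for every topology so the topology marginal stays uniform);
* clock rate ~ Gamma(2, 2) (mean 1/2 substitution per character per unit
  height, weakly informative);
* pi1 ~ Uniform(0, 1); alpha ~ Exponential(1);
* relaxed clock ("relaxed_ulnorm"): independent lognormal branch-rate
  multipliers with mean 1 and log-sd sigma ~ Exponential(3) — an uncorrelated
  simplification of autocorrelated relaxed clocks;
* non-clock ("none"): free branch lengths ~ Exponential(5).

Proposals: NNI on the topology, node-age slide, clock-rate/alpha scale,
pi1 reflected slide, plus branch-rate and sigma moves for the relaxed clock
and branch-length scaling for the non-clock model. Constraint-violating
topology proposals have prior probability zero and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charmatrix import MISSING, CharacterMatrix
from .likelihood import (
    SubstModel,
    discrete_gamma_rates,
    prune_site_likelihoods_binary,
)
from .trees import PhyloTree, TreeNode

__all__ = [
    "MCMCConfig",
    "Constraint",
    "PosteriorTrace",
    "run_mcmc",
    "sample_accounting",
    "effective_sample_size",
    "check_constraint",
]

_DEFAULT_WEIGHTS = {
    "nni": 3.0,
    "age_slide": 3.0,
    "clock_scale": 1.0,
    "pi1_slide": 0.5,
    "alpha_scale": 0.5,
    "branch_rate": 0.0,
    "sigma_scale": 0.0,
    "blen_scale": 0.0,
}


@dataclass(frozen=True)
class Constraint:
    """A monophyly constraint: the named taxa must form a clade in every
    sampled tree."""

    taxa: frozenset[str]
    kind: str = "monophyly"

    def __post_init__(self) -> None:
        if self.kind != "monophyly":
            raise ValueError("only monophyly constraints are supported")
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        if len(self.taxa) < 2:
            raise ValueError("a monophyly constraint needs at least 2 taxa")


@dataclass(frozen=True)
class MCMCConfig:
    n_generations: int = 2_000_000
    sample_every: int = 500
    burnin_fraction: float = 0.25
    clock: str = "strict"
    constraints: tuple[Constraint, ...] = ()
    outgroup: str | None = None
    seed: int = 0
    proposal_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_generations < 0 or self.sample_every <= 0:
            raise ValueError("invalid generation counts")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.clock not in ("strict", "relaxed_ulnorm", "none"):
            raise ValueError('clock must be "strict", "relaxed_ulnorm" or "none"')
        object.__setattr__(self, "constraints", tuple(self.constraints))


@dataclass
class PosteriorTrace:
    """Sampled trees and parameters from one chain."""

    trees: list[PhyloTree]
    generations: np.ndarray
    log_likelihood: np.ndarray
    log_prior: np.ndarray
    pi1: np.ndarray
    alpha: np.ndarray
    clock_rate: np.ndarray
    seed: int
    config: MCMCConfig
    acceptance_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.trees)

    def burnin_count(self) -> int:
        return int(math.floor(self.config.burnin_fraction * self.n_samples))

    def retained_trees(self) -> list[PhyloTree]:
        return self.trees[self.burnin_count():]

    def retained_log_likelihood(self) -> np.ndarray:
        return self.log_likelihood[self.burnin_count():]


def sample_accounting(cfg: MCMCConfig) -> tuple[int, int, int]:
    """(n_sampled, n_burned, n_retained) under the sampling grid.

    Generation 0 is always sampled, so n_sampled = floor(G / s) + 1; the
    burn-in count is floor(burnin_fraction * n_sampled).
    """
    n_sampled = cfg.n_generations // cfg.sample_every + 1
    n_burned = int(math.floor(cfg.burnin_fraction * n_sampled))
    return n_sampled, n_burned, n_sampled - n_burned


def effective_sample_size(series: np.ndarray) -> float:
    """ESS = n / (1 + 2 sum of autocorrelations), with Geyer's initial
    monotone positive-sequence truncation; capped at n. A constant series is
    reported as ESS = n (degenerate, no information about mixing)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    var = x.var()
    if var == 0:
        return float(n)
    xc = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sums of adjacent pairs, keep while positive and non-increasing
    gamma = rho[1:-1:2] + rho[2::2]
    total = 0.0
    prev = np.inf
    for g in gamma:
        if g <= 0:
            break
        g = min(g, prev)
        total += g
        prev = g
    ess = n / (1.0 + 2.0 * total)
    return float(min(ess, n))


def check_constraint(tree: PhyloTree, c: Constraint) -> bool:
    """True iff some node's tip set equals the constraint's taxa exactly."""
    want = frozenset(c.taxa)
    if not want <= set(tree.leaf_labels()):
        raise ValueError("constraint taxa must be a subset of the tree's tips")
    return want in set(tree.clades())


def _check_compatible(constraints: tuple[Constraint, ...], taxa: set[str]) -> None:
    for c in constraints:
        missing = c.taxa - taxa
        if missing:
            raise ValueError(f"constraint taxa not in matrix: {sorted(missing)}")
        if len(c.taxa) >= len(taxa):
            raise ValueError("a constraint must be a proper subset of the taxa")
    for i, a in enumerate(constraints):
        for b in constraints[i + 1:]:
            inter = a.taxa & b.taxa
            if inter and not (a.taxa <= b.taxa or b.taxa <= a.taxa):
                raise ValueError(
                    f"incompatible constraints: {sorted(a.taxa)} / {sorted(b.taxa)}"
                )


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

class TreeState:
    """Array-backed rooted binary tree with tip bitmasks.

    Tips are node ids 0..n-1; internals n..2n-2; the root keeps a fixed id.
    ``blen`` is only used for the non-clock model.
    """

    def __init__(self, n_tips: int) -> None:
        self.n = n_tips
        total = 2 * n_tips - 1
        self.parent = np.full(total, -1, dtype=int)
        self.left = np.full(total, -1, dtype=int)
        self.right = np.full(total, -1, dtype=int)
        self.age = np.zeros(total)
        self.blen = np.zeros(total)
        self.tipset = np.zeros(total, dtype=object)  # python ints (bitmasks)
        self.root = total - 1

    def recompute_tipsets(self) -> None:
        for node in self.postorder():
            if node < self.n:
                self.tipset[node] = 1 << node
            else:
                self.tipset[node] = (
                    self.tipset[self.left[node]] | self.tipset[self.right[node]]
                )

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < self.n:
                order.append(node)
            elif expanded:
                order.append(node)
            else:
                stack.append((node, True))
                stack.append((self.right[node], False))
                stack.append((self.left[node], False))
        return order

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for v in range(2 * self.n - 1):
            if self.left[v] >= 0:
                out[v] = [self.left[v], self.right[v]]
        return out

    def branch_lengths(self, clock: str, clock_rate: float,
                       branch_rates: np.ndarray | None) -> np.ndarray:
        if clock == "none":
            return self.blen.copy()
        b = np.zeros(2 * self.n - 1)
        has_parent = self.parent >= 0
        b[has_parent] = (
            self.age[self.parent[has_parent]] - self.age[has_parent]
        ) * clock_rate
        if clock == "relaxed_ulnorm" and branch_rates is not None:
            b[has_parent] *= branch_rates[has_parent]
        return b

    def to_phylo(self, labels: list[str], clock: str, clock_rate: float,
                 branch_rates: np.ndarray | None) -> PhyloTree:
        blens = self.branch_lengths(clock, clock_rate, branch_rates)
        nodes: dict[int, TreeNode] = {}
        for v in self.postorder():
            if v < self.n:
                nodes[v] = TreeNode(label=labels[v], length=float(blens[v]),
                                    age=float(self.age[v]))
            else:
                node = TreeNode(length=float(blens[v]), age=float(self.age[v]))
                node.add_child(nodes[self.left[v]])
                node.add_child(nodes[self.right[v]])
                nodes[v] = node
        return PhyloTree(nodes[self.root])


def _random_constrained_topology(
    n: int, masks: list[int], rng: np.random.Generator, state: TreeState
) -> None:
    """Random rooted topology containing every constraint mask as a clade."""
    next_internal = [n]

    def build(tip_ids: list[int], inner_masks: list[int]) -> int:
        if len(tip_ids) == 1:
            return tip_ids[0]
        # maximal constraint masks inside this group act as indivisible units
        maximal = []
        for mk in inner_masks:
            if not any(mk != other and (mk & other) == mk for other in inner_masks):
                maximal.append(mk)
        units: list[tuple[int, ...]] = []
        used = 0
        for mk in maximal:
            members = [t for t in tip_ids if (1 << t) & mk]
            units.append(tuple(members))
            used |= mk
        for t in tip_ids:
            if not (1 << t) & used:
                units.append((t,))
        # random sequential joins of units
        roots: list[int] = []
        for u in units:
            if len(u) == 1:
                roots.append(u[0])
            else:
                mask_u = 0
                for t in u:
                    mask_u |= 1 << t
                sub = [mk for mk in inner_masks if (mk & mask_u) == mk and mk != mask_u]
                roots.append(build(list(u), sub))
        while len(roots) > 1:
            i, j = sorted(rng.choice(len(roots), size=2, replace=False))
            b = roots.pop(j)
            a = roots.pop(i)
            v = next_internal[0]
            next_internal[0] += 1
            state.left[v], state.right[v] = a, b
            state.parent[a] = state.parent[b] = v
            roots.append(v)
        return roots[0]

    top = build(list(range(n)), [m for m in masks if bin(m).count("1") < n])
    # the final top-level join is the last id allocated, i.e. the fixed root
    assert top == 2 * n - 2
    state.parent[top] = -1


class _Sampler:
    """One Metropolis-Hastings chain; likelihood may be raised to a power
    beta for stepping-stone estimation."""

    def __init__(self, m: CharacterMatrix, model: SubstModel, cfg: MCMCConfig,
                 rng: np.random.Generator | None = None) -> None:
        if m.n_taxa < 4:
            raise ValueError("MCMC needs at least 4 taxa")
        taxa = set(m.taxa)
        constraints = tuple(cfg.constraints)
        if cfg.outgroup is not None:
            if cfg.outgroup not in taxa:
                raise ValueError(f"outgroup {cfg.outgroup!r} not in matrix")
            ingroup = frozenset(taxa - {cfg.outgroup})
            if len(ingroup) >= 2:
                constraints = constraints + (Constraint(ingroup),)
        _check_compatible(constraints, taxa)
        self.cfg = cfg
        self.model = model
        self.labels = list(m.taxa)
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        n = m.n_taxa
        self.n = n
        tip_of = {t: i for i, t in enumerate(self.labels)}
        self.masks = []
        for c in constraints:
            mk = 0
            for t in c.taxa:
                mk |= 1 << tip_of[t]
            self.masks.append(mk)

        data = m.states
        if data.shape[1]:
            self.patterns, self.counts = np.unique(data, axis=1, return_counts=True)
        else:
            self.patterns = np.zeros((n, 0), dtype=np.int8)
            self.counts = np.zeros(0)
        self.n_chars = data.shape[1]
        # the two constant patterns ride along for the ascertainment term
        self.all_patterns = np.concatenate(
            [
                self.patterns,
                np.zeros((n, 1), dtype=np.int8),
                np.ones((n, 1), dtype=np.int8),
            ],
            axis=1,
        )
        self.tip_row = np.concatenate(
            [np.arange(n), np.full(n - 1, -1)]
        )

        # state
        self.tree = TreeState(n)
        _random_constrained_topology(n, self.masks, self.rng, self.tree)
        self._init_ages()
        self.pi1 = model.pi1
        self.alpha = model.alpha
        self.clock_rate = 0.5
        self.sigma = 0.1
        self.branch_rates = np.ones(2 * n - 1)
        if cfg.clock == "none":
            self.tree.blen[:] = 0.1
            self.tree.blen[self.tree.root] = 0.0
        self.tree.recompute_tipsets()
        self._rates_cache: tuple[float, np.ndarray] | None = None
        self._order_cache: np.ndarray | None = None
        self.log_like = self._log_likelihood()
        self.log_pri = self._log_prior()
        self.weights = dict(_DEFAULT_WEIGHTS)
        if cfg.clock == "relaxed_ulnorm":
            self.weights["branch_rate"] = 2.0
            self.weights["sigma_scale"] = 0.5
        if cfg.clock == "none":
            self.weights["blen_scale"] = 3.0
            self.weights["age_slide"] = 0.0
            self.weights["clock_scale"] = 0.0
        self.weights.update(cfg.proposal_weights)
        kinds = [k for k, w in self.weights.items() if w > 0]
        probs = np.array([self.weights[k] for k in kinds])
        self.kinds = kinds
        self.kind_probs = probs / probs.sum()
        self.n_proposed = {k: 0 for k in kinds}
        self.n_accepted = {k: 0 for k in kinds}

    # -- initialization ----------------------------------------------------

    def _init_ages(self) -> None:
        t = self.tree
        t.age[:self.n] = 0.0
        t.age[t.root] = 1.0
        order = t.postorder()
        for v in reversed(order):  # preorder
            if v >= self.n and v != t.root:
                t.age[v] = t.age[t.parent[v]] * self.rng.uniform(0.3, 0.9)
        # ages assigned top-down are automatically valid (children get
        # fractions of the parent's age afterwards)
        for v in order:
            if v >= self.n and v != t.root:
                hi = t.age[t.parent[v]]
                lo = max(t.age[t.left[v]], t.age[t.right[v]])
                if not lo < t.age[v] < hi:
                    t.age[v] = lo + 0.5 * (hi - lo)

    # -- densities ----------------------------------------------------------

    def _gamma_rates(self) -> np.ndarray:
        if self._rates_cache is None or self._rates_cache[0] != self.alpha:
            self._rates_cache = (
                self.alpha, discrete_gamma_rates(self.alpha, self.model.n_cat)
            )
        return self._rates_cache[1]

    def _internal_postorder(self) -> np.ndarray:
        if self._order_cache is None:
            self._order_cache = np.array(
                [v for v in self.tree.postorder() if v >= self.n],
                dtype=np.int64,
            )
        return self._order_cache

    def _log_likelihood(self) -> float:
        if self.n_chars == 0:
            return 0.0
        t = self.tree
        blens = t.branch_lengths(self.cfg.clock, self.clock_rate,
                                 self.branch_rates)
        rates = self._gamma_rates()
        site = prune_site_likelihoods_binary(
            self._internal_postorder(), t.left, t.right, blens,
            self.tip_row, self.all_patterns, self.pi1, rates,
        )
        lc = site[-2:]
        site = site[:-2]
        with np.errstate(divide="ignore"):
            logs = np.log(site)
        if not np.all(np.isfinite(logs)):
            return -np.inf
        total = float(np.dot(self.counts, logs))
        if self.model.ascertainment == "variable":
            p_var = 1.0 - lc.sum()
            if p_var <= 0:
                return -np.inf
            total -= self.n_chars * math.log(p_var)
        return total

    def _log_prior(self) -> float:
        t = self.tree
        n = self.n
        root = t.root
        lp = 0.0
        nonroot_internal = np.arange(n, 2 * n - 1) != root
        nonroot = np.arange(2 * n - 1) != root
        if self.cfg.clock in ("strict", "relaxed_ulnorm"):
            parents = t.parent[n:2 * n - 1][nonroot_internal]
            lp -= float(np.sum(np.log(t.age[parents])))
            # clock rate ~ Gamma(2, 2)
            r = self.clock_rate
            lp += math.log(4.0) + math.log(r) - 2.0 * r
        if self.cfg.clock == "relaxed_ulnorm":
            s = self.sigma
            lp += math.log(3.0) - 3.0 * s
            x = self.branch_rates[nonroot]
            lx = np.log(x)
            lp += float(np.sum(
                -lx - math.log(s * math.sqrt(2 * math.pi))
                - (lx + 0.5 * s * s) ** 2 / (2 * s * s)
            ))
        if self.cfg.clock == "none":
            lam = 5.0
            lp += float(np.sum(
                math.log(lam) - lam * t.blen[nonroot]
            ))
        lp -= self.alpha  # alpha ~ Exp(1); pi1 ~ U(0,1) contributes 0
        return lp

    # -- proposals -----------------------------------------------------------

    def _propose_nni(self) -> tuple[float, callable] | None:
        t = self.tree
        rng = self.rng
        internals = [v for v in range(self.n, 2 * self.n - 1) if v != t.root]
        if not internals:
            return None
        v = internals[rng.integers(len(internals))]
        u = t.parent[v]
        s = t.right[u] if t.left[u] == v else t.left[u]
        c = t.left[v] if rng.random() < 0.5 else t.right[v]
        if self.cfg.clock != "none" and t.age[s] >= t.age[v]:
            return None  # invalid height ordering; prior zero
        old_tipset = t.tipset[v]
        new_tipset = (old_tipset & ~t.tipset[c]) | t.tipset[s]
        for mk in self.masks:
            if old_tipset == mk and new_tipset != mk:
                return None  # breaks a constraint clade
        # apply
        def do_swap():
            if t.left[u] == s:
                t.left[u] = c
            else:
                t.right[u] = c
            if t.left[v] == c:
                t.left[v] = s
            else:
                t.right[v] = s
            t.parent[c] = u
            t.parent[s] = v
            t.tipset[v] = (t.tipset[v] & ~t.tipset[c]) | t.tipset[s]
            self._order_cache = None

        def undo():
            if t.left[u] == c:
                t.left[u] = s
            else:
                t.right[u] = s
            if t.left[v] == s:
                t.left[v] = c
            else:
                t.right[v] = c
            t.parent[s] = u
            t.parent[c] = v
            t.tipset[v] = old_tipset
            self._order_cache = None

        do_swap()
        return 0.0, undo

    def _propose_age_slide(self) -> tuple[float, callable] | None:
        t = self.tree
        internals = [v for v in range(self.n, 2 * self.n - 1) if v != t.root]
        if not internals:
            return None
        v = internals[self.rng.integers(len(internals))]
        lo = max(t.age[t.left[v]], t.age[t.right[v]])
        hi = t.age[t.parent[v]]
        old = t.age[v]
        t.age[v] = self.rng.uniform(lo, hi)

        def undo():
            t.age[v] = old

        return 0.0, undo

    def _scale(self, get, set_) -> tuple[float, callable]:
        old = get()
        factor = math.exp(1.0 * (self.rng.random() - 0.5))
        set_(old * factor)

        def undo():
            set_(old)

        return math.log(factor), undo

    def _propose_param(self, kind: str) -> tuple[float, callable] | None:
        if kind == "clock_scale":
            return self._scale(
                lambda: self.clock_rate,
                lambda x: setattr(self, "clock_rate", x),
            )
        if kind == "alpha_scale":
            return self._scale(
                lambda: self.alpha, lambda x: setattr(self, "alpha", x)
            )
        if kind == "sigma_scale":
            return self._scale(
                lambda: self.sigma, lambda x: setattr(self, "sigma", x)
            )
        if kind == "pi1_slide":
            old = self.pi1
            x = old + self.rng.uniform(-0.1, 0.1)
            while not 0.0 < x < 1.0:
                if x <= 0.0:
                    x = -x
                if x >= 1.0:
                    x = 2.0 - x
                if x == 0.0:
                    x = 1e-9
            self.pi1 = x

            def undo():
                self.pi1 = old

            return 0.0, undo
        if kind == "branch_rate":
            t = self.tree
            v = self.rng.integers(2 * self.n - 1)
            while v == t.root:
                v = self.rng.integers(2 * self.n - 1)
            old = self.branch_rates[v]
            factor = math.exp(0.8 * (self.rng.random() - 0.5))
            self.branch_rates[v] = old * factor

            def undo():
                self.branch_rates[v] = old

            return math.log(factor), undo
        if kind == "blen_scale":
            t = self.tree
            v = self.rng.integers(2 * self.n - 1)
            while v == t.root:
                v = self.rng.integers(2 * self.n - 1)
            old = t.blen[v]
            factor = math.exp(1.0 * (self.rng.random() - 0.5))
            t.blen[v] = old * factor

            def undo():
                t.blen[v] = old

            return math.log(factor), undo
        raise ValueError(kind)

    # -- chain ---------------------------------------------------------------

    def step(self, beta: float = 1.0) -> None:
        kind = self.kinds[
            self.rng.choice(len(self.kinds), p=self.kind_probs)
        ]
        self.n_proposed[kind] += 1
        if kind == "nni":
            prop = self._propose_nni()
        elif kind == "age_slide":
            prop = self._propose_age_slide()
        else:
            prop = self._propose_param(kind)
        if prop is None:
            return
        log_hastings, undo = prop
        try:
            new_pri = self._log_prior()
            new_like = self._log_likelihood()
        except (ValueError, FloatingPointError):
            undo()
            return
        if not np.isfinite(new_pri) or not np.isfinite(new_like):
            undo()
            return
        log_ratio = (
            beta * (new_like - self.log_like)
            + (new_pri - self.log_pri)
            + log_hastings
        )
        if math.log(self.rng.random()) < log_ratio:
            self.log_like = new_like
            self.log_pri = new_pri
            self.n_accepted[kind] += 1
        else:
            undo()

    def snapshot_tree(self) -> PhyloTree:
        return self.tree.to_phylo(
            self.labels, self.cfg.clock, self.clock_rate, self.branch_rates
        )


def run_mcmc(m: CharacterMatrix, model: SubstModel, cfg: MCMCConfig
             ) -> PosteriorTrace:
    """Run one MCMC chain and return its posterior trace.

    Sampling starts at generation 0 (the initial state) and repeats every
    ``sample_every`` generations; every sampled tree satisfies every
    constraint (violating proposals are rejected). Deterministic under a
    fixed seed.
    """
    sampler = _Sampler(m, model, cfg)
    trees: list[PhyloTree] = []
    gens: list[int] = []
    lls: list[float] = []
    lps: list[float] = []
    pi1s: list[float] = []
    alphas: list[float] = []
    rates: list[float] = []

    def record(g: int) -> None:
        trees.append(sampler.snapshot_tree())
        gens.append(g)
        lls.append(sampler.log_like)
        lps.append(sampler.log_pri)
        pi1s.append(sampler.pi1)
        alphas.append(sampler.alpha)
        rates.append(sampler.clock_rate)

    record(0)
    for g in range(1, cfg.n_generations + 1):
        sampler.step()
        if g % cfg.sample_every == 0:
            record(g)
    acc = {
        k: (sampler.n_accepted[k] / sampler.n_proposed[k]
            if sampler.n_proposed[k] else 0.0)
        for k in sampler.kinds
    }
    return PosteriorTrace(
        trees=trees,
        generations=np.array(gens),
        log_likelihood=np.array(lls),
        log_prior=np.array(lps),
        pi1=np.array(pi1s),
        alpha=np.array(alphas),
        clock_rate=np.array(rates),
        seed=cfg.seed,
        config=cfg,
        acceptance_rates=acc,
    )
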