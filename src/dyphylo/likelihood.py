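"""Felsenstein-pruning likelihood for binary characters on rooted trees.

The substitution process is the two-state general reversible model with
stationary frequencies (pi0, pi1), rate-normalized so one unit of branch
length equals one expected substitution per character at stationarity
(mu = 1 / (2 pi0 pi1)). Among-character rate variation uses a discrete gamma
with equal-probability categories represented by their means. Because the
analyzed matrices typically have constant characters removed, the likelihood
can condition on characters being variable (ascertainment correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaincinv

from .charmatrix import MISSING, CharacterMatrix
from .trees import PhyloTree

__all__ = [
    "SubstModel",
    "transition_matrix",
    "discrete_gamma_rates",
    "log_likelihood",
]


@dataclass(frozen=True)
class SubstModel:
    """Two-state reversible model with gamma-distributed rate variation.

    ``ascertainment="variable"`` conditions each character's likelihood on the
    character being variable across the tips, the appropriate correction when
    constant characters were filtered from the matrix. Use ``"none"`` for data
    that retains constant characters (e.g. raw simulation output).
    """

    pi1: float
    alpha: float
    n_cat: int = 4
    ascertainment: str = "variable"

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError("pi1 must lie strictly inside (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_cat < 1:
            raise ValueError("n_cat must be at least 1")
        if self.ascertainment not in ("none", "variable"):
            raise ValueError('ascertainment must be "none" or "variable"')


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    """2x2 transition probability matrix over branch length ``t``.

    P(0->1) = pi1 (1 - exp(-mu t r)) and symmetrically for P(1->0), with
    mu = 1/(2 pi0 pi1) so the expected substitution rate at stationarity is 1.
    """
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    pi1 = model.pi1
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)
    decay = np.exp(-mu * t * rate)
    p01 = pi1 * (1.0 - decay)
    p10 = pi0 * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def discrete_gamma_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability bins of Gamma(alpha, alpha).

    The returned multipliers average exactly 1. A single category collapses to
    the constant-rate model.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_cat < 1:
        raise ValueError("n_cat must be at least 1")
    if n_cat == 1:
        return np.array([1.0])
    # Bin boundaries are quantiles of the standard Gamma(alpha); the bin mean
    # of a mean-1 gamma follows from the incomplete-gamma recurrence.
    probs = np.arange(1, n_cat) / n_cat
    cuts = gammaincinv(alpha, probs)
    upper = np.concatenate([gammainc(alpha + 1.0, cuts), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, cuts)])
    rates = n_cat * (upper - lower)
    return rates / rates.mean()  # remove residual rounding, keep mean exactly 1


# ---------------------------------------------------------------------------
# pruning core (shared with the MCMC sampler)
# ---------------------------------------------------------------------------

def _edge_transition_stack(blens: np.ndarray, pi1: float, rates: np.ndarray
                           ) -> np.ndarray:
    """(n_edges, n_cat, 2, 2) transition matrices for every edge x category."""
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)
    decay = np.exp(-mu * np.outer(blens, rates))  # (E, C)
    p01 = pi1 * (1.0 - decay)
    p10 = pi0 * (1.0 - decay)
    P = np.empty(decay.shape + (2, 2))
    P[..., 0, 0] = 1.0 - p01
    P[..., 0, 1] = p01
    P[..., 1, 0] = p10
    P[..., 1, 1] = 1.0 - p10
    return P


def prune_site_likelihoods(
    order: list[int],
    children: list[list[int]],
    blens: np.ndarray,
    tip_row: np.ndarray,
    tipdata: np.ndarray,
    pi1: float,
    rates: np.ndarray,
) -> np.ndarray:
    """Per-pattern likelihoods, averaged over rate categories.

    Parameters
    ----------
    order
        Node ids in postorder (root last).
    children
        For each node id, its child ids (empty for tips).
    blens
        Branch length above each node (root entry ignored).
    tip_row
        For each node id, its row in ``tipdata`` (-1 for internal nodes).
    tipdata
        ``(n_tips, n_patterns)`` int8 over {0, 1, MISSING}.
    """
    n_nodes = len(children)
    ncat = len(rates)
    npat = tipdata.shape[1]
    if npat == 0:
        return np.empty(0)
    P = _edge_transition_stack(blens, pi1, rates)  # (nodes, cat, 2, 2)
    partial = [None] * n_nodes
    for node in order:
        kids = children[node]
        if not kids:
            row = tipdata[tip_row[node]]
            leaf = np.zeros((npat, 2))
            leaf[row == 0, 0] = 1.0
            leaf[row == 1, 1] = 1.0
            leaf[row == MISSING] = 1.0
            partial[node] = np.broadcast_to(leaf, (ncat, npat, 2))
        else:
            acc = None
            for c in kids:
                msg = np.einsum("cij,cpj->cpi", P[c], partial[c])
                acc = msg if acc is None else acc * msg
                partial[c] = None  # free
            partial[node] = acc
    root = order[-1]
    pi = np.array([1.0 - pi1, pi1])
    site = np.einsum("cps,s->p", partial[root], pi) / ncat
    return site


try:  # compiled fast path for binary trees (used by the MCMC sampler)
    from numba import njit

    @njit(cache=False)
    def _prune_binary_kernel(order_internal, left, right, blens, tip_row,
                             tipdata, pi1, rates):  # pragma: no cover - compiled
        n_nodes = left.shape[0]
        ncat = rates.shape[0]
        npat = tipdata.shape[1]
        pi0 = 1.0 - pi1
        mu = 1.0 / (2.0 * pi0 * pi1)
        partial = np.empty((n_nodes, ncat, npat, 2))
        for v in range(n_nodes):
            r = tip_row[v]
            if r >= 0:
                for p in range(npat):
                    s = tipdata[r, p]
                    if s == 0:
                        a0, a1 = 1.0, 0.0
                    elif s == 1:
                        a0, a1 = 0.0, 1.0
                    else:
                        a0, a1 = 1.0, 1.0
                    for c in range(ncat):
                        partial[v, c, p, 0] = a0
                        partial[v, c, p, 1] = a1
        for idx in range(order_internal.shape[0]):
            v = order_internal[idx]
            a = left[v]
            b = right[v]
            for c in range(ncat):
                ea = np.exp(-mu * blens[a] * rates[c])
                eb = np.exp(-mu * blens[b] * rates[c])
                a01 = pi1 * (1.0 - ea)
                a10 = pi0 * (1.0 - ea)
                b01 = pi1 * (1.0 - eb)
                b10 = pi0 * (1.0 - eb)
                for p in range(npat):
                    la0 = partial[a, c, p, 0]
                    la1 = partial[a, c, p, 1]
                    lb0 = partial[b, c, p, 0]
                    lb1 = partial[b, c, p, 1]
                    ma0 = (1.0 - a01) * la0 + a01 * la1
                    ma1 = a10 * la0 + (1.0 - a10) * la1
                    mb0 = (1.0 - b01) * lb0 + b01 * lb1
                    mb1 = b10 * lb0 + (1.0 - b10) * lb1
                    partial[v, c, p, 0] = ma0 * mb0
                    partial[v, c, p, 1] = ma1 * mb1
        root = order_internal[order_internal.shape[0] - 1]
        site = np.zeros(npat)
        for c in range(ncat):
            for p in range(npat):
                site[p] += (
                    pi0 * partial[root, c, p, 0] + pi1 * partial[root, c, p, 1]
                )
        return site / ncat

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _prune_binary_kernel = None
    HAVE_NUMBA = False


def prune_site_likelihoods_binary(
    order_internal: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    blens: np.ndarray,
    tip_row: np.ndarray,
    tipdata: np.ndarray,
    pi1: float,
    rates: np.ndarray,
) -> np.ndarray:
    """Per-pattern likelihoods on an array-encoded binary tree.

    Same contract as :func:`prune_site_likelihoods` but restricted to strictly
    binary topologies, with a compiled kernel when available.
    """
    if tipdata.shape[1] == 0:
        return np.empty(0)
    if _prune_binary_kernel is not None:
        return _prune_binary_kernel(
            np.asarray(order_internal, dtype=np.int64),
            np.asarray(left, dtype=np.int64),
            np.asarray(right, dtype=np.int64),
            np.asarray(blens, dtype=np.float64),
            np.asarray(tip_row, dtype=np.int64),
            np.asarray(tipdata, dtype=np.int8),
            float(pi1),
            np.asarray(rates, dtype=np.float64),
        )
    order = [int(v) for v in order_internal]
    children = [[] for _ in range(len(left))]
    full_order: list[int] = []
    for v in order:
        children[v] = [int(left[v]), int(right[v])]
    for v in range(len(left)):
        if not children[v]:
            full_order.append(v)
    full_order.extend(order)
    return prune_site_likelihoods(
        full_order, children, blens, tip_row, tipdata, pi1, rates
    )


def _flatten(tree: PhyloTree) -> tuple[list[int], list[list[int]], np.ndarray,
                                       np.ndarray, list[str]]:
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = [[index[id(c)] for c in n.children] for n in nodes]
    blens = np.array([n.length for n in nodes], dtype=float)
    tip_row = np.full(len(nodes), -1, dtype=int)
    tip_labels: list[str] = []
    for i, n in enumerate(nodes):
        if n.is_leaf:
            tip_row[i] = len(tip_labels)
            tip_labels.append(n.label)
    order = list(range(len(nodes)))
    return order, children, blens, tip_row, tip_labels


def log_likelihood(tree: PhyloTree, m: CharacterMatrix, model: SubstModel) -> float:
    """Log-probability of the character matrix on the tree under the model.

    Missing cells contribute a flat partial likelihood; characters are
    conditionally independent given the tree, so patterns are compressed
    before pruning. With ``ascertainment="variable"`` each character's
    likelihood is divided by the probability of being variable,
    1 - P(all zeros) - P(all ones).
    """
    tips = set(tree.leaf_labels())
    taxa = set(m.taxa)
    if tips != taxa:
        only_tree = sorted(tips - taxa)
        only_mat = sorted(taxa - tips)
        raise ValueError(
            f"tree tips and matrix taxa differ; only in tree: {only_tree}, "
            f"only in matrix: {only_mat}"
        )
    order, children, blens, tip_row, tip_labels = _flatten(tree)
    if not np.all(np.isfinite(blens)):
        raise ValueError("branch lengths must be finite")
    row_of = {t: i for i, t in enumerate(m.taxa)}
    data = m.states[[row_of[t] for t in tip_labels], :]
    if data.shape[1] == 0:
        return 0.0
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    rates = discrete_gamma_rates(model.alpha, model.n_cat)
    site = prune_site_likelihoods(
        order, children, blens, tip_row, patterns, model.pi1, rates
    )
    logs = np.log(site)
    total = float(np.dot(counts, logs))
    if model.ascertainment == "variable":
        ntips = len(tip_labels)
        const = np.concatenate(
            [np.zeros((ntips, 1), dtype=np.int8), np.ones((ntips, 1), dtype=np.int8)],
            axis=1,
        )
        lc = prune_site_likelihoods(
            order, children, blens, tip_row, const, model.pi1, rates
        )
        p_variable = 1.0 - lc.sum()
        if p_variable <= 0:
            raise ValueError("ascertainment correction degenerate: P(variable) <= 0")
        total -= data.shape[1] * np.log(p_variable)
    return total
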