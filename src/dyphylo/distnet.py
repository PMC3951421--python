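"""Distances, NeighborNet split networks, and treelikeness statistics.

Pairwise dissimilarities are uncorrected proportion distances with pairwise
deletion of missing cells. Treelikeness is measured per quartet {i,j,k,l} from
the three pairwise-distance sums m1 >= m2 >= m3:

* delta score: (m1 - m2) / (m1 - m3), 0 on additive (treelike) distances,
  1 for a maximally conflicting "box" quartet;
* Q-residual: (m1 - m2)^2 after rescaling the matrix so the mean off-diagonal
  distance is 1.

NeighborNet agglomerates taxa into a circular ordering (average-linkage
neighbor-joining selection with the Bryant-Moulton reduction), then fits
non-negative least-squares weights to every interval split of the ordering;
splits with negligible weight are dropped. A weighted circular split system
is drawable as a planar splits graph, built here as the dual of the
arrangement of one chord per split across the taxon circle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import nnls
from shapely.geometry import LineString, Point
from shapely.ops import polygonize, unary_union

from .charmatrix import MISSING, CharacterMatrix

__all__ = [
    "DistanceMatrix",
    "SplitSystem",
    "TreelikenessReport",
    "distance_matrix",
    "delta_scores",
    "q_residuals",
    "treelikeness",
    "neighbor_net",
    "splits_to_graph",
    "write_splits_nexus",
    "write_distances_nexus",
]

#: NNLS weights below this are treated as exactly zero (reproducible sparsity).
WEIGHT_EPS = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with per-pair comparable counts."""

    taxa: tuple[str, ...]
    d: np.ndarray
    n_comparable: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "taxa", tuple(self.taxa))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class SplitSystem:
    """Weighted splits of a taxon set, optionally with a circular ordering.

    Each split is stored as the side not containing the first taxon of
    ``taxa`` (splits are identified with their complements).
    """

    taxa: tuple[str, ...]
    splits: tuple[frozenset[str], ...]
    weights: np.ndarray
    ordering: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        full = frozenset(taxa)
        canon = []
        for s in self.splits:
            s = frozenset(s)
            if not s or s == full:
                raise ValueError("split sides must be proper non-empty subsets")
            if not s <= full:
                raise ValueError(f"split {sorted(s)} contains unknown taxa")
            if taxa[0] in s:
                s = full - s
            canon.append(s)
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate splits")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(canon),):
            raise ValueError("one weight per split required")
        if np.any(w < 0):
            raise ValueError("split weights must be non-negative")
        if self.ordering is not None and set(self.ordering) != set(taxa):
            raise ValueError("ordering must be a permutation of taxa")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "splits", tuple(canon))
        object.__setattr__(self, "weights", w)
        if self.ordering is not None:
            object.__setattr__(self, "ordering", tuple(self.ordering))

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def induced_distances(self) -> DistanceMatrix:
        """Pairwise distances implied by the weighted splits."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        d = np.zeros((n, n))
        for s, w in zip(self.splits, self.weights):
            inside = np.zeros(n, dtype=bool)
            inside[[idx[t] for t in s]] = True
            sep = inside[:, None] ^ inside[None, :]
            d += w * sep
        return DistanceMatrix(self.taxa, d)

    def nontrivial(self) -> "SplitSystem":
        keep = [i for i, s in enumerate(self.splits)
                if 1 < len(s) < len(self.taxa) - 1]
        return SplitSystem(
            self.taxa,
            tuple(self.splits[i] for i in keep),
            self.weights[keep],
            self.ordering,
        )


@dataclass(frozen=True)
class TreelikenessReport:
    """Average and per-taxon treelikeness statistics; fields a given scorer
    does not compute are left as None."""

    avg_delta: float | None = None
    avg_q_residual: float | None = None
    per_taxon_delta: dict[str, float] | None = None
    per_taxon_q: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(m: CharacterMatrix) -> DistanceMatrix:
    """Proportion of differing characters among jointly observed ones."""
    if m.n_taxa < 2:
        raise ValueError("need at least two taxa")
    obs = (m.states != MISSING).astype(float)
    a0 = ((m.states == 0)).astype(float)
    a1 = ((m.states == 1)).astype(float)
    comparable = obs @ obs.T
    mism = a0 @ a1.T + a1 @ a0.T
    zero_pairs = np.argwhere(comparable == 0)
    for i, j in zero_pairs:
        if i < j:
            raise ValueError(
                f"taxa {m.taxa[i]!r} and {m.taxa[j]!r} share no observed characters"
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, mism / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(m.taxa, d, comparable.astype(int))


# ---------------------------------------------------------------------------
# quartet statistics
# ---------------------------------------------------------------------------

def _quartet_sums(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All quartets (C(n,4) x 4 index array) and their sorted sums (desc)."""
    n = d.shape[0]
    quart = np.array(list(itertools.combinations(range(n), 4)), dtype=int)
    i, j, k, l = quart.T
    sums = np.stack(
        [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]], axis=1
    )
    sums = -np.sort(-sums, axis=1)  # m1 >= m2 >= m3
    return quart, sums


def _per_taxon_means(
    quart: np.ndarray, values: np.ndarray, n: int
) -> np.ndarray:
    totals = np.zeros(n)
    counts = np.zeros(n)
    for col in range(4):
        np.add.at(totals, quart[:, col], values)
        np.add.at(counts, quart[:, col], 1.0)
    return totals / counts


def delta_scores(dm: DistanceMatrix) -> TreelikenessReport:
    """Average and per-taxon delta scores over all C(n,4) quartets.

    Quartets with all three sums equal (m1 == m3) score 0 by convention.
    Scale-invariant and invariant under taxon relabeling.
    """
    if dm.n_taxa < 4:
        raise ValueError("delta scores require at least 4 taxa")
    quart, sums = _quartet_sums(dm.d)
    span = sums[:, 0] - sums[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(span > 0, (sums[:, 0] - sums[:, 1]) / span, 0.0)
    per = _per_taxon_means(quart, delta, dm.n_taxa)
    return TreelikenessReport(
        avg_delta=float(delta.mean()),
        per_taxon_delta={t: float(v) for t, v in zip(dm.taxa, per)},
    )


def q_residuals(dm: DistanceMatrix) -> TreelikenessReport:
    """Average and per-taxon Q-residuals.

    Distances are first rescaled so the mean off-diagonal distance is 1; each
    quartet contributes (m1 - m2)^2 on the rescaled distances.
    """
    if dm.n_taxa < 4:
        raise ValueError("Q-residuals require at least 4 taxa")
    n = dm.n_taxa
    off = dm.d[np.triu_indices(n, k=1)]
    mean = off.mean()
    if mean == 0:
        raise ValueError("all distances zero; Q-residual rescaling undefined")
    quart, sums = _quartet_sums(dm.d / mean)
    q = (sums[:, 0] - sums[:, 1]) ** 2
    per = _per_taxon_means(quart, q, n)
    return TreelikenessReport(
        avg_q_residual=float(q.mean()),
        per_taxon_q={t: float(v) for t, v in zip(dm.taxa, per)},
    )


def treelikeness(dm: DistanceMatrix) -> TreelikenessReport:
    """Both statistics in one report."""
    a = delta_scores(dm)
    b = q_residuals(dm)
    return TreelikenessReport(
        avg_delta=a.avg_delta,
        avg_q_residual=b.avg_q_residual,
        per_taxon_delta=a.per_taxon_delta,
        per_taxon_q=b.per_taxon_q,
    )


# ---------------------------------------------------------------------------
# NeighborNet
# ---------------------------------------------------------------------------

def _argmin_pair(Q: np.ndarray) -> tuple[int, int]:
    """Lexicographically first (i < j) minimizer of a symmetric criterion."""
    m = Q.shape[0]
    iu = np.triu_indices(m, k=1)
    vals = Q[iu]
    best = int(np.argmin(vals))
    return int(iu[0][best]), int(iu[1][best])


def _nn_reduce(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Replace the active 3-chain x-y-z by two combined nodes stored at x, z."""
    u = (2.0 / 3.0) * d[x, :] + d[y, :] / 3.0
    v = (2.0 / 3.0) * d[z, :] + d[y, :] / 3.0
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3.0
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def neighbor_net_ordering(dm: DistanceMatrix) -> tuple[str, ...]:
    """Circular taxon ordering by NeighborNet agglomeration.

    Clusters (paths with one or two active endpoint nodes) are merged by the
    neighbor-joining criterion on average-linkage cluster distances; endpoint
    selection uses the same criterion at node level; merged 3-chains are
    reduced to two combined nodes. Ties break toward the lowest index pair.
    """
    n = dm.n_taxa
    if n <= 3:
        return dm.taxa
    d = dm.d.astype(float).copy()
    CL: list[list[int]] = [[i] for i in range(n)]  # active node ids per cluster
    ords: list[list[int]] = [[i] for i in range(n)]  # full taxon paths
    DM = d.copy()  # cluster-level distances

    def update_DM(e1: int) -> None:
        for i in range(len(CL)):
            DM[i, e1] = DM[e1, i] = d[np.ix_(CL[i], CL[e1])].mean()
        DM[e1, e1] = 0.0

    while len(CL) > 1:
        m = len(CL)
        if m > 2:
            r = DM[:m, :m].sum(axis=1) / (m - 2)
            Q = DM[:m, :m] - r[:, None] - r[None, :]
            e1, e2 = _argmin_pair(Q)
        else:
            e1, e2 = 0, 1
        c1, c2 = CL[e1], CL[e2]
        n1, n2 = len(c1), len(c2)
        if n1 == 1 and n2 == 1:
            new_cl = c1 + c2
            new_ord = ords[e1] + ords[e2]
        else:
            nodes = c1 + c2
            rest = [CL[k] for k in range(m) if k not in (e1, e2)]
            ltmp = len(nodes) + len(rest)
            r2 = np.zeros(len(nodes))
            for a, x in enumerate(nodes):
                s = sum(d[x, y] for b, y in enumerate(nodes) if b != a)
                s += sum(d[x, grp].mean() for grp in rest)
                r2[a] = s
            if ltmp > 2:
                r2 = r2 / (ltmp - 2)
            D3 = d[np.ix_(nodes, nodes)] - r2[:, None] - r2[None, :]
            block = D3[:n1, n1:]
            flat = int(np.argmin(block))
            i, j = divmod(flat, n2)
            if n1 == 2 and n2 == 1:
                if i == 1:
                    new_cl = [c1[0], c2[0]]
                    new_ord = ords[e1] + ords[e2]
                    _nn_reduce(d, c1[0], c1[1], c2[0])
                else:
                    new_cl = [c2[0], c1[1]]
                    new_ord = ords[e2] + ords[e1]
                    _nn_reduce(d, c2[0], c1[0], c1[1])
            elif n1 == 1 and n2 == 2:
                if j == 0:
                    new_cl = [c1[0], c2[1]]
                    new_ord = ords[e1] + ords[e2]
                    _nn_reduce(d, c1[0], c2[0], c2[1])
                else:
                    new_cl = [c2[0], c1[0]]
                    new_ord = ords[e2] + ords[e1]
                    _nn_reduce(d, c2[0], c2[1], c1[0])
            else:  # 2 and 2
                if i == 0 and j == 0:
                    new_cl = [c1[1], c2[1]]
                    new_ord = ords[e1][::-1] + ords[e2]
                    _nn_reduce(d, c1[1], c1[0], c2[0])
                    _nn_reduce(d, c1[1], c2[0], c2[1])
                elif i == 1 and j == 0:
                    new_cl = [c1[0], c2[1]]
                    new_ord = ords[e1] + ords[e2]
                    _nn_reduce(d, c1[0], c1[1], c2[0])
                    _nn_reduce(d, c1[0], c2[0], c2[1])
                elif i == 0 and j == 1:
                    new_cl = [c1[1], c2[0]]
                    new_ord = ords[e1][::-1] + ords[e2][::-1]
                    _nn_reduce(d, c1[1], c1[0], c2[1])
                    _nn_reduce(d, c1[1], c2[1], c2[0])
                else:
                    new_cl = [c1[0], c2[0]]
                    new_ord = ords[e1] + ords[e2][::-1]
                    _nn_reduce(d, c1[0], c1[1], c2[1])
                    _nn_reduce(d, c1[0], c2[1], c2[0])
        CL[e1] = new_cl
        ords[e1] = new_ord
        del CL[e2], ords[e2]
        DM_new = np.delete(np.delete(DM, e2, axis=0), e2, axis=1)
        DM = DM_new
        update_DM(e1 if e1 < e2 else e1 - 1)
    return tuple(dm.taxa[i] for i in ords[0])


def _interval_splits(order: tuple[str, ...]) -> list[frozenset[str]]:
    """All n(n-1)/2 interval splits of a circular ordering, as the side that
    excludes the first taxon."""
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(order[i:j + 1]))
    return out


def fit_split_weights(
    dm: DistanceMatrix, candidates: list[frozenset[str]]
) -> tuple[np.ndarray, float]:
    """Non-negative least-squares weights for candidate splits against dm.

    Returns (weights, residual norm). The design matrix has one row per taxon
    pair and one column per split, 1 where the split separates the pair.
    """
    idx = {t: i for i, t in enumerate(dm.taxa)}
    n = dm.n_taxa
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(candidates)))
    for col, s in enumerate(candidates):
        inside = np.zeros(n, dtype=bool)
        inside[[idx[t] for t in s]] = True
        for row, (a, b) in enumerate(pairs):
            if inside[a] != inside[b]:
                A[row, col] = 1.0
    y = np.array([dm.d[a, b] for a, b in pairs])
    w, rnorm = nnls(A, y)
    return w, float(rnorm)


def neighbor_net(dm: DistanceMatrix) -> SplitSystem:
    """NeighborNet circular split system fitted to a distance matrix."""
    if dm.n_taxa < 2:
        raise ValueError("need at least two taxa")
    order = neighbor_net_ordering(dm)
    if dm.n_taxa == 2:
        a, b = order
        return SplitSystem(
            dm.taxa, (frozenset([order[1]]),), np.array([dm.d[0, 1]]), order
        )
    cands = _interval_splits(order)
    w, _ = fit_split_weights(dm, cands)
    keep = w > WEIGHT_EPS
    splits = tuple(s for s, k in zip(cands, keep) if k)
    return SplitSystem(dm.taxa, splits, w[keep], order)


# ---------------------------------------------------------------------------
# splits graph
# ---------------------------------------------------------------------------

def _split_intervals(s: SplitSystem) -> list[tuple[int, int]]:
    """Each split as a positional interval [p, q] of the ordering (never
    containing position 0); raises if a split is not circular."""
    assert s.ordering is not None
    pos = {t: i for i, t in enumerate(s.ordering)}
    full = frozenset(s.taxa)
    out = []
    for side in s.splits:
        if s.ordering[0] in side:
            side = full - side
        ps = sorted(pos[t] for t in side)
        if ps[-1] - ps[0] + 1 != len(ps):
            raise ValueError(
                f"split {sorted(side)} is not an interval of the ordering"
            )
        out.append((ps[0], ps[-1]))
    return out


def splits_to_graph(s: SplitSystem) -> nx.Graph:
    """Planar splits-graph node/edge list for a circular split system.

    Every split is drawn as a chord across the taxon circle (nested splits
    sharing an endpoint gap are perturbed so only incompatible splits cross);
    graph nodes are the faces of the chord arrangement, edges connect faces
    separated by a chord. Edges carry ``split`` (index into ``s.splits``),
    ``weight`` and ``length`` (= weight); graph attribute ``taxon_node`` maps
    each taxon to its face. Parallel edge classes map 1:1 to splits.
    """
    if s.ordering is None:
        raise ValueError("splits graph requires a circular ordering")
    n = len(s.ordering)
    intervals = _split_intervals(s)
    theta = {k: 2.0 * np.pi * k / n for k in range(n)}

    # place chord endpoints inside gaps; sort within a gap so nesting holds
    starts: dict[int, list[int]] = {}
    ends: dict[int, list[int]] = {}
    for si, (p, q) in enumerate(intervals):
        starts.setdefault(p, []).append(si)
        ends.setdefault(q, []).append(si)
    size = {si: q - p + 1 for si, (p, q) in enumerate(intervals)}
    endpoint_angle: dict[int, list[float]] = {si: [None, None] for si in range(len(intervals))}
    for g in range(n):  # gap between position (g-1) and g (mod n)
        ending = sorted(ends.get((g - 1) % n, []), key=lambda si: size[si])
        starting = sorted(starts.get(g, []), key=lambda si: -size[si])
        slots = ending + starting
        if not slots:
            continue
        a0 = theta[(g - 1) % n]
        a1 = theta[(g - 1) % n] + 2.0 * np.pi / n
        for k, si in enumerate(slots):
            frac = (k + 1) / (len(slots) + 1)
            ang = a0 + frac * (a1 - a0)
            which = 1 if si in ending else 0
            endpoint_angle[si][which] = ang

    boundary_angles = sorted(
        [theta[k] for k in range(n)]
        + [a for pair in endpoint_angle.values() for a in pair if a is not None]
    )
    ring = [(np.cos(a), np.sin(a)) for a in boundary_angles]
    circle = LineString(ring + [ring[0]])
    chords = []
    for si in range(len(intervals)):
        a, b = endpoint_angle[si]
        chords.append(
            LineString([(np.cos(a), np.sin(a)), (np.cos(b), np.sin(b))])
        )
    faces = list(polygonize(unary_union([circle] + chords)))

    def face_of(pt: Point) -> int:
        for fi, poly in enumerate(faces):
            if poly.contains(pt):
                return fi
        # fall back to nearest face (point on a boundary by rounding)
        return int(np.argmin([poly.exterior.distance(pt) for poly in faces]))

    g = nx.Graph()
    for fi, poly in enumerate(faces):
        c = poly.representative_point()
        g.add_node(fi, pos=(c.x, c.y))
    eps = 0.25 * np.pi / max(n * (len(intervals) + 1), 8)
    for si, chord in enumerate(chords):
        cuts = [0.0, chord.length]
        for sj, other in enumerate(chords):
            if sj == si:
                continue
            inter = chord.intersection(other)
            if inter.is_empty or inter.geom_type != "Point":
                continue
            cuts.append(chord.project(inter))
        cuts = sorted(set(cuts))
        (x0, y0), (x1, y1) = chord.coords[0], chord.coords[-1]
        ux, uy = (x1 - x0) / chord.length, (y1 - y0) / chord.length
        nxv, nyv = -uy, ux
        for t0, t1 in zip(cuts[:-1], cuts[1:]):
            tm = (t0 + t1) / 2.0
            px, py = x0 + ux * tm, y0 + uy * tm
            f1 = face_of(Point(px + eps * nxv, py + eps * nyv))
            f2 = face_of(Point(px - eps * nxv, py - eps * nyv))
            if f1 != f2:
                g.add_edge(
                    f1, f2, split=si, weight=float(s.weights[si]),
                    length=float(s.weights[si]),
                )
    taxon_node = {}
    for k, t in enumerate(s.ordering):
        taxon_node[t] = face_of(
            Point(0.98 * np.cos(theta[k]), 0.98 * np.sin(theta[k]))
        )
    g.graph["taxon_node"] = taxon_node
    g.graph["splits"] = [tuple(sorted(side)) for side in s.splits]
    return g


# ---------------------------------------------------------------------------
# NEXUS output
# ---------------------------------------------------------------------------

def _taxa_block(taxa: tuple[str, ...]) -> list[str]:
    lines = ["BEGIN TAXA;", f"    DIMENSIONS NTAX={len(taxa)};", "    TAXLABELS"]
    for t in taxa:
        lines.append(f"        '{t}'" if " " in t else f"        {t}")
    lines += ["    ;", "END;"]
    return lines


def write_splits_nexus(s: SplitSystem) -> str:
    """SplitsTree-compatible NEXUS with TAXA and SPLITS blocks."""
    idx = {t: i + 1 for i, t in enumerate(s.taxa)}
    lines = ["#NEXUS", ""]
    lines += _taxa_block(s.taxa)
    lines += [
        "",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={len(s.taxa)} NSPLITS={s.n_splits};",
        "    FORMAT LABELS=NO WEIGHTS=YES;",
    ]
    if s.ordering is not None:
        cyc = " ".join(str(idx[t]) for t in s.ordering)
        lines.append(f"    CYCLE {cyc};")
    lines.append("    MATRIX")
    for side, w in zip(s.splits, s.weights):
        members = " ".join(str(idx[t]) for t in sorted(side, key=lambda t: idx[t]))
        lines.append(f"        {w:.10g} {members},")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def write_distances_nexus(dm: DistanceMatrix) -> str:
    """NEXUS TAXA + DISTANCES blocks."""
    lines = ["#NEXUS", ""]
    lines += _taxa_block(dm.taxa)
    lines += [
        "",
        "BEGIN DISTANCES;",
        f"    DIMENSIONS NTAX={dm.n_taxa};",
        "    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
        "    MATRIX",
    ]
    for i, t in enumerate(dm.taxa):
        row = " ".join(f"{dm.d[i, j]:.10g}" for j in range(dm.n_taxa))
        label = f"'{t}'" if " " in t else t
        lines.append(f"        {label} {row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)
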