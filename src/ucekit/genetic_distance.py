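"""Pairwise genetic distances, neighbor joining, and base-genome ranking.

Distances use pairwise deletion: any site with a gap or ambiguity in either
member of a pair is excluded for that pair. Saturated distances (log of a
non-positive argument) are reported as ``nan`` and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "TaxonRanking",
    "pairwise_distance",
    "neighbor_joining",
    "patristic",
    "rank_base_candidates",
    "Tree",
]

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    method: str
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        with np.errstate(invalid="ignore"):
            if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
                raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("matrix diagonal must be zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def mean_to_others(self, taxon: str) -> float:
        i = self.taxa.index(taxon)
        others = [j for j in range(len(self.taxa)) if j != i]
        return float(np.nanmean(self.matrix[i, others]))

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for i, t in enumerate(self.taxa):
            vals = " ".join(f"{v:.6f}" for v in self.matrix[i])
            lines.append(f"{t:<12s}{vals}")
        return "\n".join(lines) + "\n"


@dataclass
class TaxonRanking:
    mean_rank: dict[str, float]
    order: list[str]  # ascending mean rank; order[0] = recommended base


def _pairwise_sites(a: str, b: str) -> list[tuple[str, str]]:
    return [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in _BASES and y in _BASES
    ]


def _p_distance(sites: Sequence[tuple[str, str]]) -> float:
    return sum(1 for x, y in sites if x != y) / len(sites)


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * math.log(arg)


def _tn93(sites: Sequence[tuple[str, str]]) -> float:
    n = len(sites)
    freq = {b: 0.0 for b in _BASES}
    for x, y in sites:
        freq[x] += 0.5 / n
        freq[y] += 0.5 / n
    gA, gC, gG, gT = freq["A"], freq["C"], freq["G"], freq["T"]
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for x, y in sites if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in sites if {x, y} == {"C", "T"}) / n
    q = (
        sum(
            1
            for x, y in sites
            if x != y and ((x in _PURINES) != (y in _PURINES))
        )
        / n
    )
    if min(gR, gY) <= 0 or gA * gG <= 0 or gT * gC <= 0:
        # degenerate composition: fall back to JC69 on total p
        return _jc69(p1 + p2 + q)
    w1 = 2.0 * gA * gG / gR
    w2 = 2.0 * gT * gC / gY
    w3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    a1 = 1.0 - p1 / w1 - q / (2.0 * gR)
    a2 = 1.0 - p2 / w2 - q / (2.0 * gY)
    a3 = 1.0 - q / (2.0 * gR * gY)
    if a1 <= 0 or a2 <= 0 or a3 <= 0:
        return float("nan")
    return -w1 * math.log(a1) - w2 * math.log(a2) - w3 * math.log(a3)


def pairwise_distance(alignment: Mapping[str, str], method: str = "p") -> DistanceMatrix:
    """Distance matrix over an aligned set of equal-length sequences.

    method: 'p' (proportion of differences), 'JC69', or 'TN93'.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("pairwise_distance: need >= 2 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("pairwise_distance: sequences are not aligned (unequal lengths)")
    n = len(taxa)
    m = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            sites = _pairwise_sites(alignment[taxa[i]], alignment[taxa[j]])
            if not sites:
                raise ValueError(
                    f"pairwise_distance: zero comparable sites between "
                    f"{taxa[i]!r} and {taxa[j]!r}"
                )
            p = _p_distance(sites)
            if method == "p":
                d = p
            elif method == "JC69":
                d = _jc69(p)
            elif method == "TN93":
                d = _tn93(sites)
            else:
                raise ValueError(f"unknown method {method!r}")
            if math.isnan(d):
                saturated.add((taxa[i], taxa[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m, method, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class Tree:
    """Unrooted tree as an adjacency map node -> {neighbor: branch length}.

    Leaf nodes are taxon names; internal nodes are ``"__nj<i>"``.
    """

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]
    clamped: list[tuple[str, str]] = field(default_factory=list)

    def path_length(self, a: str, b: str) -> float:
        # BFS path sum; trees are tiny.
        prev: dict[str, str | None] = {a: None}
        queue = [a]
        while queue:
            node = queue.pop(0)
            if node == b:
                break
            for nb in self.adjacency[node]:
                if nb not in prev:
                    prev[nb] = node
                    queue.append(nb)
        total = 0.0
        node = b
        while prev.get(node) is not None:
            parent = prev[node]
            total += self.adjacency[node][parent]
            node = parent
        return total

    def newick(self) -> str:
        # Root at the last internal node (or a leaf for 2-taxon trees).
        root = next(
            (n for n in self.adjacency if n.startswith("__nj")), self.leaves[0]
        )

        def render(node: str, parent: str | None) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return node
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.6f}" for c in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Standard NJ agglomeration (Q criterion, lowest-index tie-break).

    Negative branch lengths are clamped to 0 and recorded in
    ``Tree.clamped``.
    """
    taxa = list(dist.taxa)
    if len(taxa) < 3:
        raise ValueError("neighbor_joining: need >= 3 taxa")
    if np.isnan(dist.matrix).any():
        raise ValueError("neighbor_joining: matrix contains saturated (nan) distances")
    D = {t: {u: float(dist.get(t, u)) for u in taxa if u != t} for t in taxa}
    adjacency: dict[str, dict[str, float]] = {t: {} for t in taxa}
    clamped: list[tuple[str, str]] = []
    active = list(taxa)
    next_id = 0

    def connect(a: str, b: str, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped.append((a, b))
            length = 0.0
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(active) > 2:
        r = len(active)
        sums = {t: sum(D[t][u] for u in active if u != t) for t in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * D[a][b] - sums[a] - sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        a, b = active[i], active[j]
        node = f"__nj{next_id}"
        next_id += 1
        la = 0.5 * D[a][b] + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = D[a][b] - la
        connect(node, a, la)
        connect(node, b, lb)
        D[node] = {}
        for u in active:
            if u in (a, b):
                continue
            d = 0.5 * (D[a][u] + D[b][u] - D[a][b])
            D[node][u] = d
            D[u][node] = d
        active = [t for t in active if t not in (a, b)] + [node]
    a, b = active
    connect(a, b, D[a][b])
    tree = Tree(adjacency, taxa)
    tree.clamped = clamped
    return tree


def patristic(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf branch-length path sums as a DistanceMatrix."""
    taxa = tree.leaves
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.path_length(taxa[i], taxa[j])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m, "NJ-patristic")


def rank_base_candidates(matrices: Sequence[DistanceMatrix]) -> TaxonRanking:
    """Mean rank of per-taxon average distance across markers x methods.

    Rank 1 = smallest average distance = recommended base genome. Ties share
    the mean rank. A taxon absent from a matrix skips that matrix.
    """
    if not matrices:
        raise ValueError("rank_base_candidates: no matrices")
    all_taxa = sorted({t for dm in matrices for t in dm.taxa})
    ranks: dict[str, list[float]] = {t: [] for t in all_taxa}
    for dm in matrices:
        means = np.array([dm.mean_to_others(t) for t in dm.taxa])
        if np.isnan(means).any():
            means = np.where(np.isnan(means), np.inf, means)
        rk = rankdata(means, method="average")
        for t, r in zip(dm.taxa, rk):
            ranks[t].append(float(r))
    mean_rank = {t: float(np.mean(rs)) for t, rs in ranks.items() if rs}
    order = sorted(mean_rank, key=lambda t: (mean_rank[t], t))
    return TaxonRanking(mean_rank, order)
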