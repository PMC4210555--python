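"""Compression: cluster individuals into groups and build group kinship.

Individuals are clustered hierarchically on a distance derived from the
kinship matrix (d = k_max - k, shift-invariant and monotone in kinship);
cutting the merge tree at s groups gives the compression assignment, and
a group-kinship operator phi in {average, median, maximum} collapses each
between-group multiset of individual kinships into one group-level value.

Eight linkage rules are supported: UPGMA (average), UPGMC (centroid),
COM (complete), FLE (Lance-Williams flexible-beta, beta = -0.25), WPGMA
(McQuitty), WPGMC (median), SIN (single) and WAR (Ward).  All but FLE
are delegated to scipy.cluster.hierarchy; FLE is computed by the
Lance-Williams recurrence and emitted in the same linkage-matrix format,
so cutting is uniform.  The Euclidean-assuming rules (UPGMC, WPGMC, WAR)
are run on kinship-derived distances anyway, mirroring common practice;
inversions in the centroid methods are tolerated (cutting goes by merge
order, not height).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .kinship import KinshipMatrix

__all__ = [
    "LINKAGES",
    "PHI_OPERATORS",
    "GroupAssignment",
    "GroupModel",
    "kinship_to_distance",
    "hierarchical_cluster",
    "cut_to_groups",
    "group_kinship",
]

# field name -> scipy method (None = implemented here)
LINKAGES: dict = {
    "UPGMA": "average",
    "UPGMC": "centroid",
    "COM": "complete",
    "FLE": None,
    "WPGMA": "weighted",
    "WPGMC": "median",
    "SIN": "single",
    "WAR": "ward",
}
PHI_OPERATORS = ("average", "median", "maximum")
_FLEXIBLE_BETA = -0.25


@dataclass
class GroupAssignment:
    """Partition of n individuals into s non-empty groups (labels 0..s-1)."""

    group_of: np.ndarray
    s: int

    def __post_init__(self) -> None:
        self.group_of = np.asarray(self.group_of, dtype=int)
        labels = np.unique(self.group_of)
        if not np.array_equal(labels, np.arange(self.s)):
            raise ValueError("groups must be labelled 0..s-1 with none empty")

    @property
    def n(self) -> int:
        return self.group_of.size

    @property
    def compression_level(self) -> float:
        """Average number of individuals per group, n/s."""
        return self.n / self.s

    def incidence(self) -> np.ndarray:
        """n x s incidence matrix Z (one 1 per row)."""
        Z = np.zeros((self.n, self.s))
        Z[np.arange(self.n), self.group_of] = 1.0
        return Z


@dataclass
class GroupModel:
    """Group kinship K (s x s), incidence Z and provenance for one config."""

    assignment: GroupAssignment
    K_group: np.ndarray
    Z: np.ndarray
    phi: str
    linkage: str | None = None
    psd_ridge: float = 0.0


def kinship_to_distance(K: KinshipMatrix | np.ndarray) -> np.ndarray:
    """d_ht = k_max - k_ht: non-negative, symmetric, monotone in kinship."""
    v = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    return v.max() - v


def _flexible_beta_linkage(d: np.ndarray, beta: float = _FLEXIBLE_BETA) -> np.ndarray:
    """Lance-Williams flexible-beta agglomeration.

    d(k, i+j) = a*d(k,i) + a*d(k,j) + beta*d(i,j) with a = (1-beta)/2.
    Ties merge the lexicographically smallest pair of current cluster ids.
    Returns a scipy-format linkage matrix.
    """
    n = d.shape[0]
    alpha = (1.0 - beta) / 2.0
    dist = d.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    cluster_id = np.arange(n)  # scipy id of the cluster in each active slot
    size = np.ones(n)
    active = np.ones(n, dtype=bool)
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = dist[np.ix_(sub, sub)]
        flat = np.argmin(block)
        bi, bj = divmod(flat, block.shape[1])
        # argmin already scans row-major, i.e. lowest (slot_i, slot_j) first,
        # and slots are ordered by creation so ids are non-decreasing in slot
        i, j = sub[min(bi, bj)], sub[max(bi, bj)]
        a, b = sorted((cluster_id[i], cluster_id[j]))
        h = dist[i, j]
        merges[step] = (a, b, h, size[i] + size[j])
        new = alpha * dist[:, i] + alpha * dist[:, j] + beta * h
        dist[:, i] = new
        dist[i, :] = new
        dist[i, i] = np.inf
        active[j] = False
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        cluster_id[i] = n + step
        size[i] += size[j]
    return merges


def hierarchical_cluster(d: np.ndarray, linkage: str) -> np.ndarray:
    """Full agglomerative merge tree (scipy linkage matrix) of n leaves.

    Parameters
    ----------
    d : ndarray, shape (n, n)
        Symmetric distance matrix; the diagonal is ignored.
    linkage : str
        One of UPGMA, UPGMC, COM, FLE, WPGMA, WPGMC, SIN, WAR.
    """
    if linkage not in LINKAGES:
        raise ValueError(
            f"unknown linkage {linkage!r}; valid: {', '.join(LINKAGES)}"
        )
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("clustering requires at least 2 individuals")
    if LINKAGES[linkage] is None:
        return _flexible_beta_linkage(d)
    off = d.copy()
    np.fill_diagonal(off, 0.0)
    condensed = squareform(off, checks=False)
    return hierarchy.linkage(condensed, method=LINKAGES[linkage])


def cut_to_groups(tree: np.ndarray, s: int) -> GroupAssignment:
    """Partition obtained by undoing the last s-1 merges of the tree."""
    return cut_all(tree, [s])[s]


def cut_all(tree: np.ndarray, s_values) -> dict:
    """Cut one tree at many group counts in a single pass.

    Cuts go strictly by merge order (the first n-s merges are applied),
    which stays well defined for non-monotonic trees (centroid/median
    linkages can produce inversions, where merge heights are not sorted).
    """
    n = tree.shape[0] + 1
    s_values = sorted(set(int(s) for s in s_values), reverse=True)
    for s in s_values:
        if not 1 <= s <= n:
            raise ValueError(f"s={s} out of range [1, {n}]")
    # union-find over scipy cluster ids: leaf j -> j, merge k -> n + k
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out: dict[int, GroupAssignment] = {}
    k = 0  # merges applied so far
    for s in s_values:
        while k < n - s:
            a, b = int(tree[k, 0]), int(tree[k, 1])
            parent[find(a)] = parent[find(b)] = n + k
            k += 1
        labels = np.fromiter((find(j) for j in range(n)), dtype=int, count=n)
        out[s] = GroupAssignment(_canonical_labels(labels), s)
    return out


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel groups 0..s-1 in order of first appearance (deterministic)."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {g: k for k, g in enumerate(order)}
    return np.fromiter((remap[g] for g in labels), dtype=int, count=labels.size)


def group_kinship(
    K: KinshipMatrix | np.ndarray,
    a: GroupAssignment,
    phi: str,
    linkage: str | None = None,
) -> GroupModel:
    """Collapse individual kinship to group kinship under the operator phi.

    Between groups i != j the operator acts on all |i|*|j| cross pairs; on
    the diagonal it acts on the within-group upper triangle including the
    self-kinships (so singleton groups are well defined and group kinship
    reduces to individual kinship at s = n).  If the result is not positive
    semidefinite (possible for median/maximum), the smallest diagonal ridge
    eps in {1e-6 * 2^k} restoring min eigenvalue >= -1e-8 is added and
    recorded in ``psd_ridge``.
    """
    if phi not in PHI_OPERATORS:
        raise ValueError(f"unknown phi {phi!r}; valid: {', '.join(PHI_OPERATORS)}")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    s, n = a.s, a.n
    if s == n:
        # all-singleton partition: phi over one value is that value
        order = np.argsort(a.group_of, kind="stable")
        inv = np.empty(n, dtype=int)
        inv[a.group_of[order]] = order
        Kg = Kv[np.ix_(inv, inv)].copy()
    elif phi == "average":
        Z = a.incidence()
        sizes = Z.sum(axis=0)
        S = Z.T @ Kv @ Z
        Kg = S / np.outer(sizes, sizes)
        # diagonal: upper triangle incl. self-pairs of each within block
        tr = Z.T @ np.diag(Kv)
        cnt = sizes * (sizes + 1) / 2.0
        np.fill_diagonal(Kg, (np.diag(S) + tr) / 2.0 / cnt)
    else:
        members = [np.where(a.group_of == i)[0] for i in range(s)]
        op = np.max if phi == "maximum" else np.median
        Kg = np.zeros((s, s))
        for i in range(s):
            gi = members[i]
            block = Kv[np.ix_(gi, gi)]
            iu = np.triu_indices(gi.size)
            Kg[i, i] = op(block[iu])
            for j in range(i + 1, s):
                v = op(Kv[np.ix_(gi, members[j])])
                Kg[i, j] = Kg[j, i] = v
    Kg = 0.5 * (Kg + Kg.T)
    ridge = _psd_ridge(Kg)
    if ridge:
        Kg = Kg + ridge * np.eye(s)
    return GroupModel(a, Kg, a.incidence(), phi, linkage, ridge)


def _psd_ridge(Kg: np.ndarray, tol: float = -1e-8) -> float:
    eigmin = float(np.linalg.eigvalsh(Kg)[0])
    if eigmin >= tol:
        return 0.0
    eps = 1e-6
    while eigmin + eps < tol:
        eps *= 2.0
    return eps
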