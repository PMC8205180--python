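"""District delimitation: WPGMA clustering, tree cutting, consolidation of
minor groups, and the MRPP significance test.

WPGMA (McQuitty linkage) merges, at each step, the pair of clusters at
minimal distance and sets the new cluster's distance to any other cluster to
the plain average of the two merged clusters' distances — each merged
*cluster* (not each leaf) contributes equally. The k-group cut typically
yields a few large groups plus scattered minor ones; consolidation relabels
minor-group cells to the major district they join at the lowest dendrogram
height, reproducing the common practice of reassigning unrepresented cells
to the better-represented groups. MRPP then asks whether within-district
mean dissimilarity δ is smaller than expected under random relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from skbio import DistanceMatrix

__all__ = [
    "Dendrogram",
    "RegionAssignment",
    "MrppResult",
    "wpgma",
    "cut_tree",
    "consolidate_districts",
    "mrpp",
]


@dataclass
class Dendrogram:
    """Merge tree in scipy linkage form plus leaf labels.

    ``linkage`` row t is (left, right, height, size): clusters ``left`` and
    ``right`` (leaves are 0..n-1, the merge at row t creates cluster n+t)
    merged at ``height``.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick string; branch lengths from merge heights (leaf height 0)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for t, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + t] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[n + t] = h
        return node[n + len(self.linkage) - 1] + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def wpgma(dm: DistanceMatrix) -> Dendrogram:
    """WPGMA agglomeration of a dissimilarity matrix.

    Ties in the minimum search are broken by the lexicographically smallest
    (i, j) cluster-id pair, so the merge sequence is deterministic across
    platforms.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two leaves")
    if np.isnan(D).any():
        raise ValueError("NaN in dissimilarity matrix")

    # current[i] = cluster id occupying slot i; dist over active slots
    dist = D.copy()
    active = list(range(n))
    cluster_id = list(range(n))
    Z = np.zeros((n - 1, 4))
    size = {i: 1 for i in range(n)}

    for t in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                d = dist[active[ii], active[jj]]
                pair = tuple(sorted((cluster_id[active[ii]], cluster_id[active[jj]])))
                key = (d, pair)
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        key, ii, jj = best
        d_min = key[0]
        si, sj = active[ii], active[jj]
        ca, cb = cluster_id[si], cluster_id[sj]
        new_id = n + t
        Z[t] = (min(ca, cb), max(ca, cb), d_min, size[ca] + size[cb])
        size[new_id] = size[ca] + size[cb]

        for sk in active:
            if sk in (si, sj):
                continue
            dist[si, sk] = dist[sk, si] = 0.5 * (dist[si, sk] + dist[sj, sk])
        cluster_id[si] = new_id
        active.remove(sj)

    return Dendrogram(linkage=Z, labels=list(dm.ids))


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Labels from removing the k−1 last (highest) merges.

    Merges are applied in dendrogram order, which for the greedy WPGMA
    sequence means ties at equal height resolve by merge order. Group
    numbers (1..k) are assigned by each group's first leaf in sorted label
    order.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    parent: dict[int, int] = {}

    def findc(x):
        r = x
        while parent.get(r, r) != r:
            r = parent[r]
        while parent.get(x, x) != x:
            parent[x], x = r, parent[x]
        return r

    for t in range(n - k):
        a, b, _, _ = dendrogram.linkage[t]
        ra, rb = findc(int(a)), findc(int(b))
        new = n + t
        parent[ra] = new
        parent[rb] = new

    leaf_root = [findc(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: dendrogram.labels[i])
    group_num: dict[int, int] = {}
    for i in order:
        r = leaf_root[i]
        if r not in group_num:
            group_num[r] = len(group_num) + 1
    labels = pd.Series(
        [group_num[leaf_root[i]] for i in range(n)],
        index=pd.Index(dendrogram.labels, name="cell_id"),
        name="group",
    )
    return labels.sort_index()


@dataclass
class RegionAssignment:
    """Final cell → district labelling with provenance."""

    assignment: pd.DataFrame  # index cell_id; columns district, provenance

    @property
    def districts(self) -> pd.Series:
        return self.assignment["district"]

    def write_csv(self, path) -> None:
        self.assignment.to_csv(path, index_label="cell_id")


def consolidate_districts(
    labels: pd.Series,
    dendrogram: Dendrogram,
    k_final: int = 2,
    min_cells: int | None = None,
) -> RegionAssignment:
    """Keep the ``k_final`` largest groups as districts; reassign the rest.

    A minor-group cell joins the major district with the smallest cophenetic
    distance (the dendrogram height at which it first fuses with any cell of
    that district). Districts are named "A", "B", ... in decreasing size of
    their founding group. Groups smaller than ``min_cells`` are treated as
    minor even when within the k_final largest (default: only the size rank
    matters).
    """
    counts = labels.value_counts()
    if len(counts) < k_final:
        raise ValueError(f"only {len(counts)} groups; cannot form {k_final} districts")
    ranked = sorted(counts.index, key=lambda g: (-counts[g], g))
    major = ranked[:k_final]
    if min_cells is not None:
        major = [g for g in major if counts[g] >= min_cells]
        if len(major) < k_final:
            raise ValueError(f"fewer than k_final={k_final} groups reach min_cells={min_cells}")
    district_name = {g: chr(ord("A") + r) for r, g in enumerate(major)}

    label_pos = {lab: i for i, lab in enumerate(dendrogram.labels)}
    coph = cophenet(dendrogram.linkage)
    n = dendrogram.n_leaves

    def coph_at(i: int, j: int) -> float:
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        return coph[n * i + j - ((i + 2) * (i + 1)) // 2]

    major_pos = {g: [label_pos[c] for c in labels.index[labels == g]] for g in major}

    rows = []
    for cid, g in labels.items():
        if g in district_name:
            rows.append((cid, district_name[g], "cluster"))
        else:
            p = label_pos[cid]
            best = min(
                district_name,
                key=lambda mg: (min(coph_at(p, q) for q in major_pos[mg]), district_name[mg]),
            )
            rows.append((cid, district_name[best], "reassigned"))
    df = pd.DataFrame(rows, columns=["cell_id", "district", "provenance"]).set_index("cell_id")
    return RegionAssignment(assignment=df.sort_index())


@dataclass
class MrppResult:
    """MRPP summary: observed δ, per-group means ξ_g, weights, p and the
    chance-corrected within-group agreement A = 1 − δ_obs / mean(δ_perm)."""

    observed_delta: float
    group_means: dict[str, float]
    group_weights: dict[str, float]
    permutations: int
    p_value: float
    a_statistic: float
    expected_delta: float

    def to_dict(self) -> dict:
        return {
            "observed_delta": self.observed_delta,
            "group_means": self.group_means,
            "group_weights": self.group_weights,
            "permutations": self.permutations,
            "p_value": self.p_value,
            "a_statistic": self.a_statistic,
            "expected_delta": self.expected_delta,
        }


def _delta(D: np.ndarray, codes: np.ndarray, groups: np.ndarray, weights: np.ndarray) -> float:
    delta = 0.0
    for g, w in zip(groups, weights):
        idx = np.flatnonzero(codes == g)
        sub = D[np.ix_(idx, idx)]
        m = idx.size
        delta += w * (sub.sum() / (m * (m - 1)))
    return delta


def mrpp(
    dm: DistanceMatrix,
    assignment: pd.Series | RegionAssignment,
    permutations: int = 999,
    seed: int | None = None,
) -> MrppResult:
    """Multi-response permutation procedure on a dissimilarity matrix.

    δ = Σ_g (n_g / N) ξ_g with ξ_g the mean pairwise within-group
    dissimilarity; the null permutes labels holding group sizes fixed, and
    the one-sided p-value is (#{δ_perm ≤ δ_obs} + 1) / (P + 1) — small δ
    means compositionally homogeneous groups.
    """
    if isinstance(assignment, RegionAssignment):
        labels = assignment.districts
    else:
        labels = assignment
    labels = labels.reindex(list(dm.ids))
    if labels.isna().any():
        raise ValueError("assignment is missing labels for some matrix ids")

    codes, uniques = pd.factorize(labels.to_numpy(), sort=True)
    sizes = np.bincount(codes)
    if len(uniques) < 2:
        raise ValueError("MRPP needs at least two groups")
    if sizes.min() < 2:
        small = [str(uniques[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with fewer than two members: {small}")

    D = np.asarray(dm.data, dtype=float)
    groups = np.arange(len(uniques))
    weights = sizes / sizes.sum()
    observed = _delta(D, codes, groups, weights)

    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(permutations)
    work = codes.copy()
    for b in range(permutations):
        rng.shuffle(work)
        perm_deltas[b] = _delta(D, work, groups, weights)

    p = (np.count_nonzero(perm_deltas <= observed) + 1) / (permutations + 1)
    expected = float(perm_deltas.mean())
    a_stat = 1.0 - observed / expected if expected > 0 else 0.0
    return MrppResult(
        observed_delta=float(observed),
        group_means={
            str(uniques[g]): float(
                D[np.ix_(np.flatnonzero(codes == g), np.flatnonzero(codes == g))].sum()
                / (sizes[g] * (sizes[g] - 1))
            )
            for g in groups
        },
        group_weights={str(uniques[g]): float(weights[g]) for g in groups},
        permutations=permutations,
        p_value=float(p),
        a_statistic=float(a_stat),
        expected_delta=expected,
    )
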