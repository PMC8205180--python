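"""Relative environmental turnover and biogeographic tracks.

``envfit`` regresses each (standardized) environmental variable on the NMDS
axes; the normalized coefficient vector is the variable's direction in
ordination space, its r² the fraction of variance explained, and the
p-value comes from permuting the variable across cells — the classical
post-hoc vector fitting used to display environmental drivers on an
ordination.

``exclusive_species`` lists species restricted to a single district, and
``mst_track`` links their collecting points with a minimum spanning tree
over great-circle distances — a biogeographic track summarizing the shared
distribution of a district's restricted taxa.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from ._geo import EARTH_RADIUS_KM, write_feature_collection

__all__ = ["envfit", "exclusive_species", "Track", "mst_track", "haversine_matrix"]


def envfit(
    scores: pd.DataFrame,
    env: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit environmental vectors onto ordination axes.

    Returns a table indexed by variable with unit direction cosines (one
    column per axis), ``r2`` and permutation ``p``. Scores and env must
    share cell ids; each variable is centered before fitting, and the null
    permutes the variable's values across cells (the scores stay fixed).
    """
    env = env.reindex(scores.index)
    if env.isna().any().any():
        raise ValueError("env table missing values for some ordinated cells")
    S = scores.to_numpy(dtype=float)
    Sc = S - S.mean(axis=0)
    Q, _ = np.linalg.qr(Sc)
    n, k = Sc.shape

    rng = np.random.default_rng(seed)
    rows = {}
    for var in env.columns:
        v = env[var].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise ValueError(f"constant variable {var!r} cannot be fitted")
        vc = v - v.mean()
        sstot = float(vc @ vc)
        coef, *_ = np.linalg.lstsq(Sc, vc, rcond=None)
        fitted = Sc @ coef
        r2 = float(fitted @ fitted) / sstot

        # vectorized permutation null: r2 = |Q' v_perm|^2 / |v_perm|^2
        perm_idx = np.argsort(rng.random((permutations, n)), axis=1)
        Vp = vc[perm_idx]  # P x n
        proj = Vp @ Q  # P x k
        r2_perm = np.sum(proj * proj, axis=1) / sstot
        p = (np.count_nonzero(r2_perm >= r2) + 1) / (permutations + 1)

        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        rows[var] = list(direction) + [r2, float(p)]

    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(scores.columns) + ["r2", "p"]
    )
    out.index.name = "variable"
    out["permutations"] = permutations
    return out


def exclusive_species(species_sets: dict[str, set], assignment) -> dict[str, list[str]]:
    """Species occurring in only one district.

    ``species_sets`` maps cell_id → species set (see
    :meth:`phytoreg.gridding.CellTable.species_sets`); a species is
    exclusive to district D iff every cell containing it is labelled D.
    """
    districts = assignment.districts if hasattr(assignment, "districts") else assignment
    seen: dict[str, set[str]] = {}
    for cid, spp in species_sets.items():
        d = districts.get(cid)
        if d is None:
            raise ValueError(f"cell {cid} has no district label")
        for sp in spp:
            seen.setdefault(sp, set()).add(str(d))
    out: dict[str, list[str]] = {str(d): [] for d in sorted(set(map(str, districts)))}
    for sp, ds in seen.items():
        if len(ds) == 1:
            out[next(iter(ds))].append(sp)
    return {d: sorted(spp) for d, spp in out.items()}


def haversine_matrix(points: np.ndarray, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Pairwise great-circle distances (km) for an (n, 2) lon/lat array."""
    lon = np.radians(points[:, 0])
    lat = np.radians(points[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.minimum(1.0, np.sqrt(h)))


@dataclass
class Track:
    """Minimum-spanning-tree biogeographic track for one district."""

    district: str
    points: np.ndarray  # (n, 2) lon/lat, deduplicated, lexicographically sorted
    edges: list[tuple[int, int, float]]  # point indices + length (km)

    @property
    def total_length_km(self) -> float:
        return float(sum(e[2] for e in self.edges))

    def to_features(self) -> tuple[list[dict], list[dict]]:
        geoms, props = [], []
        for i, j, length in self.edges:
            geoms.append(
                {
                    "type": "LineString",
                    "coordinates": [list(self.points[i]), list(self.points[j])],
                }
            )
            props.append({"district": self.district, "length_km": round(length, 3)})
        return geoms, props


def mst_track(records: pd.DataFrame, district: str) -> Track:
    """Minimum spanning tree over the distinct collecting points of a
    district's exclusive species.

    ``records`` needs ``lon``/``lat`` columns. Distances are haversine on a
    spherical Earth (R = 6371 km); duplicate coordinates are collapsed and
    points sorted lexicographically, with Prim's algorithm breaking
    distance ties by lowest point index, so the tree is deterministic.
    """
    pts = (
        records[["lon", "lat"]]
        .drop_duplicates()
        .sort_values(["lon", "lat"], kind="mergesort")
        .to_numpy(dtype=float)
    )
    n = len(pts)
    if n < 2:
        raise ValueError(f"need at least two distinct points, got {n}")

    D = haversine_matrix(pts)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best_dist = D[0].copy()
    best_from = np.zeros(n, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        cand = np.where(~in_tree, best_dist, np.inf)
        j = int(np.argmin(cand))  # argmin takes the lowest index on ties
        i = int(best_from[j])
        edges.append((min(i, j), max(i, j), float(D[i, j])))
        in_tree[j] = True
        closer = D[j] < best_dist
        update = closer & ~in_tree
        best_dist[update] = D[j][update]
        best_from[update] = j
    return Track(district=district, points=pts, edges=edges)


def write_tracks_geojson(tracks: list[Track], path) -> None:
    geoms: list[dict] = []
    props: list[dict] = []
    for tr in tracks:
        g, p = tr.to_features()
        geoms.extend(g)
        props.extend(p)
    write_feature_collection(path, geoms, props)
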