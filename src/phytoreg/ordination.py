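"""Non-metric multidimensional scaling (NMDS) of the turnover matrix.

Minimizes Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

where d are configuration distances and d̂ the disparities — the isotonic
(monotone in dissimilarity rank) least-squares fit to d. Each restart
alternates an isotonic-regression step with a Guttman (majorization) update
of the coordinates; the update is accepted only if stress does not
increase (step-halving otherwise), so the stress trace is non-increasing
by construction. The best of ``restarts`` random starts plus one classical
metric-scaling start wins; the final configuration is centered and rotated
to its principal axes.

Ties in the dissimilarities use Kruskal's primary approach: tied values may
be fitted in any order (they are ordered by current configuration distance
before the isotonic fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from ._geo import write_feature_collection

__all__ = ["OrdinationResult", "nmds", "stress_quality", "axis_maps", "stress_of"]


def stress_of(configuration: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of an arbitrary configuration against a
    dissimilarity matrix (isotonic disparities recomputed)."""
    diss = squareform(np.asarray(dm.data, dtype=float), checks=False)
    d = pdist(np.asarray(configuration, dtype=float))
    order = np.lexsort((d, diss))
    dhat = _isotonic_fit(d, order)
    return _stress1(d, dhat)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # index cell_id, columns NMDS1..NMDSk
    stress: float
    n_restarts: int
    best_restart_seed: int | None
    converged: bool
    stress_history: list[float] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "stress": self.stress,
            "stress_label": stress_quality(self.stress),
            "n_restarts": self.n_restarts,
            "best_restart_seed": self.best_restart_seed,
            "converged": self.converged,
            "n_iterations_best": len(self.stress_history),
        }

    def write_csv(self, path) -> None:
        self.scores.to_csv(path, index_label="cell_id", float_format="%.10g")


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d * d))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _isotonic_fit(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Disparities: isotonic regression of configuration distances on
    dissimilarity rank (primary tie handling handled by the caller's
    ordering)."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = np.arange(order.size, dtype=float)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(x, d[order])
    return dhat


def _classical_start(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling of the dissimilarities."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w_k)


def _guttman(X: np.ndarray, dhat_sq: np.ndarray) -> np.ndarray:
    """Majorization update for raw stress with fixed disparities."""
    n = X.shape[0]
    d = squareform(pdist(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat_sq / d, 0.0)
    B = -ratio
    np.fill_diagonal(B, ratio.sum(axis=1))
    return (B @ X) / n


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Best-of-restarts Kruskal NMDS of a dissimilarity matrix."""
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of objects n={n}")
    diss = squareform(D, checks=False)
    if np.allclose(diss, diss[0]):
        warnings.warn("all dissimilarities equal; NMDS solution is degenerate")

    # primary tie handling needs a stable dissimilarity order; ties are
    # re-ordered by current distances inside each iteration
    base_order = np.argsort(diss, kind="stable")

    rng = np.random.default_rng(seed)
    start_seeds: list[int | None] = [None]  # classical scaling start
    start_seeds += [int(rng.integers(0, 2**31 - 1)) for _ in range(restarts)]

    best = None
    for start_seed in start_seeds:
        if start_seed is None:
            X = _classical_start(D, k)
            if np.allclose(X, 0):
                X = np.random.default_rng(0).standard_normal((n, k)) * 1e-3
        else:
            X = np.random.default_rng(start_seed).standard_normal((n, k))

        d = pdist(X)
        order = np.lexsort((d, diss))  # primary ties: order by current d
        dhat = _isotonic_fit(d, order)
        stress = _stress1(d, dhat)
        history = [stress]
        converged = False

        for _ in range(max_iter):
            X_prop = _guttman(X, squareform(dhat, checks=False))
            accepted = False
            step = 1.0
            for _half in range(8):
                X_try = X + step * (X_prop - X)
                d_try = pdist(X_try)
                order = np.lexsort((d_try, diss))
                dhat_try = _isotonic_fit(d_try, order)
                s_try = _stress1(d_try, dhat_try)
                if s_try <= stress:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                converged = True
                break
            rel = (stress - s_try) / max(stress, 1e-30)
            X, d, dhat, stress = X_try, d_try, dhat_try, s_try
            history.append(stress)
            if rel < tol:
                converged = True
                break

        if best is None or stress < best[0]:
            best = (stress, X, start_seed, converged, history)

    stress, X, best_seed, converged, history = best
    X = X - X.mean(axis=0)
    # stress-1 is scale-invariant, so the optimizer may drift in scale;
    # fix the convention: configuration distances match the dissimilarities
    # in root-mean-square magnitude
    d_final = pdist(X)
    if np.linalg.norm(d_final) > 0:
        X = X * (np.linalg.norm(diss) / np.linalg.norm(d_final))
    # principal-axis rotation with a deterministic sign convention
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(k):
        col = X[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            X[:, j] = -col

    scores = pd.DataFrame(
        X, index=pd.Index(list(dm.ids), name="cell_id"),
        columns=[f"NMDS{j + 1}" for j in range(k)],
    )
    return OrdinationResult(
        scores=scores,
        stress=float(stress),
        n_restarts=len(start_seeds),
        best_restart_seed=best_seed,
        converged=converged,
        stress_history=[float(s) for s in history],
    )


def stress_quality(stress: float) -> str:
    """Verbal quality of a stress-1 value: <=0.1 excellent, <=0.2 good,
    <0.3 fair, >=0.3 poor."""
    if stress < 0:
        raise ValueError("stress cannot be negative")
    if stress <= 0.1:
        return "excellent"
    if stress <= 0.2:
        return "good"
    if stress < 0.3:
        return "fair"
    return "poor"


def axis_maps(
    ordination: OrdinationResult,
    assignment,
    cells: pd.DataFrame | None = None,
    grid=None,
    geojson_path=None,
) -> dict[str, pd.DataFrame]:
    """Per-axis score tables, sign-fixed for mapping.

    Each axis is flipped, if needed, so the first district in label-sort
    order has non-negative mean score; the export is therefore invariant to
    a global sign flip of the configuration. Optionally writes a GeoJSON of
    cell polygons carrying the scores as properties.
    """
    districts = assignment.districts if hasattr(assignment, "districts") else assignment
    districts = districts.reindex(ordination.scores.index)
    if districts.isna().any():
        raise ValueError("assignment does not cover all ordinated cells")

    first = sorted(districts.unique())[0]
    mask = (districts == first).to_numpy()
    scores = ordination.scores.copy()
    for col in scores.columns:
        mean_first = scores.loc[mask, col].mean()
        if mean_first < 0:
            scores[col] = -scores[col]
        elif mean_first == 0:
            col_v = scores[col].to_numpy()
            if col_v[np.argmax(np.abs(col_v))] < 0:
                scores[col] = -scores[col]

    tables = {
        col: scores[[col]].reset_index().rename(columns={col: "score"})
        for col in scores.columns
    }

    if geojson_path is not None:
        if cells is None or grid is None:
            raise ValueError("cells and grid are required for GeoJSON export")
        geoms = [grid.cell_polygon(int(r.ix), int(r.iy)) for r in cells.itertuples()]
        props = []
        for cid in cells.index:
            p = {"cell_id": cid, "district": str(districts.get(cid, ""))}
            for col in scores.columns:
                p[col] = round(float(scores.at[cid, col]), 6)
            props.append(p)
        write_feature_collection(geojson_path, geoms, props)
    return tables
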