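"""Environmental predictors of species composition.

Pixel-level environmental variables are averaged into grid cells, pruned
for collinearity (greedy Pearson |r| elimination), z-standardized, and fed
to a redundancy analysis (RDA). Forward selection ranks candidate
predictors by a Gaussian AIC of the multivariate least-squares fit and
admits the best candidate only if its marginal pseudo-F is significant
under row permutation of the response — producing the familiar stepwise
table (Df, AIC, F, p) of the most parsimonious constrained model.

RDA here is the classical one: regress every (standardized) response column
on the predictor matrix; the constrained (canonical) variance is the total
variance of the fitted values, and the proportion explained is the
redundancy statistic tr(Ŷ'Ŷ) / tr(Y'Y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_pixels",
    "prune_collinear",
    "standardize",
    "destandardize",
    "RdaResult",
    "rda",
    "ForwardSelectResult",
    "forward_select",
]


def aggregate_pixels(
    pixels: pd.DataFrame,
    grid,
    cell_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Average pixel values into grid cells.

    ``pixels`` has columns ``lon``, ``lat`` plus one column per variable;
    a pixel belongs to the cell containing its centre under the same
    half-open rule used for occurrence gridding. If ``cell_ids`` is given,
    the table is restricted to those cells and the ones without any pixel
    are returned as the second element (flagged, excluded with a warning).
    """
    if "lon" not in pixels.columns or "lat" not in pixels.columns:
        raise ValueError("pixel table needs 'lon' and 'lat' columns")
    ix, iy = grid.cell_index(pixels["lon"].to_numpy(), pixels["lat"].to_numpy())
    if (ix < 0).any() or (iy < 0).any():
        raise ValueError("pixel(s) below the grid origin")
    cids = [f"c{i:03d}_{j:03d}" for i, j in zip(ix, iy)]
    values = pixels.drop(columns=["lon", "lat"])
    env = values.groupby(pd.Index(cids, name="cell_id")).mean().sort_index()

    missing: list[str] = []
    if cell_ids is not None:
        missing = sorted(set(cell_ids) - set(env.index))
        if missing:
            warnings.warn(f"{len(missing)} cells have no pixel coverage and are excluded")
        env = env.reindex([c for c in sorted(cell_ids) if c not in missing])
    return env, missing


def prune_collinear(
    env: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy collinearity pruning by pairwise Pearson correlation.

    Constant columns are dropped first. Then, while any pair exceeds
    |r| > threshold, the worst pair's member with the larger mean absolute
    correlation to all remaining variables is dropped. Every drop is
    reported with the triggering pair and its r.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables")
    if env.shape[0] < 3:
        raise ValueError("need at least three cells")

    report_rows = []
    kept = env.copy()
    const = [c for c in kept.columns if kept[c].std(ddof=1) == 0 or kept[c].isna().all()]
    for c in const:
        report_rows.append((c, "", np.nan, "constant column"))
    kept = kept.drop(columns=const)

    while kept.shape[1] >= 2:
        corr = kept.corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        r = float(corr.loc[worst[0], worst[1]])
        if r <= threshold:
            break
        v1, v2 = sorted(worst)
        mean_abs = corr.mean(axis=0)  # diagonal zeroed; close enough for ranking
        drop = v1 if mean_abs[v1] > mean_abs[v2] else v2
        if mean_abs[v1] == mean_abs[v2]:
            drop = max(v1, v2)  # deterministic tie-break
        keep_partner = v2 if drop == v1 else v1
        report_rows.append((drop, keep_partner, r, f"|r|>{threshold} with {keep_partner}"))
        kept = kept.drop(columns=[drop])

    report = pd.DataFrame(report_rows, columns=["dropped", "partner", "r", "reason"])
    return kept, report


def standardize(env: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """z-score each column (sample sd, n−1). Returns (z, means, sds)."""
    means = env.mean()
    sds = env.std(ddof=1)
    bad = sds[sds == 0].index.tolist()
    if bad:
        raise ValueError(f"constant column(s) {bad}: prune before standardizing")
    return (env - means) / sds, means, sds


def destandardize(z: pd.DataFrame, means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    return z * sds + means


@dataclass
class RdaResult:
    proportion_explained: float
    canonical_variance: float
    total_variance: float
    eigenvalues: np.ndarray
    n_samples: int
    n_predictors: int

    def to_dict(self) -> dict:
        return {
            "proportion_explained": self.proportion_explained,
            "canonical_variance": self.canonical_variance,
            "total_variance": self.total_variance,
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "n_samples": self.n_samples,
            "n_predictors": self.n_predictors,
        }


def _as_matrix(df) -> np.ndarray:
    return np.asarray(df, dtype=float)


def rda(Y, X) -> RdaResult:
    """Redundancy analysis of response Y (cells × species) on predictors X.

    Both matrices are centered internally; callers normally pass z-scored
    tables. Raises on rank-deficient X, naming the dependent columns.
    """
    Ym = _as_matrix(Y)
    Xm = _as_matrix(X)
    if Ym.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X row counts differ")
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than predictors ({p})")

    Yc = Ym - Ym.mean(axis=0)
    Xc = Xm - Xm.mean(axis=0)

    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        names = list(X.columns) if hasattr(X, "columns") else [str(i) for i in range(p)]
        # QR with pivoting flags the columns that add no rank
        from scipy.linalg import qr

        _, R, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
        dep = sorted(names[piv[i]] for i in range(p) if i >= rank or diag[i] < tol)
        raise ValueError(f"rank-deficient predictor matrix; dependent columns: {dep}")

    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ B
    total = float(np.sum(Yc * Yc))
    canonical = float(np.sum(fitted * fitted))
    prop = canonical / total if total > 0 else 0.0
    cov_fit = fitted.T @ fitted / max(n - 1, 1)
    eig = np.linalg.eigvalsh(cov_fit)[::-1]
    eig = np.clip(eig, 0.0, None)[: min(p, Ym.shape[1])]
    return RdaResult(
        proportion_explained=prop,
        canonical_variance=canonical,
        total_variance=total,
        eigenvalues=eig,
        n_samples=n,
        n_predictors=p,
    )


def _rss(Yc: np.ndarray, Q: np.ndarray | None) -> float:
    """Total residual sum of squares of centered Y on the column space Q."""
    total = float(np.sum(Yc * Yc))
    if Q is None or Q.size == 0:
        return total
    proj = Q.T @ Yc
    return total - float(np.sum(proj * proj))


def _aic(n: int, rss: float, p: int) -> float:
    """Gaussian-likelihood AIC of the multivariate fit, used as the
    forward-selection ranking statistic: n·ln(RSS/n) + 2(p+1)."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (p + 1)


@dataclass
class ForwardSelectResult:
    steps: pd.DataFrame  # variable, df, aic, f, p, cum_proportion
    selected: list[str]
    proportion_explained: float
    total_variance: float
    permutations: int
    alpha: float

    def write_csv(self, path) -> None:
        self.steps.to_csv(path, index=False, float_format="%.6g")

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "proportion_explained": self.proportion_explained,
            "total_variance": self.total_variance,
            "permutations": self.permutations,
            "alpha": self.alpha,
            "steps": self.steps.to_dict(orient="records"),
        }


def forward_select(
    Y,
    X,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    max_steps: int | None = None,
    require_aic_improvement: bool = True,
) -> ForwardSelectResult:
    """AIC-ranked forward selection of RDA predictors with permutation tests.

    At each step every unused variable is scored by the AIC of the model
    that adds it; the best (lowest-AIC) candidate is admitted if it improves
    the current AIC and its marginal pseudo-F,

        F = Δ(canonical variance) / (RSS_full / (n − p − 1)),

    is significant (p ≤ alpha) under unrestricted row permutation of Y,
    p = (#{F_perm ≥ F_obs} + 1)/(P + 1). Selection stops at the first
    rejected candidate. ``require_aic_improvement`` (default) additionally
    stops once the best candidate no longer lowers the model AIC — the
    parsimony stop; with ``alpha=1`` the procedure is then AIC-only and the
    recorded AIC path is monotone non-increasing. Disable it to calibrate
    or study the permutation gate in isolation.
    """
    Ym = _as_matrix(Y)
    names = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(X.shape[1])]
    Xm = _as_matrix(X)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    Xc = Xm - Xm.mean(axis=0)
    total = float(np.sum(Yc * Yc))
    if total == 0:
        raise ValueError("response matrix has zero variance")

    rng = np.random.default_rng(seed)
    selected: list[int] = []
    rows = []
    current_aic = _aic(n, total, 0)
    current_rss = total
    limit = max_steps if max_steps is not None else len(names)

    while len(selected) < min(limit, len(names)):
        remaining = [j for j in range(len(names)) if j not in selected]
        if not remaining:
            break
        best_j, best_aic, best_rss, best_Q = None, np.inf, None, None
        for j in remaining:
            cols = Xc[:, selected + [j]]
            Q, _ = np.linalg.qr(cols)
            rss = _rss(Yc, Q)
            aic = _aic(n, rss, len(selected) + 1)
            if aic < best_aic:
                best_j, best_aic, best_rss, best_Q = j, aic, rss, Q

        if best_j is None:
            break
        if require_aic_improvement and best_aic >= current_aic:
            break

        p_new = len(selected) + 1
        dof = n - p_new - 1
        if dof <= 0:
            break
        delta_can = current_rss - best_rss
        f_obs = delta_can / (best_rss / dof) if best_rss > 0 else np.inf

        # permutation null: same reduced and full spaces, permuted Y rows
        Q_red = None
        if selected:
            Q_red, _ = np.linalg.qr(Xc[:, selected])
        perm_f = np.empty(permutations)
        for b in range(permutations):
            Yp = Yc[rng.permutation(n)]
            rss_red = _rss(Yp, Q_red)
            rss_full = _rss(Yp, best_Q)
            perm_f[b] = (rss_red - rss_full) / (rss_full / dof) if rss_full > 0 else np.inf
        p_val = (np.count_nonzero(perm_f >= f_obs) + 1) / (permutations + 1)

        if p_val > alpha:
            break

        selected.append(best_j)
        current_aic, current_rss = best_aic, best_rss
        rows.append(
            (
                names[best_j],
                1,
                float(best_aic),
                float(f_obs),
                float(p_val),
                float(1.0 - current_rss / total),
            )
        )

    if not rows:
        warnings.warn("forward selection admitted no variable")
    steps = pd.DataFrame(rows, columns=["variable", "df", "aic", "f", "p", "cum_proportion"])
    return ForwardSelectResult(
        steps=steps,
        selected=[names[j] for j in selected],
        proportion_explained=float(1.0 - current_rss / total),
        total_variance=total,
        permutations=permutations,
        alpha=alpha,
    )
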