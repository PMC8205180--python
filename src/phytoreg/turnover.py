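"""Beta-Simpson (βSim) species turnover between grid cells.

βSim(i, j) = 1 − a / (a + min(b, c)), where a is the number of species
shared by cells i and j, b the number found only in i and c the number found
only in j. Taking min(b, c) makes the index insensitive to richness
imbalance: a cell whose assemblage is nested inside another's scores 0, so
βSim isolates true spatial replacement of species. Values near 0 mean most
taxa are shared; values above ~0.8 mean almost complete turnover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = ["beta_sim", "turnover_matrix", "write_matrix_csv", "read_matrix_csv"]


def beta_sim(species_i: set, species_j: set) -> float:
    """βSim between two species sets; raises if both are empty (0/0)."""
    si, sj = set(species_i), set(species_j)
    if not si and not sj:
        raise ValueError("beta_sim undefined for two empty species sets")
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    if min(b, c) == 0:
        # nested assemblages (incl. one empty set): no spatial replacement
        return 0.0
    return 1.0 - a / (a + min(b, c))


def turnover_matrix(incidence: pd.DataFrame) -> DistanceMatrix:
    """Pairwise βSim over all rows of a presence/absence matrix.

    Vectorized with incidence linear algebra: shared counts a = M Mᵀ and
    b, c from row richness. Returns a labelled, validated
    :class:`skbio.DistanceMatrix`.
    """
    if incidence.shape[0] < 2:
        raise ValueError("need at least two cells")
    M = (incidence.to_numpy() > 0).astype(np.int64)
    richness = M.sum(axis=1)
    empty = np.where(richness == 0)[0]
    if empty.size:
        raise ValueError(f"cell(s) with zero species: {list(incidence.index[empty])}")

    a = M @ M.T
    b = richness[:, None] - a
    c = richness[None, :] - a
    d = 1.0 - a / (a + np.minimum(b, c))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float wobble
    return DistanceMatrix(d, ids=list(incidence.index))


def write_matrix_csv(dm: DistanceMatrix, path) -> None:
    """Square labelled CSV (header row and column of cell ids)."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, index_label="cell_id", float_format="%.10g"
    )


def read_matrix_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
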