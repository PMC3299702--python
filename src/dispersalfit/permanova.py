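"""Nested two-factor PERMANOVA on a dissimilarity matrix.

Partitions the total sum of squared dissimilarities for a balanced design
with a fixed station factor and a random island factor nested in station
(panels as replicates within islands):

    SS_total    = (1/N) * sum_{i<j} d_ij^2
    SS_station  = SS_total - sum_stations SS_within(station)
    SS_island   = sum_stations SS_within(station) - SS_residual
    SS_residual = sum_islands SS_within(island)

with SS_within(g) = (1/n_g) * sum_{i<j in g} d_ij^2. Expected mean squares
give pseudo-F(station) = MS_station / MS_island and pseudo-F(island) =
MS_island / MS_residual. P-values come from seeded permutations appropriate
to each stratum: whole islands are permuted across stations for the station
test (islands are the exchangeable units under no station effect), and
observations are permuted among islands within their station for the island
test. p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1).

With Euclidean distances on univariate data this partition reproduces the
classical nested mixed-model ANOVA exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "bray_curtis",
    "dissimilarity_matrix",
    "permanova_nested",
    "PermanovaTable",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1].

    Defined as 0 when both abundance vectors are entirely zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    denom = np.sum(x + y)
    if denom == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / denom)


def dissimilarity_matrix(data, metric: str = "braycurtis") -> np.ndarray:
    """Pairwise dissimilarities between sample rows.

    ``data`` is (n_samples, n_variables); univariate counts may be passed as
    a 1-d array and are treated as length-1 abundance vectors.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    out = np.zeros((n, n))
    if metric == "braycurtis":
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(arr[i], arr[j])
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        out = squareform(pdist(arr, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return out


@dataclass(frozen=True)
class PermanovaTable:
    """Source table mirroring PRIMER-style PERMANOVA output."""

    table: pd.DataFrame
    n_permutations: int

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    # canonical (sorted-label) group order keeps the seeded permutation
    # stream aligned across row reorderings of the same data
    return [np.flatnonzero(labels == g) for g in sorted(pd.unique(labels), key=str)]


def _ss_within(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    return sum(float(d2[np.ix_(g, g)].sum()) / (2.0 * len(g)) for g in groups)


def _check_balanced(stations: np.ndarray, cells: np.ndarray) -> tuple[int, int, int]:
    """Return (a stations, b islands/station, n panels/island); raise if the
    design is unbalanced or islands are not nested in stations."""
    df = pd.DataFrame({"station": stations, "cell": cells})
    st_per_cell = df.groupby("cell")["station"].nunique()
    if (st_per_cell > 1).any():
        raise ValueError("island labels are not nested within stations")
    cells_per_station = df.groupby("station")["cell"].nunique()
    if cells_per_station.nunique() > 1:
        raise ValueError(
            "unbalanced design: stations carry different island counts "
            f"({dict(cells_per_station)}); balance the survey first"
        )
    b = int(cells_per_station.iloc[0])
    if b < 2:
        raise ValueError("need >= 2 islands per station for the nested test")
    panels_per_cell = df.groupby("cell").size()
    if panels_per_cell.nunique() > 1:
        raise ValueError(
            "unbalanced design: islands carry different panel counts "
            f"({dict(panels_per_cell)}); balance the survey first"
        )
    n = int(panels_per_cell.iloc[0])
    a = int(cells_per_station.shape[0])
    return a, b, n


def permanova_nested(
    dism,
    stations,
    islands,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermanovaTable:
    """Nested PERMANOVA: station fixed, island random nested in station.

    Parameters
    ----------
    dism : (N, N) array
        Symmetric dissimilarity matrix over sampling units (panels).
    stations, islands : length-N label sequences
        Island labels need not be globally unique; they are nested within
        stations internally.
    n_permutations : int
        Permutations per test; observed statistic always included in the
        reference set.
    seed : int, optional
        Seed for the permutation generator.
    """
    d = np.asarray(dism, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    stations = np.asarray(stations)
    islands = np.asarray(islands)
    if len(stations) != d.shape[0] or len(islands) != d.shape[0]:
        raise ValueError("labels must match matrix size")
    cells = np.array([f"{s}||{i}" for s, i in zip(stations, islands)])
    a, b, n = _check_balanced(stations, cells)
    N = d.shape[0]
    d2 = d**2

    station_groups = _group_indices(stations)
    cell_groups = _group_indices(cells)

    ss_total = float(d2.sum()) / (2.0 * N)
    ss_within_st = _ss_within(d2, station_groups)
    ss_res = _ss_within(d2, cell_groups)
    ss_station = ss_total - ss_within_st
    ss_island = ss_within_st - ss_res

    df_station = a - 1
    df_island = a * (b - 1)
    df_res = a * b * (n - 1)
    ms_station = ss_station / df_station
    ms_island = ss_island / df_island
    ms_res = ss_res / df_res
    f_station = ms_station / ms_island
    f_island = ms_island / ms_res

    rng = np.random.default_rng(seed)

    # Station test: permute whole islands across stations. Precompute the
    # island-block sums of d2 so each permutation costs O((a*b)^2).
    n_cells = len(cell_groups)
    block = np.empty((n_cells, n_cells))
    for i, gi in enumerate(cell_groups):
        for j, gj in enumerate(cell_groups):
            block[i, j] = d2[np.ix_(gi, gj)].sum()
    station_order = sorted(pd.unique(stations), key=str)
    cell_order = sorted(pd.unique(cells), key=str)
    st_index = {s: i for i, s in enumerate(map(str, station_order))}
    cell_station = np.array(
        [st_index[str(c).split("||")[0]] for c in cell_order]
    )
    n_per_station = b * n
    exceed_station = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_cells)
        ss_w = 0.0
        for s in range(a):
            members = perm[cell_station == s]
            ss_w += block[np.ix_(members, members)].sum() / (2.0 * n_per_station)
        ss_st_p = ss_total - ss_w
        ss_isl_p = ss_w - ss_res  # residual invariant under whole-island moves
        f_p = (ss_st_p / df_station) / (ss_isl_p / df_island)
        exceed_station += f_p >= f_station
    p_station = (exceed_station + 1) / (n_permutations + 1)

    # Island test: permute observations among islands within each station.
    exceed_island = 0
    station_cell_local = [
        np.array([np.flatnonzero(cells[g] == c) for c in pd.unique(cells[g])])
        for g in station_groups
    ]
    for _ in range(n_permutations):
        ss_res_p = 0.0
        for g, local_cells in zip(station_groups, station_cell_local):
            perm_g = g[rng.permutation(len(g))]
            for loc in local_cells:
                members = perm_g[loc]
                ss_res_p += d2[np.ix_(members, members)].sum() / (2.0 * len(loc))
        ss_isl_p = ss_within_st - ss_res_p
        f_p = (ss_isl_p / df_island) / (ss_res_p / df_res)
        exceed_island += f_p >= f_island
    p_island = (exceed_island + 1) / (n_permutations + 1)

    table = pd.DataFrame(
        [
            {
                "source": "station",
                "df": df_station,
                "SS": ss_station,
                "MS": ms_station,
                "pseudo_F": f_station,
                "p_perm": p_station,
                "n_permutations": n_permutations,
            },
            {
                "source": "island_within_station",
                "df": df_island,
                "SS": ss_island,
                "MS": ms_island,
                "pseudo_F": f_island,
                "p_perm": p_island,
                "n_permutations": n_permutations,
            },
            {
                "source": "residual",
                "df": df_res,
                "SS": ss_res,
                "MS": ms_res,
                "pseudo_F": np.nan,
                "p_perm": np.nan,
                "n_permutations": np.nan,
            },
            {
                "source": "total",
                "df": N - 1,
                "SS": ss_total,
                "MS": np.nan,
                "pseudo_F": np.nan,
                "p_perm": np.nan,
                "n_permutations": np.nan,
            },
        ]
    )
    return PermanovaTable(table=table, n_permutations=n_permutations)
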