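"""Deterministic survey arithmetic.

Tow geometry and swept volume, larval densities, subsample extrapolation,
molecular-confirmation fractions, and balancing of the settlement design by
seeded subsampling.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KNOT_IN_M_PER_S",
    "tow_swept_volume",
    "larval_density",
    "extrapolate_total",
    "confirmed_fraction",
    "share_at_stations",
    "balance_design",
]

# 1 international knot = 1.852 km/h exactly.
KNOT_IN_M_PER_S = 1852.0 / 3600.0


def tow_swept_volume(
    speed_knots: float,
    duration_s: float,
    net_diameter_m: float,
    tow_length_m: float | None = None,
) -> float:
    """Volume of water filtered by a plankton tow, in cubic metres.

    Swept volume = tow length x net mouth area, with tow length = boat speed
    x duration and area = pi r^2. Assumes 100% net efficiency.
    ``tow_length_m`` overrides the speed x duration product, for reproducing
    report chains that round the tow length to whole metres before
    multiplying.
    """
    if min(speed_knots, duration_s, net_diameter_m) < 0:
        raise ValueError("speed, duration and net diameter must all be >= 0")
    if tow_length_m is None:
        tow_length_m = speed_knots * KNOT_IN_M_PER_S * duration_s
    elif tow_length_m < 0:
        raise ValueError("tow length must be >= 0")
    area = math.pi * (net_diameter_m / 2.0) ** 2
    return tow_length_m * area


def larval_density(total_count: float, total_volume_m3: float) -> float:
    """Larvae per cubic metre of seawater filtered."""
    if total_volume_m3 <= 0:
        raise ValueError("total volume must be > 0 m^3")
    if total_count < 0:
        raise ValueError("count must be >= 0")
    return total_count / total_volume_m3


def extrapolate_total(counted: float, examined_fraction: float) -> float:
    """Estimated total count when only a fraction of the sample was examined.

    Returns the real-valued estimate counted / fraction; integer reporting
    should truncate toward zero.
    """
    if not 0.0 < examined_fraction <= 1.0:
        raise ValueError("examined_fraction must lie in (0, 1]")
    if counted < 0:
        raise ValueError("counted must be >= 0")
    return counted / examined_fraction


def confirmed_fraction(n_confirmed: float, n_assayed: float) -> float:
    """Proportion of assayed individuals confirmed as the focal species."""
    if n_assayed <= 0:
        raise ValueError("n_assayed must be > 0")
    if not 0 <= n_confirmed <= n_assayed:
        raise ValueError("need 0 <= n_confirmed <= n_assayed")
    return n_confirmed / n_assayed


def share_at_stations(
    records: pd.DataFrame,
    station_subset: Iterable[str],
    column: str = "n_confirmed",
) -> float:
    """Share of all confirmed individuals found at a subset of stations.

    E.g. the fraction of confirmed settlers recorded at the stations closest
    to the source.
    """
    subset = set(station_subset)
    total = records[column].sum()
    if total <= 0:
        raise ValueError("no confirmed individuals in records")
    at_subset = records.loc[records["station_id"].isin(subset), column].sum()
    return float(at_subset) / float(total)


def balance_design(
    records: pd.DataFrame,
    n_islands_keep: int,
    n_panels_keep: int,
    seed: int,
) -> pd.DataFrame:
    """Subsample a settlement survey to a balanced design.

    For every station, keeps ``n_islands_keep`` islands chosen uniformly at
    random among islands carrying at least ``n_panels_keep`` panels, then
    ``n_panels_keep`` panels uniformly within each kept island, so the output
    has exactly ``n_islands_keep * n_panels_keep`` rows per station. Raises if
    any station cannot supply the requested replication, naming the station.
    """
    rng = np.random.default_rng(seed)
    kept: list[pd.DataFrame] = []
    for station_id, st_rows in records.groupby("station_id", sort=True):
        panel_counts = st_rows.groupby("island_id")["panel_id"].count()
        eligible = sorted(panel_counts.index[panel_counts >= n_panels_keep])
        if len(eligible) < n_islands_keep:
            raise ValueError(
                f"station {station_id}: only {len(eligible)} island(s) with >= "
                f"{n_panels_keep} panels, need {n_islands_keep}"
            )
        islands = rng.choice(eligible, size=n_islands_keep, replace=False)
        for island in sorted(islands):
            isl_rows = st_rows[st_rows["island_id"] == island]
            idx = rng.choice(len(isl_rows), size=n_panels_keep, replace=False)
            kept.append(isl_rows.iloc[np.sort(idx)])
    return pd.concat(kept, ignore_index=True)


def survey_summary(
    plankton: pd.DataFrame,
    settlement: pd.DataFrame | None = None,
    close_stations: Sequence[str] = ("S1", "S2", "S3"),
) -> dict:
    """Headline survey quantities: swept volumes, extrapolated larval totals,
    overall density, and confirmation fractions."""
    volumes = [
        tow_swept_volume(r.speed_knots, r.duration_s, r.net_diameter_m)
        for r in plankton.itertuples()
    ]
    total_volume = float(np.sum(volumes))
    counted = float(plankton["counted_larvae"].sum())
    extrapolated = [
        extrapolate_total(r.counted_larvae, r.examined_fraction)
        for r in plankton.itertuples()
    ]
    total_larvae = float(np.sum(extrapolated))
    out: dict = {
        "n_tows": int(len(plankton)),
        "total_swept_volume_m3": total_volume,
        "counted_larvae": counted,
        "estimated_total_larvae": total_larvae,
        "larval_density_per_m3": larval_density(total_larvae, total_volume)
        if total_volume > 0
        else None,
        "plankton_confirmed_fraction": (
            confirmed_fraction(
                plankton["n_confirmed"].sum(), plankton["n_assayed"].sum()
            )
            if plankton["n_assayed"].sum() > 0
            else None
        ),
    }
    if settlement is not None:
        n_conf = int(settlement["n_confirmed"].sum())
        out["n_panels"] = int(len(settlement))
        out["total_settlers"] = int(settlement["total_gastropods"].sum())
        out["confirmed_settlers"] = n_conf
        out["confirmed_share_close_stations"] = (
            share_at_stations(settlement, close_stations) if n_conf > 0 else None
        )
    return out
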