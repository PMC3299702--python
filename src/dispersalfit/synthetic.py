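"""Synthetic settlement and plankton surveys with known generating truth.

Counts per elementary sampling unit (settlement panel; plankton tow) are drawn
from a Poisson or negative-binomial distribution whose mean follows the
dispersal kernel at the station's distance from the source. Molecular
confirmation of the focal species is emulated by independent binomial thinning
of each unit's count. Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
import pandas as pd

from .design import KernelTruth, SurveyDesign, TowGeometry
from .kernels import kernel_mean
from .survey import tow_swept_volume

__all__ = ["gen_settlement", "gen_plankton", "truth_manifest"]

SETTLEMENT_COLUMNS = [
    "station_id",
    "distance_km",
    "island_id",
    "panel_id",
    "total_gastropods",
    "n_confirmed",
]

PLANKTON_COLUMNS = [
    "station_id",
    "distance_km",
    "tow_id",
    "speed_knots",
    "duration_s",
    "net_diameter_m",
    "examined_fraction",
    "counted_larvae",
    "n_assayed",
    "n_confirmed",
]


def _draw_counts(
    rng: np.random.Generator, mu: float, size: int, dispersion: float | None
) -> np.ndarray:
    """Poisson(mu) or negative-binomial(mean mu, size theta) counts."""
    if mu == 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion is None:
        return rng.poisson(mu, size=size).astype(np.int64)
    theta = float(dispersion)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p, size=size).astype(np.int64)


def _check_power_distances(truth: KernelTruth, design: SurveyDesign) -> None:
    if truth.family == "power" and any(d <= 0 for d in design.distances_km):
        raise ValueError("power-law kernel is undefined at distance <= 0")


def gen_settlement(
    design: SurveyDesign, truth: KernelTruth, seed: int
) -> pd.DataFrame:
    """Generate one settlement survey: one row per (station, island, panel).

    ``total_gastropods`` is drawn from the count distribution with mean
    mu(D_station); ``n_confirmed`` is a binomial thinning of the total by the
    station's id_probability.
    """
    _check_power_distances(truth, design)
    rng = np.random.default_rng(seed)
    rows: list[tuple[Any, ...]] = []
    for st in design.stations:
        mu = kernel_mean(truth.family, truth.intercept, truth.slope, st.distance_km)
        p_id = truth.id_prob_for(st.station_id)
        for i in range(st.n_islands):
            totals = _draw_counts(rng, mu, st.panels_per_island, truth.dispersion)
            confirmed = rng.binomial(totals, p_id)
            for j, (tot, conf) in enumerate(zip(totals, confirmed)):
                rows.append(
                    (
                        st.station_id,
                        st.distance_km,
                        f"{st.station_id}-AI{i + 1}",
                        f"P{j + 1}",
                        int(tot),
                        int(conf),
                    )
                )
    return pd.DataFrame(rows, columns=SETTLEMENT_COLUMNS)


def gen_plankton(
    design: SurveyDesign,
    truth: KernelTruth,
    tow_geometry: TowGeometry | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one plankton survey: one row per (station, tow).

    ``counted_larvae`` has mean mu(D_station) per tow. Per station, at most
    ``assay_cap_per_station`` larvae are assayed for species identity; the
    assayed individuals are allocated across the station's tows in proportion
    to their counts (multivariate hypergeometric draw), and ``n_confirmed``
    thins the assayed subset binomially. A zero-duration tow sweeps no water
    and is forced to zero larvae.
    """
    geom = tow_geometry or TowGeometry()
    _check_power_distances(truth, design)
    rng = np.random.default_rng(seed)
    swept = tow_swept_volume(geom.speed_knots, geom.duration_s, geom.net_diameter_m)
    rows: list[tuple[Any, ...]] = []
    for st in design.stations:
        if st.n_tows == 0:
            continue
        mu = kernel_mean(truth.family, truth.intercept, truth.slope, st.distance_km)
        if swept == 0.0:
            counts = np.zeros(st.n_tows, dtype=np.int64)
        else:
            counts = _draw_counts(rng, mu, st.n_tows, truth.dispersion)
        n_assay_station = min(int(counts.sum()), geom.assay_cap_per_station)
        if n_assay_station > 0:
            assayed = rng.multivariate_hypergeometric(counts, n_assay_station)
        else:
            assayed = np.zeros(st.n_tows, dtype=np.int64)
        p_id = truth.id_prob_for(st.station_id)
        confirmed = rng.binomial(assayed, p_id)
        for t in range(st.n_tows):
            rows.append(
                (
                    st.station_id,
                    st.distance_km,
                    f"T{t + 1}",
                    geom.speed_knots,
                    geom.duration_s,
                    geom.net_diameter_m,
                    geom.examined_fraction,
                    int(counts[t]),
                    int(assayed[t]),
                    int(confirmed[t]),
                )
            )
    return pd.DataFrame(rows, columns=PLANKTON_COLUMNS)


def truth_manifest(
    truth: KernelTruth, design: SurveyDesign, seed: int
) -> dict[str, Any]:
    """JSON-serialisable record of the exact generating conditions.

    Regenerating with the parameters and seed in the manifest reproduces the
    dataset bit-for-bit; recovery tests compare estimates against it.
    """
    id_prob = truth.id_probability
    if not isinstance(id_prob, (int, float)):
        id_prob = dict(id_prob)
    return {
        "family": truth.family,
        "intercept": truth.intercept,
        "slope": truth.slope,
        "dispersion": truth.dispersion,
        "id_probability": id_prob,
        "count_unit": "per elementary sampling unit (settlement panel / plankton tow)",
        "seed": int(seed),
        "stations": [
            {
                "station_id": s.station_id,
                "distance_km": s.distance_km,
                "n_islands": s.n_islands,
                "panels_per_island": s.panels_per_island,
                "n_tows": s.n_tows,
            }
            for s in design.stations
        ],
    }


def manifest_to_json(manifest: dict[str, Any]) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)


def design_from_manifest(manifest: dict[str, Any]) -> SurveyDesign:
    from .design import Station

    return SurveyDesign(
        tuple(
            Station(
                s["station_id"],
                s["distance_km"],
                s["n_islands"],
                s["panels_per_island"],
                s["n_tows"],
            )
            for s in manifest["stations"]
        )
    )


def truth_from_manifest(manifest: dict[str, Any]) -> KernelTruth:
    return KernelTruth(
        family=manifest["family"],
        intercept=manifest["intercept"],
        slope=manifest["slope"],
        dispersion=manifest["dispersion"],
        id_probability=manifest["id_probability"],
    )
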