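"""Survey design and generating-truth descriptions.

A survey consists of stations placed at increasing distances from a larval
source population. Each station carries replicate artificial islands (AIs,
moored floating habitat mimics), each AI carries settlement panels, and each
station is additionally sampled with replicate plankton tows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Station",
    "SurveyDesign",
    "KernelTruth",
    "TowGeometry",
    "default_design",
    "DEFAULT_DISTANCES_KM",
    "DEFAULT_ID_PROBABILITIES",
]

#: Station distances (km) from the source used throughout: the station inside
#: continuous source habitat is carried at 0.05 km so that power-law kernels
#: (undefined at D = 0) remain evaluable.
DEFAULT_DISTANCES_KM = (0.05, 0.5, 5.0, 15.0, 50.0)

#: Default per-station probability that an individual gastropod is the focal
#: species (molecular confirmation rate), nearest to farthest station.
DEFAULT_ID_PROBABILITIES = (0.08, 0.12, 0.08, 0.04, 0.04)


@dataclass(frozen=True)
class Station:
    station_id: str
    distance_km: float
    n_islands: int = 2
    panels_per_island: int = 8
    n_tows: int = 3

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValueError(
                f"station {self.station_id}: distance must be > 0 km "
                f"(got {self.distance_km})"
            )
        if self.n_islands < 1 or self.panels_per_island < 1:
            raise ValueError(
                f"station {self.station_id}: settlement replication must be >= 1"
            )
        if self.n_tows < 0:
            raise ValueError(f"station {self.station_id}: n_tows must be >= 0")


@dataclass(frozen=True)
class SurveyDesign:
    """Stations with their replication structure.

    Distances must be strictly positive and strictly increasing in station
    order.
    """

    stations: tuple[Station, ...]

    def __post_init__(self) -> None:
        if not self.stations:
            raise ValueError("design needs at least one station")
        d = [s.distance_km for s in self.stations]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("station distances must be strictly increasing")

    @property
    def distances_km(self) -> tuple[float, ...]:
        return tuple(s.distance_km for s in self.stations)

    @property
    def n_panels_total(self) -> int:
        return sum(s.n_islands * s.panels_per_island for s in self.stations)


@dataclass(frozen=True)
class KernelTruth:
    """Generating parameters for a synthetic survey.

    ``intercept`` is the expected count per elementary sampling unit (panel or
    tow) at the kernel's reference distance: D = 0 for the exponential family
    (R0) and D = 1 km for the power family (R1). ``dispersion`` is the
    negative-binomial size theta (variance mu + mu^2/theta); ``None`` means
    Poisson counts. ``id_probability`` is the per-individual probability of
    molecular confirmation as the focal species, either a single float or a
    per-station mapping keyed by station_id.
    """

    family: str  # "exponential" | "power"
    intercept: float
    slope: float
    dispersion: float | None = None
    id_probability: float | Mapping[str, float] = field(
        default_factory=lambda: dict(
            zip(("S1", "S2", "S3", "S4", "S5"), DEFAULT_ID_PROBABILITIES)
        )
    )

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "power"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.intercept <= 0:
            raise ValueError("kernel intercept must be > 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be > 0")
        probs = (
            self.id_probability.values()
            if isinstance(self.id_probability, Mapping)
            else [self.id_probability]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("id_probability must lie in [0, 1]")

    def id_prob_for(self, station_id: str) -> float:
        if isinstance(self.id_probability, Mapping):
            try:
                return float(self.id_probability[station_id])
            except KeyError:
                raise KeyError(
                    f"no id_probability given for station {station_id!r}"
                ) from None
        return float(self.id_probability)


@dataclass(frozen=True)
class TowGeometry:
    """Plankton tow geometry: boat speed, tow duration, net mouth diameter."""

    speed_knots: float = 3.0
    duration_s: float = 120.0
    net_diameter_m: float = 0.5
    examined_fraction: float = 0.4
    assay_cap_per_station: int = 50

    def __post_init__(self) -> None:
        if min(self.speed_knots, self.duration_s, self.net_diameter_m) < 0:
            raise ValueError("tow geometry values must be >= 0")
        if not 0.0 < self.examined_fraction <= 1.0:
            raise ValueError("examined_fraction must lie in (0, 1]")


def default_design(
    distances_km: Sequence[float] = DEFAULT_DISTANCES_KM,
    n_islands: int = 2,
    panels_per_island: int = 8,
    n_tows: int = 3,
) -> SurveyDesign:
    """The study layout: 5 stations along a distance gradient, 2 AIs per
    station, 8 panels per AI, 3 plankton tows per station."""
    stations = tuple(
        Station(f"S{i + 1}", float(d), n_islands, panels_per_island, n_tows)
        for i, d in enumerate(distances_km)
    )
    return SurveyDesign(stations)
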