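"""Marine reserve network spacing and connectivity on a 1D coastline.

Reserves are represented as intervals ``[s_start, s_end]`` (km of arc
position along a shared coastline polyline); point reserves are allowed.
Spacing is edge-to-edge arc distance, the 1D counterpart of the
closest-edge distance a GIS measurement would produce.  Gaps are compared
against the per-generation dispersal estimate: a reserve whose nearest
neighbour lies within the dispersal point estimate is classed connected
("within_sigma"), within the upper confidence bound "within_ci", and
beyond that "isolated".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersal import DispersalEstimate

__all__ = [
    "Reserve",
    "SpacingReport",
    "filter_reserves",
    "spacing",
    "network_gap",
    "classify_connectivity",
]


@dataclass
class Reserve:
    """A conservation area collapsed to a coastline interval.

    ``shallow_habitat`` means the area contains habitat above 50 m depth
    (within reach of nearshore rockfish); ``protected`` means rockfish are
    protected from both commercial and recreational take; ``outer_coast``
    excludes inland-sea areas.  A reserve enters the analysis only if all
    three hold.
    """

    name: str
    network: str
    s_start: float
    s_end: float
    area_km2: float | None = None
    shallow_habitat: bool = True
    protected: bool = True
    outer_coast: bool = True

    def __post_init__(self) -> None:
        if self.s_end < self.s_start:
            raise ValueError(f"reserve {self.name}: s_end < s_start")

    def edge_distance(self, other: "Reserve") -> float:
        """Edge-to-edge arc distance; overlapping intervals give 0."""
        if self.s_end < other.s_start:
            return other.s_start - self.s_end
        if other.s_end < self.s_start:
            return self.s_start - other.s_end
        return 0.0


def filter_reserves(raw: pd.DataFrame, depth_limit_m: float = 50.0) -> tuple[list[Reserve], pd.DataFrame]:
    """Apply the three inclusion rules to a raw reserve table.

    Expected columns: ``name, network, s_start_km, s_end_km`` and either
    boolean flags (``shallow_habitat, protected, outer_coast``) or
    ``min_depth_m`` (habitat rule: minimum depth above ``depth_limit_m``)
    plus ``protection``/``outer_coast``.  Returns the included reserves and
    a log of exclusions with the failed rule.
    """
    included: list[Reserve] = []
    log_rows = []
    for _, row in raw.iterrows():
        if "shallow_habitat" in row:
            shallow = bool(row["shallow_habitat"])
        else:
            shallow = float(row["min_depth_m"]) < depth_limit_m
        protected = bool(row.get("protection", row.get("protected", True)))
        outer = bool(row.get("outer_coast", True))
        reasons = []
        if not outer:
            reasons.append("not on the outer coast")
        if not shallow:
            reasons.append(f"no habitat <{depth_limit_m:.0f} m")
        if not protected:
            reasons.append("rockfish not protected from take")
        if reasons:
            log_rows.append(dict(name=row["name"], included=False,
                                 reason="; ".join(reasons)))
            continue
        included.append(
            Reserve(
                name=str(row["name"]),
                network=str(row.get("network", "default")),
                s_start=float(row["s_start_km"]),
                s_end=float(row["s_end_km"]),
                area_km2=float(row["area_km2"]) if "area_km2" in row and pd.notna(row["area_km2"]) else None,
                shallow_habitat=shallow,
                protected=protected,
                outer_coast=outer,
            )
        )
        log_rows.append(dict(name=row["name"], included=True, reason=""))
    return included, pd.DataFrame(log_rows)


@dataclass
class SpacingReport:
    """Nearest-neighbour spacings per reserve plus network summaries."""

    table: pd.DataFrame                 # name, network, spacing_km, neighbor
    network_spacings: dict[str, list[float]]
    areas: dict[str, list[float]]


def spacing(reserves: list[Reserve], k: int = 1) -> SpacingReport:
    """Distance from each reserve to its ``k`` nearest neighbours.

    Distances are symmetric edge-to-edge arc lengths; the report rounds to
    whole km only at presentation time, values here are exact.
    """
    if len(reserves) < 2:
        raise ValueError("spacing needs at least two reserves")
    rows = []
    for i, r in enumerate(reserves):
        dists = sorted(
            ((r.edge_distance(o), o.name) for j, o in enumerate(reserves) if j != i),
        )
        for rank, (d, nm) in enumerate(dists[:k], start=1):
            rows.append(dict(name=r.name, network=r.network, rank=rank,
                             spacing_km=d, neighbor=nm))
    table = pd.DataFrame(rows)
    nn = table[table["rank"] == 1]
    network_spacings = {
        net: sorted(sub["spacing_km"].tolist())
        for net, sub in nn.groupby("network")
    }
    areas = {
        net: sorted(r.area_km2 for r in reserves
                    if r.network == net and r.area_km2 is not None)
        for net in {r.network for r in reserves}
    }
    return SpacingReport(table=table, network_spacings=network_spacings, areas=areas)


def network_gap(network_a: list[Reserve], network_b: list[Reserve]) -> float:
    """Minimum edge-to-edge distance between two reserve networks."""
    if not network_a or not network_b:
        raise ValueError("both networks must be non-empty")
    return min(a.edge_distance(b) for a in network_a for b in network_b)


def classify_connectivity(
    report: SpacingReport,
    dispersal: DispersalEstimate,
) -> pd.DataFrame:
    """Class each reserve's nearest-neighbour gap against dispersal.

    ``spacing <= sigma_point`` -> ``within_sigma`` (connected within one
    generation of average dispersal); ``<= sigma_high`` -> ``within_ci``;
    otherwise ``isolated``.
    """
    nn = report.table[report.table["rank"] == 1].copy()

    def cls(d: float) -> str:
        if d <= dispersal.point:
            return "within_sigma"
        if d <= dispersal.high:
            return "within_ci"
        return "isolated"

    nn["class"] = nn["spacing_km"].map(cls)
    nn["generations"] = nn["spacing_km"] / dispersal.point
    return nn.reset_index(drop=True)
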