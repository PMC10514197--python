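"""Ecosystem-service layers: filling, allocation, zonal stats, rescaling.

Raw service valuations (flood-protected people and property, carbon
density, fishing intensity) arrive as sparse point values on planning
units. The processing chain is:

1. nearest-neighbour fill — units without data take the value of the
   nearest unit with data (centroid distance, ties to the lower unit id);
2. point allocation (coastal-protection style) — each source value is
   converted to a per-km² rate over the group of units sharing it, then
   re-multiplied by each unit's mangrove area, so group totals conserve
   the source value exactly;
3. zonal means and density→stock conversion for carbon and fishing;
4. linear rescaling of the per-unit totals to [0, 1000], the range used
   as optimisation amounts (raw native-unit totals are kept for
   reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .seascape import ServicePointSet


@dataclass
class ServiceFeature:
    """A processed service layer ready to enter the optimisation.

    ``raw_total_by_unit`` is in native units (USD, people, Tg C, fisher
    days yr⁻¹); ``rescaled_by_unit`` is its [0, 1000] linear rescaling,
    used as the amount a_fi. The target is always 100% of the rescaled
    total.
    """

    service_name: str
    unit_ids: np.ndarray
    raw_total_by_unit: np.ndarray
    rescaled_by_unit: np.ndarray
    units_of_measure: str = ""
    target_fraction: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.raw_total_by_unit < 0):
            raise ValueError(f"service {self.service_name!r}: raw totals must be >= 0")
        if np.any((self.rescaled_by_unit < 0) | (self.rescaled_by_unit > 1000 + 1e-9)):
            raise ValueError(f"service {self.service_name!r}: rescaled values outside [0, 1000]")
        if self.target_fraction != 1.0:
            raise ValueError("service features carry a fixed 100% target")


def _centroids(units: pd.DataFrame) -> np.ndarray:
    xy = np.array([[g.centroid.x, g.centroid.y] for g in units["geometry"]])
    return xy


def nn_fill(
    points: Mapping[int, float], units: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    """Fill missing unit values from the nearest unit with data.

    Returns ``(filled, source_id)`` aligned with ``units`` (ascending unit
    id): units with data keep their own value and are their own source;
    missing units take the value of the geometrically nearest unit with
    data (centroid-to-centroid Euclidean distance, ties broken toward the
    lower unit id). The source ids define the sharing groups used by
    :func:`allocate_point_service`.
    """
    if not points:
        raise ValueError("nn_fill: the service layer has no values at all")
    units = units.sort_values("id")
    ids = units["id"].to_numpy(dtype=int)
    unknown = sorted(set(points) - set(ids.tolist()))
    if unknown:
        raise ValueError(f"nn_fill: point values for unknown unit ids {unknown}")
    xy = _centroids(units)
    has = np.array([uid in points for uid in ids])
    donor_idx = np.flatnonzero(has)
    filled = np.empty(len(ids), dtype=float)
    source = np.empty(len(ids), dtype=int)
    filled[has] = [points[uid] for uid in ids[has]]
    source[has] = ids[has]
    missing_idx = np.flatnonzero(~has)
    if missing_idx.size:
        d2 = ((xy[missing_idx, None, :] - xy[None, donor_idx, :]) ** 2).sum(axis=2)
        # argmin returns the first minimum; donor_idx ascends with unit id,
        # so exact ties resolve to the lower unit id
        nearest = donor_idx[np.argmin(d2, axis=1)]
        filled[missing_idx] = filled[nearest]
        source[missing_idx] = ids[nearest]
    return filled, source


def allocate_point_service(
    filled: np.ndarray, source_ids: np.ndarray, units: pd.DataFrame
) -> np.ndarray:
    """Spread each source value over its sharing group by mangrove area.

    The per-km² rate of a group is its source value divided by the group's
    total mangrove area; each unit's total is the rate times its own
    mangrove area, so summing a group recovers the source value exactly.
    Groups with zero total mangrove area are dropped with a warning.
    """
    units = units.sort_values("id")
    areas = units["mangrove_area_km2"].to_numpy(dtype=float)
    ids = units["id"].to_numpy(dtype=int)
    out = np.zeros(len(ids), dtype=float)
    for src in np.unique(source_ids):
        mask = source_ids == src
        group_area = areas[mask].sum()
        value = filled[mask][0]
        if group_area <= 0:
            warnings.warn(
                f"allocate_point_service: group of source unit {src} has zero mangrove "
                "area; its value is dropped",
                stacklevel=2,
            )
            continue
        out[mask] = value / group_area * areas[mask]
    return out


def zonal_mean_density(
    samples: Mapping[int, Sequence[float]], units: pd.DataFrame
) -> np.ndarray:
    """Mean of the density samples overlapping each unit.

    Every unit must carry at least one sample (apply :func:`nn_fill`
    first if the raw layer has gaps). Negative samples are rejected.
    """
    units = units.sort_values("id")
    ids = units["id"].to_numpy(dtype=int)
    if not any(len(samples.get(int(uid), ())) for uid in ids):
        raise ValueError("zonal_mean_density: no samples in any planning unit")
    out = np.empty(len(ids), dtype=float)
    empty = []
    for j, uid in enumerate(ids):
        vals = np.asarray(samples.get(int(uid), ()), dtype=float)
        if vals.size == 0:
            empty.append(int(uid))
            continue
        if np.any(vals < 0):
            raise ValueError(f"zonal_mean_density: negative density sample in unit {uid}")
        out[j] = vals.mean()
    if empty:
        raise ValueError(f"zonal_mean_density: units without samples: {empty}; nn_fill first")
    return out


def density_to_stock(density: np.ndarray, area_km2: np.ndarray) -> np.ndarray:
    """Convert a per-km² density to a per-unit stock (e.g. Tg C km⁻² → Tg C).

    When a layer has separate above-ground and soil components, sum the
    densities before converting.
    """
    return np.asarray(density, dtype=float) * np.asarray(area_km2, dtype=float)


def rescale(values: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1000]; a constant vector maps to zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("rescale: empty input")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("rescale: constant layer rescaled to all zeros", stacklevel=2)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo) * 1000.0


#: which processing chain each standard service layer uses
POINT_ALLOCATED = ("property_usd", "people")
DENSITY_SERVICES = ("carbon_density", "fishing_density")

#: native units of the reported totals per service
SERVICE_TOTAL_UNITS = {
    "property_usd": "USD",
    "people": "people",
    "carbon_density": "Tg C",
    "fishing_density": "fisher days yr-1",
}


def build_service_features(
    services: Mapping[str, ServicePointSet],
    units: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
) -> list[ServiceFeature]:
    """Run each raw layer through its chain and rescale to [0, 1000].

    People and property values are point-allocated (per-km² conversion and
    re-multiplication within nearest-neighbour sharing groups); carbon and
    fishing densities are filled, then converted to per-unit stocks/totals
    by multiplying by mangrove area.
    """
    weights = dict(weights or {})
    units = units.sort_values("id")
    ids = units["id"].to_numpy(dtype=int)
    areas = units["mangrove_area_km2"].to_numpy(dtype=float)
    out = []
    for name in sorted(services):
        layer = services[name]
        filled, source = nn_fill(layer.points, units)
        if name in POINT_ALLOCATED:
            raw = allocate_point_service(filled, source, units)
        else:
            raw = density_to_stock(filled, areas)
        out.append(
            ServiceFeature(
                service_name=name,
                unit_ids=ids,
                raw_total_by_unit=raw,
                rescaled_by_unit=rescale(raw),
                units_of_measure=SERVICE_TOTAL_UNITS.get(name, layer.units_of_measure),
                weight=weights.get(name, 1.0),
            )
        )
    return out
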