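"""Synthetic coastal seascapes for testing the prioritisation pipeline.

Real analyses of this kind run on global GIS layers (mangrove cover,
species ranges, marine provinces, service valuations, protected areas).
This module fabricates a planar stand-in with the same statistical
structure: a strip of hexagonal 20-km planning units along an abstract
coastline, species ranges realised as contiguous runs of units whose
realised areas span several orders of magnitude, ecosystem-service
layers whose spreads differ by service (heavy-tailed for flood-protected
people and property, narrow for carbon density), and per-unit
protected-area coverage fractions.

Everything is driven by one root seed; each component draws from its own
child generator at a fixed offset so that adding a component never
perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from shapely.geometry import Polygon

SERVICE_NAMES = ("property_usd", "people", "carbon_density", "fishing_density")

#: carbon density of mangroves (above-ground biomass + soil), Tg C per km²
MANGROVE_CARBON_DENSITY_TG_PER_KM2 = 0.096

# fixed child-seed offsets (root seed + offset -> component generator)
_SEED_OFFSETS = {
    "areas": 1,
    "zones": 2,
    "typologies": 3,
    "species": 4,
    "services": 5,
    "protection": 6,
    "hotspots": 7,
}


@dataclass(frozen=True)
class ServiceSpec:
    """Distribution of one raw ecosystem-service layer across units.

    family is "lognormal" (location/scale are the log-space mean/sd) or
    "normal" (location/scale are mean/sd, truncated at ``lower``).
    ``missing_rate`` is the fraction of units left without a value, to
    exercise nearest-neighbour filling downstream.
    """

    family: str
    location: float
    scale: float
    units_of_measure: str
    missing_rate: float = 0.3
    lower: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"ServiceSpec.family must be lognormal or normal, got {self.family!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"ServiceSpec.missing_rate must be in [0,1), got {self.missing_rate}")


def default_service_specs() -> Dict[str, ServiceSpec]:
    """Service distributions emulating the published frequency structure.

    People and property safeguarded from flooding vary by many orders of
    magnitude between planning units; carbon density sits in a tight band
    around 0.096 Tg C km⁻²; fishing intensity is moderately skewed.
    """
    return {
        "property_usd": ServiceSpec("lognormal", math.log(5e6), 2.3, "USD"),
        "people": ServiceSpec("lognormal", math.log(500.0), 2.3, "people"),
        "carbon_density": ServiceSpec(
            "normal", MANGROVE_CARBON_DENSITY_TG_PER_KM2, 0.006, "Tg C km-2", lower=0.06
        ),
        "fishing_density": ServiceSpec("lognormal", math.log(200.0), 1.0, "fisher days km-2 yr-1"),
    }


@dataclass(frozen=True)
class SeascapeConfig:
    n_units: int = 500
    unit_spacing_km: float = 20.0
    n_species: int = 30
    range_area_bounds_km2: Tuple[float, float] = (2_000.0, 350_000.0)
    n_typologies: int = 4
    n_provinces: int = 6
    n_zones: int = 8
    mangrove_area_median_km2: float = 1_000.0
    mangrove_area_sigma: float = 0.5
    service_specs: Mapping[str, ServiceSpec] = field(default_factory=default_service_specs)
    protected_fraction_target: float = 0.135
    any_protected_fraction_target: float = 0.43
    smoothing_radius_km: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_units", "n_species", "n_typologies", "n_provinces", "n_zones"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"SeascapeConfig.{name} must be a positive integer, got {value!r}")
        if self.unit_spacing_km <= 0:
            raise ValueError(f"SeascapeConfig.unit_spacing_km must be > 0, got {self.unit_spacing_km}")
        lo, hi = self.range_area_bounds_km2
        if not (0 < lo < hi):
            raise ValueError(
                f"SeascapeConfig.range_area_bounds_km2 must satisfy 0 < min < max, got {(lo, hi)}"
            )
        if self.mangrove_area_median_km2 <= 0:
            raise ValueError("SeascapeConfig.mangrove_area_median_km2 must be > 0")
        for name in ("protected_fraction_target", "any_protected_fraction_target"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"SeascapeConfig.{name} must be in [0,1], got {value}")
        if self.any_protected_fraction_target < self.protected_fraction_target:
            raise ValueError(
                "SeascapeConfig.any_protected_fraction_target must be >= protected_fraction_target"
            )
        if self.smoothing_radius_km < 0:
            raise ValueError("SeascapeConfig.smoothing_radius_km must be >= 0")


@dataclass
class SpeciesRange:
    """A species' occurrence as mangrove area per planning unit."""

    species_id: int
    area_by_unit_km2: Dict[int, float]

    @property
    def member_units(self) -> frozenset:
        return frozenset(self.area_by_unit_km2)

    @property
    def range_area_km2(self) -> float:
        return float(sum(self.area_by_unit_km2.values()))


@dataclass
class ServicePointSet:
    """Sparse raw service values keyed by planning-unit id.

    Units absent from ``points`` are 'missing' and must be filled by
    nearest-neighbour assignment before use.
    """

    service_name: str
    points: Dict[int, float]
    units_of_measure: str

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError(f"ServicePointSet {self.service_name!r} has no values")
        if any(v < 0 for v in self.points.values()):
            raise ValueError(f"ServicePointSet {self.service_name!r} contains negative values")


@dataclass
class SyntheticDataset:
    """One generated seascape: units table, species ranges, service layers."""

    config: SeascapeConfig
    units: "pd.DataFrame"  # noqa: F821 - imported lazily to keep module import light
    species: List[SpeciesRange]
    services: Dict[str, ServicePointSet]
    hotspots: Dict[str, List[int]] = field(default_factory=dict)

    def content_hash(self) -> str:
        """SHA-256 over a canonical JSON serialisation (determinism checks)."""
        payload = {
            "units": {
                col: [repr(v) for v in self.units[col].tolist()]
                for col in self.units.columns
                if col != "geometry"
            },
            "geometry": [list(g.exterior.coords) for g in self.units["geometry"]],
            "species": [
                {str(k): repr(v) for k, v in sorted(s.area_by_unit_km2.items())}
                for s in self.species
            ],
            "services": {
                name: {str(k): repr(v) for k, v in sorted(ps.points.items())}
                for name, ps in sorted(self.services.items())
            },
            "hotspots": {k: sorted(v) for k, v in sorted(self.hotspots.items())},
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _hexagon(cx: float, cy: float, circumradius: float) -> Polygon:
    angles = np.deg2rad(np.arange(30, 390, 60))
    return Polygon(zip(cx + circumradius * np.cos(angles), cy + circumradius * np.sin(angles)))


def _contiguous_labels(n_units: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Partition 0..n_units-1 into up to n_groups contiguous segments."""
    n_groups = min(n_groups, n_units)
    if n_groups == 1:
        return np.zeros(n_units, dtype=int)
    cuts = np.sort(rng.choice(np.arange(1, n_units), size=n_groups - 1, replace=False))
    labels = np.zeros(n_units, dtype=int)
    labels[cuts] = 1
    return np.cumsum(labels)


def _run_labels(n_units: int, n_labels: int, mean_run: float, rng: np.random.Generator) -> np.ndarray:
    """Random label per geometric-length run (spatially clumped categories)."""
    labels = np.empty(n_units, dtype=int)
    i = 0
    while i < n_units:
        run = int(rng.geometric(1.0 / mean_run))
        labels[i : i + run] = rng.integers(0, n_labels)
        i += run
    return labels


def _range_targets(config: SeascapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Range-area spectrum, log-uniform between bounds with anchored extremes.

    The smallest and largest species sit exactly at the configured bounds
    so the spectrum always spans them regardless of seed.
    """
    lo, hi = config.range_area_bounds_km2
    n = config.n_species
    if n == 1:
        return np.array([math.sqrt(lo * hi)])
    middle = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n - 2))
    return np.concatenate([[lo], np.sort(middle), [hi]])


def _realise_range(
    target_km2: float, areas: np.ndarray, start: int
) -> Dict[int, float]:
    """Contiguous run of units summing (up to a partial last unit) to target.

    Extends rightward from ``start``; once the end of the strip is hit it
    continues leftward from ``start - 1``, so the run stays contiguous.
    """
    n = len(areas)
    order = list(range(start, n)) + list(range(start - 1, -1, -1))
    out: Dict[int, float] = {}
    remaining = target_km2
    for idx in order:
        take = min(areas[idx], remaining)
        if take <= 0:
            break
        out[idx] = float(take)
        remaining -= take
        if remaining <= 1e-12:
            break
    return out


def _draw_service(
    spec: ServiceSpec, n_units: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.family == "lognormal":
        return rng.lognormal(spec.location, spec.scale, size=n_units)
    values = rng.normal(spec.location, spec.scale, size=n_units)
    return np.clip(values, spec.lower, None)


def _smooth(values: np.ndarray, centroids_x: np.ndarray, radius_km: float) -> np.ndarray:
    if radius_km <= 0:
        return values
    out = np.empty_like(values)
    for i, x in enumerate(centroids_x):
        mask = np.abs(centroids_x - x) <= radius_km
        out[i] = values[mask].mean()
    return out


def generate_seascape(config: SeascapeConfig) -> SyntheticDataset:
    """Generate one deterministic synthetic seascape from ``config``.

    Returns the units table (id, geometry, mangrove_area_km2, protection
    fractions, typology/province/zone labels), species ranges realised as
    contiguous runs, and sparse raw service layers with deliberate gaps.
    """
    import pandas as pd

    n = config.n_units
    rngs = {
        name: np.random.default_rng(config.seed + off) for name, off in _SEED_OFFSETS.items()
    }

    circumradius = config.unit_spacing_km / math.sqrt(3.0)
    centroids_x = np.arange(n, dtype=float) * config.unit_spacing_km
    geometry = [_hexagon(x, 0.0, circumradius) for x in centroids_x]

    areas = rngs["areas"].lognormal(
        math.log(config.mangrove_area_median_km2), config.mangrove_area_sigma, size=n
    )

    province = _contiguous_labels(n, config.n_provinces, rngs["zones"])
    zone = _contiguous_labels(n, config.n_zones, rngs["zones"])
    typology = _run_labels(n, config.n_typologies, mean_run=5.0, rng=rngs["typologies"])

    # protection fractions: strict <= any; hit both >=0.5 coverage targets
    rng_p = rngs["protection"]
    strict_hi = rng_p.random(n) < config.protected_fraction_target
    strict = np.where(strict_hi, rng_p.uniform(0.5, 1.0, n), rng_p.uniform(0.0, 0.5, n))
    p_extra = (config.any_protected_fraction_target - config.protected_fraction_target) / max(
        1.0 - config.protected_fraction_target, 1e-12
    )
    any_hi = strict_hi | (rng_p.random(n) < p_extra)
    any_frac = np.where(
        any_hi,
        np.maximum(strict, rng_p.uniform(0.5, 1.0, n)),
        strict + rng_p.random(n) * (0.5 - np.minimum(strict, 0.5)) * 0.9,
    )
    any_frac = np.clip(np.maximum(any_frac, strict), 0.0, 1.0)

    units = pd.DataFrame(
        {
            "id": np.arange(n),
            "geometry": geometry,
            "mangrove_area_km2": areas,
            "strict_protected_fraction": strict,
            "any_protected_fraction": any_frac,
            "province_id": province,
            "zone_id": zone,
            "typology_id": typology,
        }
    )

    rng_s = rngs["species"]
    targets = _range_targets(config, rng_s)
    species = []
    for sid, target in enumerate(targets):
        start = int(rng_s.integers(0, n))
        species.append(SpeciesRange(sid, _realise_range(float(target), areas, start)))

    rng_v = rngs["services"]
    services: Dict[str, ServicePointSet] = {}
    for name in sorted(config.service_specs):
        spec = config.service_specs[name]
        values = _draw_service(spec, n, rng_v)
        values = _smooth(values, centroids_x, config.smoothing_radius_km)
        missing = rng_v.random(n) < spec.missing_rate
        if missing.all():
            missing[0] = False
        points = {int(i): float(values[i]) for i in range(n) if not missing[i]}
        services[name] = ServicePointSet(name, points, spec.units_of_measure)

    return SyntheticDataset(config=config, units=units, species=species, services=services)


def plant_hotspots(
    dataset: SyntheticDataset,
    k: int,
    multiplier: float,
    service_name: str,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Multiply the named service at ``k`` random units-with-data by ``multiplier``.

    Returns a new dataset; planted unit ids are recorded under
    ``dataset.hotspots[service_name]`` as ground truth for recovery tests.
    """
    if service_name not in dataset.services:
        raise ValueError(f"unknown service {service_name!r}; have {sorted(dataset.services)}")
    if multiplier <= 0:
        raise ValueError(f"multiplier must be > 0, got {multiplier}")
    if k > len(dataset.units):
        raise ValueError(f"k={k} exceeds the number of planning units")
    layer = dataset.services[service_name]
    candidates = sorted(layer.points)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} units with data for {service_name!r}")
    root = dataset.config.seed if seed is None else seed
    rng = np.random.default_rng(root + _SEED_OFFSETS["hotspots"])
    chosen = sorted(int(i) for i in rng.choice(candidates, size=k, replace=False))
    points = dict(layer.points)
    for uid in chosen:
        points[uid] = points[uid] * multiplier
    services = dict(dataset.services)
    services[service_name] = ServicePointSet(service_name, points, layer.units_of_measure)
    hotspots = {**dataset.hotspots, service_name: chosen}
    return replace(dataset, services=services, hotspots=hotspots)
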