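"""Biodiversity conservation features and range-size-scaled targets.

Each mangrove species' distribution is split into sub-features by
intersecting it with the biophysical typology and marine province of
each planning unit, so that the heterogeneity of mangrove communities
across biogeographic settings is represented explicitly. Every
sub-feature receives a conservation target: the fraction of its area
the reserve system should hold, interpolated on a log10 scale from the
species' range size — 100% for very restricted species (range below
10,000 km²) sliding down to 10% for widespread ones (above 250,000 km²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .seascape import SpeciesRange
from .services import ServiceFeature

logger = logging.getLogger(__name__)

#: sub-features with less area than this are dropped as degenerate
MIN_SUBFEATURE_AREA_KM2 = 1e-6


class InfeasibleBudgetError(ValueError):
    """Locked-in units cost more than the budget allows.

    Raise the budget floor (e.g. start the budget grid at the fraction of
    total area already locked in) and rebuild the problem.
    """


@dataclass(frozen=True)
class TargetRule:
    """Log10-linear interpolation of representation targets from range size."""

    lower_threshold_km2: float = 10_000.0
    upper_threshold_km2: float = 250_000.0
    max_target: float = 1.00
    min_target: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.lower_threshold_km2 < self.upper_threshold_km2:
            raise ValueError("TargetRule thresholds must satisfy 0 < lower < upper")
        if not 0 < self.min_target < self.max_target <= 1:
            raise ValueError("TargetRule targets must satisfy 0 < min_target < max_target <= 1")


def assign_target(range_area_km2: float, rule: TargetRule = TargetRule()) -> float:
    """Representation target (fraction of the distribution) for a range size.

    Species with ranges at or below the lower threshold get ``max_target``
    (protect the whole distribution); at or above the upper threshold get
    ``min_target``; in between the target falls linearly in log10(area).
    At the geometric mean of the thresholds the target is exactly midway.
    """
    if range_area_km2 <= 0:
        raise ValueError(f"range_area_km2 must be > 0, got {range_area_km2}")
    if range_area_km2 <= rule.lower_threshold_km2:
        return rule.max_target
    if range_area_km2 >= rule.upper_threshold_km2:
        return rule.min_target
    span = math.log10(rule.upper_threshold_km2) - math.log10(rule.lower_threshold_km2)
    frac = (math.log10(range_area_km2) - math.log10(rule.lower_threshold_km2)) / span
    return rule.max_target + frac * (rule.min_target - rule.max_target)


@dataclass
class SubFeature:
    """One species × typology × province slice of a species distribution."""

    feature_id: int
    species_id: int
    typology_id: int
    province_id: int
    amount_by_unit: Dict[int, float]
    target_fraction: float
    weight: float = 1.0

    @property
    def total_area_km2(self) -> float:
        return float(sum(self.amount_by_unit.values()))

    @property
    def target_area_km2(self) -> float:
        return self.target_fraction * self.total_area_km2


def compute_subfeatures(
    species_ranges: Sequence[SpeciesRange],
    typology_by_unit: Mapping[int, int],
    province_by_unit: Mapping[int, int],
    rule: TargetRule = TargetRule(),
    interpolate_on: str = "species",
) -> List[SubFeature]:
    """Split each species range by (typology, province) and assign targets.

    Every planning unit carries exactly one predominant typology and one
    predominant province label, so each unit's share of a species' area
    lands in exactly one sub-feature: sub-feature totals partition the
    species' range area exactly.

    ``interpolate_on`` selects the area fed to the target rule: the
    species' global range area (``"species"``, default) or each
    sub-feature's own total (``"subfeature"``).
    """
    if interpolate_on not in ("species", "subfeature"):
        raise ValueError(f"interpolate_on must be 'species' or 'subfeature', got {interpolate_on!r}")
    all_units = set()
    for sp in species_ranges:
        all_units.update(sp.area_by_unit_km2)
    unlabeled = sorted(u for u in all_units if u not in typology_by_unit or u not in province_by_unit)
    if unlabeled:
        raise ValueError(f"planning units missing typology/province labels: {unlabeled}")

    out: List[SubFeature] = []
    fid = 0
    for sp in species_ranges:
        if not sp.area_by_unit_km2:
            logger.warning("species %d is absent from every planning unit; skipped", sp.species_id)
            continue
        groups: Dict[tuple, Dict[int, float]] = {}
        for uid, area in sp.area_by_unit_km2.items():
            key = (typology_by_unit[uid], province_by_unit[uid])
            groups.setdefault(key, {})[uid] = area
        species_target = assign_target(sp.range_area_km2, rule)
        for (typ, prov) in sorted(groups):
            amounts = groups[(typ, prov)]
            total = sum(amounts.values())
            if total < MIN_SUBFEATURE_AREA_KM2:
                continue
            target = (
                species_target
                if interpolate_on == "species"
                else assign_target(total, rule)
            )
            out.append(SubFeature(fid, sp.species_id, typ, prov, amounts, target))
            fid += 1
    return out


@dataclass
class ProblemInstance:
    """A minimum-shortfall reserve-selection problem.

    ``amounts`` is the sparse feature × unit matrix a_fi; the objective
    minimised by the solvers is the weighted proportional shortfall
    Σ_f w_f · max(0, t_f − Σ_i a_fi x_i) / t_f subject to the cost budget
    Σ_i c_i x_i ≤ B, with locked-in units forced into every solution.
    """

    amounts: sparse.csr_matrix
    targets: np.ndarray
    weights: np.ndarray
    costs: np.ndarray
    unit_ids: np.ndarray
    feature_labels: List[str]
    locked_in: frozenset
    budget: float

    def __post_init__(self) -> None:
        f, n = self.amounts.shape
        if not (len(self.targets) == len(self.weights) == f == len(self.feature_labels)):
            raise ValueError("feature dimensions inconsistent")
        if not (len(self.costs) == n == len(self.unit_ids)):
            raise ValueError("unit dimensions inconsistent")
        if np.any(self.targets <= 0):
            raise ValueError("targets must be > 0")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")
        if np.any(self.costs < 0):
            raise ValueError("costs must be >= 0")
        totals = np.asarray(self.amounts.sum(axis=1)).ravel()
        if np.any(self.targets > totals * (1 + 1e-9) + 1e-12):
            raise ValueError("every target must be attainable: t_f <= sum_i a_fi")
        unknown = self.locked_in - set(self.unit_ids.tolist())
        if unknown:
            raise ValueError(f"locked-in ids not in problem: {sorted(unknown)}")
        locked_cost = self.locked_cost()
        if locked_cost > self.budget * (1 + 1e-9) + 1e-9:
            raise InfeasibleBudgetError(
                f"locked-in cost {locked_cost:.6g} exceeds budget {self.budget:.6g}; "
                "raise the budget floor"
            )

    @property
    def n_units(self) -> int:
        return self.amounts.shape[1]

    @property
    def n_features(self) -> int:
        return self.amounts.shape[0]

    def column_of(self) -> Dict[int, int]:
        return {int(u): j for j, u in enumerate(self.unit_ids)}

    def locked_mask(self) -> np.ndarray:
        col = self.column_of()
        mask = np.zeros(self.n_units, dtype=bool)
        for uid in self.locked_in:
            mask[col[uid]] = True
        return mask

    def locked_cost(self) -> float:
        return float(self.costs[self.locked_mask()].sum()) if self.locked_in else 0.0

    def objective(self, chosen_mask: np.ndarray) -> float:
        """Weighted proportional shortfall of a selection (column mask)."""
        held = self.amounts @ chosen_mask.astype(float)
        short = np.maximum(0.0, self.targets - held)
        return float(np.sum(self.weights * short / self.targets))

    def with_budget(self, budget: float, locked_in: Optional[frozenset] = None) -> "ProblemInstance":
        return ProblemInstance(
            self.amounts,
            self.targets,
            self.weights,
            self.costs,
            self.unit_ids,
            self.feature_labels,
            self.locked_in if locked_in is None else locked_in,
            budget,
        )


def build_problem(
    subfeatures: Sequence[SubFeature],
    service_features: Sequence[ServiceFeature],
    units: pd.DataFrame,
    locked_in: Iterable[int] = (),
    budget_fraction: float = 1.0,
    service_weights: Optional[Mapping[str, float]] = None,
) -> ProblemInstance:
    """Stack biodiversity sub-features and service features into a problem.

    Costs are each unit's mangrove area (km²); the budget is
    ``budget_fraction`` of the total mangrove area. Zero-mangrove units
    are excluded from the problem entirely. Service features enter with
    their rescaled per-unit values as amounts and a 100% target.
    """
    if not 0 < budget_fraction <= 1:
        raise ValueError(f"budget_fraction must be in (0, 1], got {budget_fraction}")
    service_weights = dict(service_weights or {})

    keep = units["mangrove_area_km2"].to_numpy() > 0
    unit_ids = units.loc[keep, "id"].to_numpy(dtype=int)
    costs = units.loc[keep, "mangrove_area_km2"].to_numpy(dtype=float)
    col = {int(u): j for j, u in enumerate(unit_ids)}
    n = len(unit_ids)

    rows, cols, vals = [], [], []
    targets, weights, labels = [], [], []
    f = 0
    for sf in subfeatures:
        for uid, amount in sf.amount_by_unit.items():
            if uid in col and amount > 0:
                rows.append(f)
                cols.append(col[uid])
                vals.append(amount)
        targets.append(sf.target_area_km2)
        weights.append(sf.weight)
        labels.append(f"sp{sf.species_id}_t{sf.typology_id}_p{sf.province_id}")
        f += 1
    for svc in service_features:
        for uid, value in zip(svc.unit_ids, svc.rescaled_by_unit):
            if uid in col and value > 0:
                rows.append(f)
                cols.append(col[int(uid)])
                vals.append(float(value))
        total = float(np.sum(svc.rescaled_by_unit[np.isin(svc.unit_ids, unit_ids)]))
        if total <= 0:
            continue  # constant layer rescaled to all zeros carries no signal
        targets.append(svc.target_fraction * total)
        weights.append(service_weights.get(svc.service_name, svc.weight))
        labels.append(f"service:{svc.service_name}")
        f += 1

    amounts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(targets), n), dtype=float
    )
    total_cost = float(costs.sum())
    budget = budget_fraction * total_cost
    return ProblemInstance(
        amounts,
        np.asarray(targets, dtype=float),
        np.asarray(weights, dtype=float),
        costs,
        unit_ids,
        labels,
        frozenset(int(u) for u in locked_in),
        budget,
    )
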