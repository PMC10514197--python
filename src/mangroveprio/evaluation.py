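"""Reporting on reserve solutions: representation, services, gaps, agreement.

Mirrors the standard reporting toolkit of systematic conservation
planning: how many feature targets a selection meets, how fast each
ecosystem service accumulates along the priority ranking, how well the
existing protected-area estate covers mangroves and services, and the
chance-corrected agreement (Cohen's kappa) between two alternative
solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import ProblemInstance
from .solvers import RankMap, lock_protected

REL_TOL = 1e-9


@dataclass
class RepresentationReport:
    """Per-feature target accounting for one selection."""

    per_feature: pd.DataFrame  # feature, amount_held, target, shortfall, met
    n_met: int
    n_features: int

    @property
    def percent_met(self) -> float:
        return 100.0 * self.n_met / self.n_features if self.n_features else float("nan")

    def summary(self) -> str:
        return f"{self.n_met} of {self.n_features} targets met ({self.percent_met:.1f}%)"


def representation_report(
    problem: ProblemInstance, chosen: Iterable[int]
) -> RepresentationReport:
    """Exact per-feature accounting of amounts held by a selection."""
    chosen = set(int(u) for u in chosen)
    col = problem.column_of()
    mask = np.zeros(problem.n_units, dtype=bool)
    for uid in chosen:
        if uid in col:
            mask[col[uid]] = True
    held = np.asarray(problem.amounts @ mask.astype(float)).ravel()
    met = held >= problem.targets * (1 - REL_TOL)
    table = pd.DataFrame(
        {
            "feature": problem.feature_labels,
            "amount_held": held,
            "target": problem.targets,
            "shortfall": np.maximum(0.0, problem.targets - held),
            "met": met,
        }
    )
    return RepresentationReport(table, int(met.sum()), problem.n_features)


def service_accumulation(
    rank_map: RankMap,
    service_totals: Mapping[str, Mapping[int, float]],
    problem: Optional[ProblemInstance] = None,
) -> pd.DataFrame:
    """Cumulative service capture (and optionally targets met) per budget step.

    For each budget step r the selection is every unit of rank ≤ r
    (rank-0 locked-in units are in every selection). Returns one row per
    step with, per service, the cumulative raw total in native units and
    the percent of the global total; plus ``percent_targets_met`` when a
    problem is supplied.
    """
    rank_map.validate_nested()
    n_steps = len(rank_map.budget_grid)
    rows = []
    for step in range(1, n_steps + 1):
        selected = rank_map.units_at_step(step)
        row: Dict[str, float] = {"step": step, "budget_fraction": rank_map.budget_grid[step - 1]}
        for name, totals in service_totals.items():
            global_total = float(sum(totals.values()))
            inside = float(sum(v for u, v in totals.items() if u in selected))
            row[f"{name}_total"] = inside
            row[f"{name}_percent"] = 100.0 * inside / global_total if global_total else 0.0
        if problem is not None:
            row["percent_targets_met"] = representation_report(problem, selected).percent_met
        rows.append(row)
    return pd.DataFrame(rows)


def cohens_kappa(
    selection_a: Iterable[int],
    selection_b: Iterable[int],
    universe: Iterable[int],
    area_by_unit: Optional[Mapping[int, float]] = None,
) -> float:
    """Chance-corrected agreement between two binary selections.

    κ = (p_o − p_e) / (1 − p_e), where p_o is the (optionally
    area-weighted) fraction of units on which the selections agree and
    p_e = p_A·p_B + (1−p_A)(1−p_B) the agreement expected by chance.
    Returns NaN when p_e = 1 with imperfect agreement (undefined); 1.0
    for two identical all-or-nothing selections.
    """
    universe = sorted(set(int(u) for u in universe))
    if not universe:
        raise ValueError("cohens_kappa: empty universe")
    a = set(int(u) for u in selection_a)
    b = set(int(u) for u in selection_b)
    if not a <= set(universe) or not b <= set(universe):
        raise ValueError("cohens_kappa: selections must be subsets of the universe")
    if area_by_unit is None:
        w = {u: 1.0 for u in universe}
    else:
        w = {u: float(area_by_unit[u]) for u in universe}
    total = sum(w.values())
    p_a = sum(w[u] for u in universe if u in a) / total
    p_b = sum(w[u] for u in universe if u in b) / total
    p_o = sum(w[u] for u in universe if (u in a) == (u in b)) / total
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        return 1.0 if math.isclose(p_o, 1.0, abs_tol=1e-12) else float("nan")
    return (p_o - p_e) / (1 - p_e)


@dataclass
class GapReport:
    """Protected-area coverage of mangroves and services."""

    category_mode: str
    percent_area_protected_strict: float
    percent_area_protected_any: float
    coverage_by_zone: pd.DataFrame  # zone_id, percent_area_protected
    service_totals_protected: Dict[str, float]
    service_percent_protected: Dict[str, float]
    class_mean_services: pd.DataFrame  # class x service mean per unit
    mean_area_ratio_protected_vs_unprotected: float

    def summary(self) -> str:
        lines = [
            f"strictly protected mangrove area: {self.percent_area_protected_strict:.1f}%",
            f"protected under any category:     {self.percent_area_protected_any:.1f}%",
            "service totals inside protected units "
            f"({self.category_mode} mode): "
            + ", ".join(
                f"{k}={v:.4g} ({self.service_percent_protected[k]:.1f}%)"
                for k, v in self.service_totals_protected.items()
            ),
            "mean mangrove area, protected vs unprotected units: "
            f"{self.mean_area_ratio_protected_vs_unprotected:.3f}x",
        ]
        return "\n".join(lines)


def _area_coverage(units: pd.DataFrame, protected: frozenset) -> float:
    areas = units.set_index("id")["mangrove_area_km2"]
    total = float(areas.sum())
    inside = float(areas.loc[[u for u in areas.index if u in protected]].sum())
    return 100.0 * inside / total if total else float("nan")


def gap_report(
    units: pd.DataFrame,
    service_totals: Mapping[str, Mapping[int, float]],
    category_mode: str = "strict",
    threshold: float = 0.5,
    prioritised: Optional[Iterable[int]] = None,
) -> GapReport:
    """Protected-area gap analysis over the units table.

    Coverage percentages are mangrove-area-weighted (share of total
    mangrove area inside protected units), matching how global coverage
    statistics are quoted. Class means (per-unit raw service values) are
    reported for strictly protected units, other protected units, and —
    when a selection is supplied — prioritised-but-unprotected units.
    """
    strict = lock_protected(units, "strict", threshold)
    anyprot = lock_protected(units, "all", threshold)
    chosen_mode = strict if category_mode == "strict" else anyprot

    by_zone = []
    for zone, grp in units.groupby("zone_id"):
        total = float(grp["mangrove_area_km2"].sum())
        inside = float(
            grp.loc[grp["id"].isin(chosen_mode), "mangrove_area_km2"].sum()
        )
        by_zone.append(
            {"zone_id": zone, "percent_area_protected": 100.0 * inside / total if total else np.nan}
        )

    totals_inside, pct_inside = {}, {}
    for name, totals in service_totals.items():
        global_total = float(sum(totals.values()))
        inside = float(sum(v for u, v in totals.items() if u in chosen_mode))
        totals_inside[name] = inside
        pct_inside[name] = 100.0 * inside / global_total if global_total else float("nan")

    classes = {
        "strict_pa": strict,
        "other_pa": anyprot - strict,
    }
    if prioritised is not None:
        classes["prioritised_not_pa"] = frozenset(int(u) for u in prioritised) - anyprot
    rows = []
    for cls, members in classes.items():
        if not members:
            continue
        row = {"class": cls, "n_units": len(members)}
        for name, totals in service_totals.items():
            row[f"{name}_mean"] = float(np.mean([totals.get(u, 0.0) for u in members]))
        rows.append(row)
    class_means = pd.DataFrame(rows)

    prot_mask = units["id"].isin(chosen_mode)
    mean_prot = float(units.loc[prot_mask, "mangrove_area_km2"].mean()) if prot_mask.any() else np.nan
    mean_unprot = (
        float(units.loc[~prot_mask, "mangrove_area_km2"].mean()) if (~prot_mask).any() else np.nan
    )
    ratio = mean_prot / mean_unprot if mean_unprot else float("nan")

    return GapReport(
        category_mode=category_mode,
        percent_area_protected_strict=_area_coverage(units, strict),
        percent_area_protected_any=_area_coverage(units, anyprot),
        coverage_by_zone=pd.DataFrame(by_zone),
        service_totals_protected=totals_inside,
        service_percent_protected=pct_inside,
        class_mean_services=class_means,
        mean_area_ratio_protected_vs_unprotected=ratio,
    )
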