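"""Readers and writers binding the pipeline stages together.

Planning units travel as GeoJSON (polygon features with the attribute
columns id, mangrove_area_km2, strict_protected_fraction,
any_protected_fraction, province_id, zone_id); feature and service
tables as long-format CSV; configuration as YAML; the run manifest as
JSON. All round-trips preserve values to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from .features import SubFeature
from .services import ServiceFeature
from .solvers import RankMap, Selection

UNIT_COLUMNS = [
    "id",
    "mangrove_area_km2",
    "strict_protected_fraction",
    "any_protected_fraction",
    "province_id",
    "zone_id",
]


def write_units(units: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        raise NotImplementedError(
            "GeoPackage output is not supported in this build; write GeoJSON (.geojson)"
        )
    features = []
    extra = [c for c in units.columns if c != "geometry"]
    for _, row in units.iterrows():
        props = {}
        for c in extra:
            v = row[c]
            props[c] = v.item() if isinstance(v, np.generic) else v
        features.append(
            {"type": "Feature", "geometry": shapely_mapping(row["geometry"]), "properties": props}
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_units(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        raise NotImplementedError(
            "GeoPackage input is not supported in this build; supply GeoJSON (.geojson)"
        )
    doc = json.loads(path.read_text())
    rows = []
    for feat in doc["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shapely_shape(feat["geometry"])
        rows.append(row)
    units = pd.DataFrame(rows)
    missing = [c for c in UNIT_COLUMNS if c not in units.columns]
    if missing:
        raise ValueError(f"units file {path} is missing mandatory columns: {missing}")
    return units.sort_values("id").reset_index(drop=True)


def write_features(
    subfeatures: Sequence[SubFeature], amounts_path: str | Path, metadata_path: str | Path
) -> None:
    long_rows: List[Dict] = []
    meta_rows: List[Dict] = []
    for sf in subfeatures:
        for uid, amount in sorted(sf.amount_by_unit.items()):
            long_rows.append({"feature_id": sf.feature_id, "unit_id": uid, "amount_km2": amount})
        meta_rows.append(
            {
                "feature_id": sf.feature_id,
                "species_id": sf.species_id,
                "typology_id": sf.typology_id,
                "province_id": sf.province_id,
                "total_km2": sf.total_area_km2,
                "target_fraction": sf.target_fraction,
                "target_km2": sf.target_area_km2,
                "weight": sf.weight,
            }
        )
    pd.DataFrame(long_rows).to_csv(amounts_path, index=False, float_format="%.17g")
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False, float_format="%.17g")


def read_features(amounts_path: str | Path, metadata_path: str | Path) -> List[SubFeature]:
    amounts = pd.read_csv(amounts_path)
    meta = pd.read_csv(metadata_path)
    for frame, path, required in (
        (amounts, amounts_path, ["feature_id", "unit_id", "amount_km2"]),
        (meta, metadata_path, ["feature_id", "species_id", "typology_id", "province_id", "target_fraction"]),
    ):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"{path} is missing mandatory columns: {missing}")
    grouped = {
        fid: dict(zip(grp["unit_id"].astype(int), grp["amount_km2"].astype(float)))
        for fid, grp in amounts.groupby("feature_id")
    }
    out = []
    for _, row in meta.sort_values("feature_id").iterrows():
        fid = int(row["feature_id"])
        out.append(
            SubFeature(
                feature_id=fid,
                species_id=int(row["species_id"]),
                typology_id=int(row["typology_id"]),
                province_id=int(row["province_id"]),
                amount_by_unit=grouped.get(fid, {}),
                target_fraction=float(row["target_fraction"]),
                weight=float(row.get("weight", 1.0)),
            )
        )
    return out


def write_services(service_features: Sequence[ServiceFeature], path: str | Path) -> None:
    rows = []
    for svc in service_features:
        for uid, raw, scaled in zip(svc.unit_ids, svc.raw_total_by_unit, svc.rescaled_by_unit):
            rows.append(
                {
                    "service_name": svc.service_name,
                    "unit_id": int(uid),
                    "raw_value": raw,
                    "rescaled_value": scaled,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_selection(selection: Selection, unit_ids: Sequence[int], path: str | Path) -> None:
    pd.DataFrame(
        {"unit_id": list(unit_ids), "chosen": [int(u in selection.chosen) for u in unit_ids]}
    ).to_csv(path, index=False)


def write_rank_map(rank_map: RankMap, path: str | Path) -> None:
    items = sorted(rank_map.rank_by_unit.items())
    pd.DataFrame({"unit_id": [u for u, _ in items], "rank": [r for _, r in items]}).to_csv(
        path, index=False
    )


def read_rank_map(path: str | Path, budget_grid: Sequence[float]) -> RankMap:
    frame = pd.read_csv(path)
    return RankMap(
        rank_by_unit=dict(zip(frame["unit_id"].astype(int), frame["rank"].astype(int))),
        budget_grid=list(budget_grid),
    )


def write_config(config: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=True))


def read_config(path: str | Path) -> Dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(manifest), indent=2, sort_keys=True))
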