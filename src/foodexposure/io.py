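"""Readers and writers for the pipeline's on-disk formats.

GeoJSON for geometry layers (network lines, outlet points, exposure-area
polygons), CSV for tabular layers (households, margins, weights, profiles,
estimates), YAML for configuration.  Everything is plain text.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .exposure import AnchorPoint, ExposureArea, Household
from .outlets import FoodOutlet
from .synthetic import CityConfig, CovariateParams
from .weights import PopulationMargins

MAX_ANCHORS = 4  # two adults x two anchors


# -------------------------------------------------------------------- outlets
def write_outlets_geojson(outlets: Iterable[FoodOutlet], path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(o.location)},
            "properties": {"id": o.id, "category": o.category},
        }
        for o in outlets
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_outlets_geojson(path) -> list[FoodOutlet]:
    with open(path) as fh:
        fc = json.load(fh)
    outlets = []
    for feat in fc["features"]:
        x, y = feat["geometry"]["coordinates"][:2]
        props = feat.get("properties") or {}
        outlets.append(
            FoodOutlet(
                id=str(props.get("id", len(outlets))),
                location=(float(x), float(y)),
                category=props["category"],
            )
        )
    return outlets


# ----------------------------------------------------------------- households
def households_to_frame(households: Sequence[Household]) -> pd.DataFrame:
    rows = []
    for h in households:
        row = {"household_id": h.household_id, "home_x": h.home[0], "home_y": h.home[1]}
        row.update(h.covariates)
        for i in range(MAX_ANCHORS):
            if i < len(h.anchors):
                a = h.anchors[i]
                row[f"anchor{i+1}_x"] = a.location[0]
                row[f"anchor{i+1}_y"] = a.location[1]
                row[f"anchor{i+1}_mode"] = a.mode
                row[f"anchor{i+1}_adult"] = a.adult_index
            else:
                row[f"anchor{i+1}_x"] = None
                row[f"anchor{i+1}_y"] = None
                row[f"anchor{i+1}_mode"] = None
                row[f"anchor{i+1}_adult"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_households(df: pd.DataFrame) -> list[Household]:
    households = []
    anchor_cols = [
        c for c in df.columns if c.startswith("anchor") and c.endswith("_x")
    ]
    covariate_cols = [
        c
        for c in df.columns
        if not c.startswith("anchor")
        and c not in ("household_id", "home_x", "home_y")
    ]
    for _, row in df.iterrows():
        anchors = []
        for xc in anchor_cols:
            stem = xc[: -len("_x")]
            if pd.notna(row[xc]):
                anchors.append(
                    AnchorPoint(
                        location=(float(row[xc]), float(row[f"{stem}_y"])),
                        mode=str(row[f"{stem}_mode"]),
                        adult_index=int(row[f"{stem}_adult"]),
                    )
                )
        households.append(
            Household(
                household_id=str(row["household_id"]),
                home=(float(row["home_x"]), float(row["home_y"])),
                anchors=anchors,
                covariates={c: row[c] for c in covariate_cols},
            )
        )
    return households


def write_households_csv(households: Sequence[Household], path) -> None:
    households_to_frame(households).to_csv(path, index=False)


def read_households_csv(path) -> list[Household]:
    return frame_to_households(pd.read_csv(path))


# ---------------------------------------------------------------------- areas
def write_areas_geojson(areas: Iterable[ExposureArea], path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(a.polygon),
            "properties": {
                "household_id": a.household_id,
                "kind": a.kind,
                "area_m2": a.area_m2,
            },
        }
        for a in areas
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_areas_geojson(path) -> list[ExposureArea]:
    with open(path) as fh:
        fc = json.load(fh)
    areas = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        areas.append(
            ExposureArea(
                kind=props["kind"],
                polygon=shape(feat["geometry"]),
                household_id=props.get("household_id"),
            )
        )
    return areas


# -------------------------------------------------------------------- margins
def write_margins_csv(margins: PopulationMargins, path) -> None:
    margins.to_frame().to_csv(path, index=False)


def read_margins_csv(path) -> PopulationMargins:
    return PopulationMargins.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------- config
def config_to_yaml(config: CityConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> CityConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cp_raw = raw.pop("covariate_params", None)
    kwargs = dict(raw)
    for key in ("center", "zone_radii_m"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cp_raw is not None:
        for key, val in list(cp_raw.items()):
            if isinstance(val, list):
                cp_raw[key] = tuple(val)
            elif isinstance(val, dict):
                cp_raw[key] = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in val.items()
                }
        kwargs["covariate_params"] = CovariateParams(**cp_raw)
    return CityConfig(**kwargs)
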