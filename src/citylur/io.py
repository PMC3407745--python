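"""Plain-text serialisation of scenes, campaigns and cohorts.

Roads and census blocks go to GeoJSON (built with ``shapely`` geometry
mappings), tabular data to CSV, models and ground truth to JSON, so every
artifact of a pipeline run is human-readable and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .lur import LURModel, MeasurementSet
from .predictors import DEFAULT_SIGNS
from .scene import CensusBlock, CityScene, RoadSegment
from .synthetic import _altitude_field, CityConfig


def write_roads_geojson(roads: list[RoadSegment], path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(r.as_linestring()),
            "properties": {"vehicles_per_day": r.vehicles_per_day},
        }
        for r in roads
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_roads_geojson(path: Path) -> list[RoadSegment]:
    data = json.loads(Path(path).read_text())
    roads = []
    for f in data["features"]:
        geom = shape(f["geometry"])
        coords = list(geom.coords)
        roads.append(RoadSegment(tuple(coords[0]), tuple(coords[-1]), f["properties"]["vehicles_per_day"]))
    return roads


def write_blocks_geojson(blocks: list[CensusBlock], path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(b.polygon),
            "properties": {
                "id": b.id,
                "residents": b.residents,
                "area": b.area,
                "altitude": b.altitude,
                "green_adjacent": b.green_adjacent,
            },
        }
        for b in blocks
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_blocks_geojson(path: Path) -> list[CensusBlock]:
    data = json.loads(Path(path).read_text())
    out = []
    for f in data["features"]:
        p = f["properties"]
        out.append(
            CensusBlock(
                id=p["id"], polygon=shape(f["geometry"]), residents=p["residents"],
                area=p["area"], altitude=p["altitude"], green_adjacent=p["green_adjacent"],
            )
        )
    return out


def write_scene(city: CityScene, out_dir: Path, config: CityConfig | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_roads_geojson(city.roads, out_dir / "roads.geojson")
    write_blocks_geojson(city.blocks, out_dir / "blocks.geojson")
    meta = {"extent": city.extent, "centre": list(city.centre)}
    if config is not None:
        meta["config"] = config.__dict__
    (out_dir / "scene.json").write_text(json.dumps(meta, indent=2))


def read_scene(out_dir: Path) -> CityScene:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "scene.json").read_text())
    cfg = CityConfig(**meta["config"]) if "config" in meta else CityConfig(extent=meta["extent"])
    return CityScene(
        extent=meta["extent"],
        centre=tuple(meta["centre"]),
        roads=read_roads_geojson(out_dir / "roads.geojson"),
        blocks=read_blocks_geojson(out_dir / "blocks.geojson"),
        altitude_field=_altitude_field(cfg),
    )


def write_measurements(ms: MeasurementSet, out_dir: Path, stem: str) -> None:
    out_dir = Path(out_dir)
    rec = ms.records.copy()
    rec.insert(0, "campaign", ms.campaign)
    rec["sampler"] = ms.sampler
    rec.to_csv(out_dir / f"{stem}_measurements.csv", index=False)
    ms.sites.to_csv(out_dir / f"{stem}_sites.csv", index=False)


def read_measurements(out_dir: Path, stem: str) -> MeasurementSet:
    out_dir = Path(out_dir)
    rec = pd.read_csv(out_dir / f"{stem}_measurements.csv")
    sites = pd.read_csv(out_dir / f"{stem}_sites.csv")
    return MeasurementSet(
        campaign=int(rec["campaign"].iloc[0]),
        sampler=str(rec["sampler"].iloc[0]),
        records=rec[["site_id", "period", "value"]],
        sites=sites,
    )


def write_model(model: LURModel, path: Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, default=float))


def read_model(path: Path) -> LURModel:
    d = json.loads(Path(path).read_text())
    return LURModel(
        campaign=d["campaign"], predictors=d["predictors"], intercept=d["intercept"],
        coefficients=d["coefficients"], pvalues=d["pvalues"], r2=d["r2"],
        adjusted_r2=d["adjusted_r2"], rmse_log=d["rmse_log"], n_sites=d["n_sites"],
        signs=DEFAULT_SIGNS, smearing_factor=d.get("smearing_factor", 1.0),
        removal_trace=d.get("removal_trace", []),
    )


def write_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
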