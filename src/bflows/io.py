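"""Plain-text serialization of worlds and results.

A "world directory" holds everything the pipeline consumes, in diffable
CSV/YAML with explicit labels:

    labels.csv       region,sector,is_food (region-major order)
    A.csv            technical coefficients, two-level row/column labels
    Y.csv            final demand, (region,sector) rows x region columns
    x.csv            region,sector,gross_output
    extensions.csv   region,sector plus one unit-annotated column per indicator
    proxies.csv      region plus unit-annotated proxy columns
    boundaries.yaml  global boundaries with units, optional proxy mapping
                     and per-region overrides

Units are declared and validated, never converted silently; the single
exception is Tg/yr -> t/yr for nitrogen/phosphorus boundaries (1 Tg = 1e6 t),
applied at config load so one internal unit system holds throughout.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    INDICATORS,
    PROXY_COLUMNS,
    PROXY_UNITS,
    UNITS,
    ExtensionSet,
    MRIOTable,
    PlanetaryBoundarySet,
    ProxyTable,
    ValidationError,
    region_sector_index,
)
from .pipeline import AnalysisResult
from .transgression import FlowMatrix

WORLD_FILES = (
    "labels.csv",
    "A.csv",
    "Y.csv",
    "x.csv",
    "extensions.csv",
    "proxies.csv",
    "boundaries.yaml",
)

_TG_PER_TONNE_INDICATORS = ("nitrogen", "phosphorus")


def _float_repr(v) -> str:
    # shortest decimal that round-trips the double exactly
    return repr(float(v))


def _unit_col(name: str, unit: str) -> str:
    return f"{name}[{unit}]"


def _split_unit_col(col: str, file: str) -> tuple[str, str]:
    if "[" not in col or not col.endswith("]"):
        raise ValidationError(f"{file}: column {col!r} lacks a [unit] annotation")
    name, unit = col[:-1].split("[", 1)
    return name, unit


def write_world(world, path) -> None:
    """Write a SyntheticWorld (or equivalent component tuple) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mrio, ext, proxies, pb = (
        world.mrio,
        world.extensions,
        world.proxies,
        world.planetary_boundaries,
    )
    labels = pd.DataFrame(
        {
            "region": mrio.index.get_level_values("region"),
            "sector": mrio.index.get_level_values("sector"),
            "is_food": [
                bool(mrio.food_mask[s]) for s in mrio.index.get_level_values("sector")
            ],
        }
    )
    labels.to_csv(path / "labels.csv", index=False)
    mrio.A.to_csv(path / "A.csv", float_format=_float_repr)
    mrio.Y.to_csv(path / "Y.csv", float_format=_float_repr)
    mrio.x.rename("gross_output").reset_index().to_csv(path / "x.csv", index=False, float_format=_float_repr)
    extdf = ext.E.T.copy()
    extdf.columns = [_unit_col(ind, ext.units[ind]) for ind in extdf.columns]
    extdf.to_csv(path / "extensions.csv", float_format=_float_repr)
    proxdf = proxies.table.copy()
    proxdf.columns = [_unit_col(c, PROXY_UNITS[c]) for c in proxdf.columns]
    proxdf.to_csv(path / "proxies.csv", float_format=_float_repr)
    bounds = {
        "planetary_boundaries": {
            ind: {"value": float(getattr(pb, ind)), "units": UNITS[ind]}
            for ind in INDICATORS
        }
    }
    (path / "boundaries.yaml").write_text(yaml.safe_dump(bounds, sort_keys=False))


def read_boundaries(path) -> tuple[PlanetaryBoundarySet, dict | None, dict | None]:
    """Parse boundaries.yaml: global boundaries, proxy mapping, overrides."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "planetary_boundaries" not in cfg:
        raise ValidationError(f"{path.name}: missing 'planetary_boundaries' section")
    values = {}
    for ind in INDICATORS:
        entry = cfg["planetary_boundaries"].get(ind)
        if entry is None:
            raise ValidationError(
                f"{path.name}: no boundary for indicator {ind!r} "
                "(no default is assumed)"
            )
        value, unit = float(entry["value"]), str(entry["units"])
        if unit == "Tg/yr" and ind in _TG_PER_TONNE_INDICATORS:
            value, unit = value * 1e6, UNITS[ind]
        if unit != UNITS[ind]:
            raise ValidationError(
                f"{path.name}: boundary for {ind!r} has units {unit!r}, "
                f"expected {UNITS[ind]!r}"
            )
        values[ind] = value
    pb = PlanetaryBoundarySet(**values)
    pb.validate()
    return pb, cfg.get("proxy_mapping"), cfg.get("national_overrides")


def read_world(path) -> tuple[MRIOTable, ExtensionSet, ProxyTable, PlanetaryBoundarySet]:
    """Read and validate a world directory.

    Any structural violation raises :class:`ValidationError` naming the
    offending file and coordinates; a missing file is fatal.
    """
    path = Path(path)
    for name in WORLD_FILES:
        if not (path / name).exists():
            raise ValidationError(f"world directory {path}: missing file {name}")

    labels = pd.read_csv(path / "labels.csv")
    for col in ("region", "sector", "is_food"):
        if col not in labels.columns:
            raise ValidationError(f"labels.csv: missing column {col!r}")
    regions = list(dict.fromkeys(labels["region"]))
    sectors = list(dict.fromkeys(labels["sector"]))
    idx = region_sector_index(regions, sectors)
    got = pd.MultiIndex.from_arrays(
        [labels["region"], labels["sector"]], names=["region", "sector"]
    )
    if not got.equals(idx):
        raise ValidationError(
            "labels.csv: rows are not in canonical region-major order "
            f"(expected the product of regions {regions} x sectors {sectors})"
        )
    food_by_sector = labels.drop_duplicates("sector").set_index("sector")["is_food"]
    inconsistent = labels.groupby("sector")["is_food"].nunique()
    if (inconsistent > 1).any():
        bad = inconsistent[inconsistent > 1].index[0]
        raise ValidationError(f"labels.csv: sector {bad!r} has inconsistent is_food flags")
    food_mask = food_by_sector.reindex(sectors).astype(bool)
    food_mask.name = "is_food"

    A = pd.read_csv(path / "A.csv", header=[0, 1], index_col=[0, 1], float_precision="round_trip")
    A.index.names = ["region", "sector"]
    A.columns.names = ["region", "sector"]
    _require_index(A.index, idx, "A.csv", "rows")
    _require_index(A.columns, idx, "A.csv", "columns")

    Y = pd.read_csv(path / "Y.csv", header=0, index_col=[0, 1], float_precision="round_trip")
    Y.index.names = ["region", "sector"]
    Y.columns.name = "region"
    _require_index(Y.index, idx, "Y.csv", "rows")
    if list(Y.columns) != regions:
        raise ValidationError(
            f"Y.csv: destination columns {list(Y.columns)} != labels.csv regions {regions}"
        )

    xdf = pd.read_csv(path / "x.csv", float_precision="round_trip")
    xi = pd.MultiIndex.from_arrays(
        [xdf["region"], xdf["sector"]], names=["region", "sector"]
    )
    _require_index(xi, idx, "x.csv", "rows")
    x = pd.Series(xdf["gross_output"].to_numpy(dtype=float), index=idx, name="gross_output")

    extdf = pd.read_csv(path / "extensions.csv", index_col=[0, 1], float_precision="round_trip")
    extdf.index.names = ["region", "sector"]
    _require_index(extdf.index, idx, "extensions.csv", "rows")
    units = {}
    names = []
    for col in extdf.columns:
        name, unit = _split_unit_col(col, "extensions.csv")
        units[name] = unit
        names.append(name)
    if names != list(INDICATORS):
        raise ValidationError(
            f"extensions.csv: indicator columns {names} != {list(INDICATORS)}"
        )
    E = extdf.T
    E.index = pd.Index(names, name="indicator")
    extensions = ExtensionSet(E=E, units=units)

    proxdf = pd.read_csv(path / "proxies.csv", index_col=0, float_precision="round_trip")
    cols = {}
    for col in proxdf.columns:
        name, unit = _split_unit_col(col, "proxies.csv")
        if name in PROXY_UNITS and unit != PROXY_UNITS[name]:
            raise ValidationError(
                f"proxies.csv: column {name!r} has units {unit!r}, "
                f"expected {PROXY_UNITS[name]!r}"
            )
        cols[name] = proxdf[col]
    table = pd.DataFrame(cols)
    table.index.name = "region"
    if list(table.index) != regions:
        raise ValidationError(
            f"proxies.csv: regions {list(table.index)} != labels.csv regions {regions}"
        )
    proxies = ProxyTable(table)

    pb, _, _ = read_boundaries(path / "boundaries.yaml")

    mrio = MRIOTable(A=A, Y=Y, x=x, food_mask=food_mask)
    mrio.validate()  # balance violations warn; structural violations raise
    extensions.validate(x)
    proxies.validate()
    return mrio, extensions, proxies, pb


def _require_index(got, expected, file: str, axis: str) -> None:
    if not got.equals(expected):
        raise ValidationError(
            f"{file}: {axis} labels do not match labels.csv; "
            f"expected {list(expected)[:6]}..., got {list(got)[:6]}..."
        )


def write_flows(flows: FlowMatrix, path) -> None:
    """Edge-list CSV: indicator,origin,destination,value,units.

    Rows sorted by indicator (canonical order) then descending value; zero
    flows are omitted.
    """
    df = flows.to_frame()
    df = df[df["value"] != 0].copy()
    df["units"] = df["indicator"].map(flows.units)
    order = {ind: n for n, ind in enumerate(INDICATORS)}
    df["_ord"] = df["indicator"].map(order)
    df = df.sort_values(["_ord", "value"], ascending=[True, False]).drop(columns="_ord")
    df.to_csv(path, index=False, float_format=_float_repr)


def read_flows(path) -> pd.DataFrame:
    """Read an edge list written by :func:`write_flows`."""
    return pd.read_csv(path, float_precision="round_trip")


def write_country_summary(result: AnalysisResult, path) -> None:
    """Per-(region, indicator) summary of every pipeline account.

    Columns: production/consumption footprints, national boundary,
    production- and consumption-based transgression, per-capita consumption
    transgression, no-trade transgression and alleviation.  On write the
    bilateral-flow column totals are checked against the consumption
    transgression they aggregate, and the flow grand total against the
    production-based transgression total (a shortfall means impacts
    embodied in non-food demand escaped the food mask; warned, not fatal).
    """
    flows_by_dest = result.flows.data.sum("origin").to_pandas()
    if not np.allclose(
        flows_by_dest.to_numpy(),
        result.transgression.T_cons.to_numpy(),
        rtol=1e-9,
        atol=1e-12,
    ):
        raise ValidationError(
            "country summary: bilateral-flow column totals disagree with "
            "consumption-based transgression"
        )
    total_flow = float(result.flows.data.sum())
    total_T = float(result.transgression.T.to_numpy().sum())
    if total_flow > total_T * (1 + 1e-8) + 1e-12:
        raise ValidationError(
            f"country summary: flow total {total_flow:.6g} exceeds "
            f"transgression total {total_T:.6g}"
        )
    if total_T > 0 and total_flow < total_T * (1 - 1e-8):
        warnings.warn(
            f"country summary: flow total {total_flow:.6g} below transgression "
            f"total {total_T:.6g}; transgressed impacts embodied in non-food "
            "final demand are not attributed to food consumption",
            stacklevel=2,
        )
    rows = []
    regions = result.boundaries.regions
    for ind in INDICATORS:
        for r in regions:
            rows.append(
                {
                    "region": r,
                    "indicator": ind,
                    "units": UNITS[ind],
                    "production_footprint": result.footprints.F_prod.loc[ind, r],
                    "consumption_footprint": result.footprints.F_cons.loc[ind, r],
                    "boundary": result.boundaries.NB.loc[ind, r],
                    "transgression_production": result.transgression.T.loc[ind, r],
                    "transgression_consumption": result.transgression.T_cons.loc[ind, r],
                    "per_capita_consumption_transgression": result.per_capita_T_cons.loc[
                        ind, r
                    ],
                    "notrade_transgression": result.counterfactual.T_notrade.loc[ind, r],
                    "alleviation": result.counterfactual.delta.loc[ind, r],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_float_repr)


def write_provenance(path, *, inputs: dict[str, Path], config: dict, seed=None) -> None:
    """Record input file hashes and run configuration as JSON."""
    hashes = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.iterdir()):
                if f.is_file():
                    hashes[f"{name}/{f.name}"] = hashlib.sha256(f.read_bytes()).hexdigest()
        elif p.is_file():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(
        json.dumps({"inputs": hashes, "config": config, "seed": seed}, indent=2)
    )
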