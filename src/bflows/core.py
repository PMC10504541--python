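"""Labelled containers for multi-regional input-output (MRIO) footprint accounting.

The canonical axis ordering everywhere is region-major, sector-minor: a
matrix over "region-sectors" is indexed by a :class:`pandas.MultiIndex`
built as ``regions x sectors``.  Four environmental indicators are carried
throughout, each with a fixed internal unit:

====================  =============================
indicator             unit
====================  =============================
water                 km3/yr  (blue water use)
land                  km2     (cropland/pasture use)
nitrogen              t/yr    (N application)
phosphorus            t/yr    (P application)
====================  =============================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDICATORS: tuple[str, ...] = ("water", "land", "nitrogen", "phosphorus")

UNITS: dict[str, str] = {
    "water": "km3/yr",
    "land": "km2",
    "nitrogen": "t/yr",
    "phosphorus": "t/yr",
}

#: Proxy used to allocate each global boundary to countries.  Water, nitrogen
#: and phosphorus boundaries follow long-run renewable water availability;
#: the land boundary follows national farmland area.
DEFAULT_PROXY_MAPPING: dict[str, str] = {
    "water": "water_availability",
    "nitrogen": "water_availability",
    "phosphorus": "water_availability",
    "land": "farmland_area",
}

PROXY_COLUMNS: tuple[str, ...] = ("water_availability", "farmland_area", "population")

PROXY_UNITS: dict[str, str] = {
    "water_availability": "km3/yr",
    "farmland_area": "km2",
    "population": "persons",
}


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant.

    The message always names the offending object (file, row, column) so a
    failure in a multi-file world directory can be located directly.
    """


def region_sector_index(regions, sectors) -> pd.MultiIndex:
    """Canonical region-major (region, sector) MultiIndex."""
    return pd.MultiIndex.from_product(
        [list(regions), list(sectors)], names=["region", "sector"]
    )


def _check_nonnegative(values: np.ndarray, labels, what: str) -> None:
    values = np.asarray(values)
    bad = np.argwhere(values < 0)
    if bad.size:
        i = tuple(bad[0])
        lab = labels(i) if callable(labels) else labels
        raise ValidationError(f"{what}: negative value {values[i]!r} at {lab}")


@dataclass
class MRIOTable:
    """A multi-regional input-output table.

    Attributes
    ----------
    A : pandas.DataFrame
        Technical-coefficient matrix, (region, sector) x (region, sector).
        Entry ``A[j, k]`` is the input from region-sector *j* required per
        unit of gross output of region-sector *k*.
    Y : pandas.DataFrame
        Bilateral final demand, rows (origin region, sector), columns the
        destination (consuming) region.
    x : pandas.Series
        Gross output per (region, sector).
    food_mask : pandas.Series
        Boolean per sector, True for food sectors.
    """

    A: pd.DataFrame
    Y: pd.DataFrame
    x: pd.Series
    food_mask: pd.Series

    @property
    def regions(self) -> list[str]:
        return list(self.A.index.get_level_values("region").unique())

    @property
    def sectors(self) -> list[str]:
        return list(self.food_mask.index)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def index(self) -> pd.MultiIndex:
        return self.A.index

    def food_rows(self) -> np.ndarray:
        """Boolean over region-sectors, True where the sector is a food sector."""
        sectors = self.A.index.get_level_values("sector")
        return self.food_mask.reindex(sectors).to_numpy(dtype=bool)

    def validate(self, balance_rtol: float = 1e-6) -> None:
        idx = region_sector_index(self.regions, self.sectors)
        if not self.A.index.equals(idx) or not self.A.columns.equals(idx):
            raise ValidationError(
                "A: index/columns are not the canonical region-major "
                f"(region, sector) product of regions={self.regions} and "
                f"sectors={self.sectors}"
            )
        if not self.Y.index.equals(idx):
            raise ValidationError("Y: row index does not match A's region-sectors")
        if list(self.Y.columns) != self.regions:
            raise ValidationError(
                f"Y: destination columns {list(self.Y.columns)} != regions {self.regions}"
            )
        if not self.x.index.equals(idx):
            raise ValidationError("x: index does not match A's region-sectors")
        _check_nonnegative(
            self.A.to_numpy(),
            lambda i: f"row {self.A.index[i[0]]}, column {self.A.columns[i[1]]}",
            "A",
        )
        _check_nonnegative(
            self.Y.to_numpy(),
            lambda i: f"row {self.Y.index[i[0]]}, column {self.Y.columns[i[1]]}",
            "Y",
        )
        _check_nonnegative(self.x.to_numpy(), lambda i: f"{self.x.index[i[0]]}", "x")
        colsums = self.A.to_numpy().sum(axis=0)
        bad = np.argwhere(colsums >= 1.0)
        if bad.size:
            j = int(bad[0][0])
            raise ValidationError(
                f"A: column sum {colsums[j]:.6g} >= 1 for column "
                f"{self.A.columns[j]} (non-productive economy)"
            )
        # Real tables carry rounding/import imbalances: warn, don't fail.
        supplied = self.A.to_numpy() @ self.x.to_numpy() + self.Y.to_numpy().sum(axis=1)
        scale = max(1.0, float(np.abs(self.x.to_numpy()).max()))
        resid = float(np.abs(self.x.to_numpy() - supplied).max()) / scale
        if resid > balance_rtol:
            warnings.warn(
                f"MRIO balance residual {resid:.3g} exceeds {balance_rtol:.1g}: "
                "x != A.x + sum(Y) (unbalanced table)",
                stacklevel=2,
            )


@dataclass
class ExtensionSet:
    """Direct environmental impacts per (region, sector), one row per indicator."""

    E: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(UNITS))

    def validate(self, x: pd.Series | None = None) -> None:
        if list(self.E.index) != list(INDICATORS):
            raise ValidationError(
                f"extensions: indicators {list(self.E.index)} != {list(INDICATORS)}"
            )
        for ind in INDICATORS:
            if self.units.get(ind) != UNITS[ind]:
                raise ValidationError(
                    f"extensions: indicator {ind!r} declared unit "
                    f"{self.units.get(ind)!r}, expected {UNITS[ind]!r}"
                )
        _check_nonnegative(
            self.E.to_numpy(),
            lambda i: f"indicator {self.E.index[i[0]]}, column {self.E.columns[i[1]]}",
            "extensions",
        )
        if x is not None:
            zero = x.to_numpy() == 0
            impact = self.E.to_numpy() > 0
            bad = np.argwhere(impact & zero[None, :])
            if bad.size:
                e, j = bad[0]
                raise ValidationError(
                    f"extensions: impact {self.E.iat[e, j]!r} for indicator "
                    f"{self.E.index[e]} at {self.E.columns[j]} but gross output is 0"
                )


@dataclass
class ProxyTable:
    """Per-region downscaling proxies and population.

    Columns: ``water_availability`` (km3/yr, 30-year mean renewable
    freshwater), ``farmland_area`` (km2) and ``population`` (persons).
    """

    table: pd.DataFrame

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    @property
    def population(self) -> pd.Series:
        return self.table["population"]

    def validate(self) -> None:
        missing = [c for c in PROXY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"proxies: missing columns {missing}")
        _check_nonnegative(
            self.table.to_numpy(),
            lambda i: f"region {self.table.index[i[0]]}, column {self.table.columns[i[1]]}",
            "proxies",
        )
        for col in PROXY_COLUMNS:
            if not (self.table[col] > 0).any():
                raise ValidationError(f"proxies: column {col!r} has no positive value")


@dataclass(frozen=True)
class PlanetaryBoundarySet:
    """Global safe-operating-space limits for food systems, one per indicator."""

    water: float
    land: float
    nitrogen: float
    phosphorus: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {ind: float(getattr(self, ind)) for ind in INDICATORS}, name="boundary"
        )

    def validate(self) -> None:
        for ind in INDICATORS:
            v = getattr(self, ind)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"planetary boundary for {ind!r} must be positive, got {v!r}"
                )


@dataclass
class NationalBoundarySet:
    """Downscaled national boundaries: indicator x region, boundary units.

    ``provenance`` records which proxy allocated each indicator.
    """

    NB: pd.DataFrame
    provenance: dict[str, str]

    @property
    def regions(self) -> list[str]:
        return list(self.NB.columns)
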