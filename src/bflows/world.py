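"""Synthetic multi-regional economies for testing the accounting pipeline.

The generator produces small worlds with the statistical structure the
analysis assumes: a productive technical-coefficient matrix, bilateral
final demand with a controlled cross-border share, heavy-tailed direct
impact intensities concentrated in food sectors, downscaling proxies
positively correlated with food output, and global boundaries set as a
fixed fraction of global direct impacts (so a tightness below one
guarantees at least one transgressing region per indicator).

Food sectors sell only to final demand by default (their rows of A are
zero): food products are modelled as final consumption goods whose supply
chains draw on non-food intermediates.  Under this structure every unit of
food-sector impact reaches final food demand, so consumption-based food
accounts conserve production-based totals exactly; a
``food_intermediate_share`` switch relaxes it for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    INDICATORS,
    ExtensionSet,
    MRIOTable,
    PlanetaryBoundarySet,
    ProxyTable,
    ValidationError,
    region_sector_index,
)

# Indicative per-unit-output impact scales (lognormal medians) per indicator.
_INTENSITY_BASE = {"water": 1.0, "land": 5.0, "nitrogen": 200.0, "phosphorus": 50.0}


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world.

    Attributes
    ----------
    n_regions, n_sectors
        World size; the full economy has ``n_regions * n_sectors``
        region-sectors.
    food_sector_ids
        Indices of sectors flagged as food (nonempty subset).
    seed
        Seed for all randomness; equal seeds give bit-identical worlds.
    intensity_dispersion
        Log-scale standard deviation of direct impact intensities across
        region-sectors (heavy-tailed heterogeneity).
    trade_openness
        Share of each region's final demand sourced from abroad, in [0, 1].
    boundary_tightness
        Ratio of each global boundary to the global direct food impact of
        its indicator; below 1 at least one region must transgress.
    population_range
        Inclusive bounds for uniform integer population draws.
    food_intermediate_share
        Fraction of intermediate supply allowed to come from food sectors
        (0 by default: food is a pure final product).
    nonfood_intensity_scale
        Relative scale of non-food direct intensities (0 by default: the
        four indicators are treated as agricultural).
    """

    n_regions: int = 6
    n_sectors: int = 8
    food_sector_ids: tuple[int, ...] = (0, 1, 2)
    seed: int = 0
    intensity_dispersion: float = 1.0
    trade_openness: float = 0.25
    boundary_tightness: float = 0.7
    population_range: tuple[int, int] = (1_000_000, 100_000_000)
    food_intermediate_share: float = 0.0
    nonfood_intensity_scale: float = 0.0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValidationError(f"WorldSpec: n_regions must be >= 1, got {self.n_regions}")
        if self.n_sectors < 1:
            raise ValidationError(f"WorldSpec: n_sectors must be >= 1, got {self.n_sectors}")
        ids = tuple(self.food_sector_ids)
        if not ids:
            raise ValidationError("WorldSpec: food_sector_ids must be nonempty")
        if len(set(ids)) != len(ids) or any(i < 0 or i >= self.n_sectors for i in ids):
            raise ValidationError(
                f"WorldSpec: food_sector_ids {ids} not a subset of "
                f"range({self.n_sectors})"
            )
        if not 0.0 <= self.trade_openness <= 1.0:
            raise ValidationError(
                f"WorldSpec: trade_openness must be in [0, 1], got {self.trade_openness}"
            )
        if self.boundary_tightness <= 0:
            raise ValidationError(
                f"WorldSpec: boundary_tightness must be positive, got {self.boundary_tightness}"
            )
        if self.intensity_dispersion <= 0:
            raise ValidationError(
                f"WorldSpec: intensity_dispersion must be positive, got {self.intensity_dispersion}"
            )
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValidationError(
                f"WorldSpec: population_range must be positive with lo <= hi, got {self.population_range}"
            )
        if not 0.0 <= self.food_intermediate_share <= 1.0:
            raise ValidationError(
                "WorldSpec: food_intermediate_share must be in [0, 1], "
                f"got {self.food_intermediate_share}"
            )


@dataclass
class SyntheticWorld:
    """A complete synthetic input set for the pipeline."""

    mrio: MRIOTable
    extensions: ExtensionSet
    proxies: ProxyTable
    planetary_boundaries: PlanetaryBoundarySet

    @property
    def population(self) -> pd.Series:
        return self.proxies.population

    def validate(self) -> None:
        self.mrio.validate(balance_rtol=1e-9)
        self.extensions.validate(self.mrio.x)
        self.proxies.validate()
        self.planetary_boundaries.validate()
        if self.proxies.regions != self.mrio.regions:
            raise ValidationError(
                f"world: proxy regions {self.proxies.regions} != MRIO regions {self.mrio.regions}"
            )
        if list(self.extensions.E.columns) != list(self.mrio.index):
            raise ValidationError("world: extension columns do not match MRIO region-sectors")


def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Draw a reproducible, economically valid world from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R, S = spec.n_regions, spec.n_sectors
    n = R * S
    regions = [f"R{i + 1}" for i in range(R)]
    sectors = [f"S{j + 1}" for j in range(S)]
    idx = region_sector_index(regions, sectors)
    food_mask = pd.Series(
        [j in set(spec.food_sector_ids) for j in range(S)], index=sectors, name="is_food"
    )
    food_rows = np.tile(food_mask.to_numpy(), R)

    # Technical coefficients: sparse nonnegative raw draws, food rows damped
    # by food_intermediate_share, columns rescaled to sums in (0, 0.7).
    raw = rng.gamma(shape=1.0, scale=1.0, size=(n, n))
    raw *= rng.random((n, n)) < 0.5
    raw[food_rows, :] *= spec.food_intermediate_share
    col_targets = rng.uniform(0.2, 0.65, size=n)
    sums = raw.sum(axis=0)
    scale = np.where(sums > 0, col_targets / np.where(sums > 0, sums, 1.0), 0.0)
    A = raw * scale[None, :]

    # Bilateral final demand: lognormal totals per (consumer, sector), the
    # foreign share spread over other regions by Dirichlet weights.
    Y = np.zeros((n, R))
    for s in range(R):
        totals = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=S)
        for j in range(S):
            t = totals[j]
            if R == 1:
                Y[s * S + j, s] = t
                continue
            foreign = [r for r in range(R) if r != s]
            w = rng.dirichlet(np.ones(len(foreign)))
            Y[s * S + j, s] += t * (1.0 - spec.trade_openness)
            for wgt, r in zip(w, foreign):
                Y[r * S + j, s] += t * spec.trade_openness * wgt

    x = np.linalg.solve(np.eye(n) - A, Y.sum(axis=1))

    # Direct impact intensities: lognormal over food sectors (all four
    # indicators), optionally a damped tail over non-food sectors.
    E = np.zeros((len(INDICATORS), n))
    for e, ind in enumerate(INDICATORS):
        q = _INTENSITY_BASE[ind] * rng.lognormal(
            mean=0.0, sigma=spec.intensity_dispersion, size=n
        )
        q = np.where(food_rows, q, q * spec.nonfood_intensity_scale)
        E[e] = q * x

    # Proxies correlated (rho ~ 0.5) with regional food output so boundaries
    # are plausible and transgression is non-degenerate.
    food_output = x.reshape(R, S)[:, food_mask.to_numpy()].sum(axis=1)
    rho = 0.5
    if R > 1 and food_output.std() > 0:
        z = (np.log(food_output) - np.log(food_output).mean()) / np.log(food_output).std()
    else:
        z = np.zeros(R)
    proxy = {}
    for name, base in (("water_availability", 50.0), ("farmland_area", 1000.0)):
        eps = rng.standard_normal(R)
        proxy[name] = base * np.exp(rho * z + np.sqrt(1 - rho**2) * eps)
    lo, hi = spec.population_range
    proxy["population"] = rng.integers(lo, hi + 1, size=R).astype(float)
    proxies = ProxyTable(
        pd.DataFrame(proxy, index=pd.Index(regions, name="region"))
    )

    # Global boundaries as a fixed fraction of global direct food impacts.
    global_food_impact = (E * food_rows[None, :]).sum(axis=1)
    pb = PlanetaryBoundarySet(
        **{
            ind: float(spec.boundary_tightness * global_food_impact[e])
            for e, ind in enumerate(INDICATORS)
        }
    )

    mrio = MRIOTable(
        A=pd.DataFrame(A, index=idx, columns=idx),
        Y=pd.DataFrame(Y, index=idx, columns=pd.Index(regions, name="region")),
        x=pd.Series(x, index=idx, name="gross_output"),
        food_mask=food_mask,
    )
    extensions = ExtensionSet(
        E=pd.DataFrame(E, index=pd.Index(list(INDICATORS), name="indicator"), columns=idx)
    )
    world = SyntheticWorld(
        mrio=mrio, extensions=extensions, proxies=proxies, planetary_boundaries=pb
    )
    world.validate()
    return world


def autarky_variant(world: SyntheticWorld) -> SyntheticWorld:
    """Re-source all final demand domestically, conserving demand totals.

    Each (consuming region, sector) keeps its total final demand but buys
    it all from the domestic sector.  The intermediate structure (A) is
    unchanged; gross output is re-balanced and direct impacts are rescaled
    at fixed intensities to the new output.
    """
    mrio = world.mrio
    regions, sectors = mrio.regions, mrio.sectors
    R, S = len(regions), len(sectors)
    n = R * S
    Yv = mrio.Y.to_numpy(dtype=float)
    totals = Yv.reshape(R, S, R).sum(axis=0)  # sector x consumer totals
    Y2 = np.zeros_like(Yv)
    for s in range(R):
        for j in range(S):
            Y2[s * S + j, s] = totals[j, s]
    A = mrio.A.to_numpy(dtype=float)
    x2 = np.linalg.solve(np.eye(n) - A, Y2.sum(axis=1))
    x2 = np.where(np.abs(x2) < 1e-12, 0.0, x2)
    xv = mrio.x.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = np.where(xv > 0, world.extensions.E.to_numpy() / np.where(xv > 0, xv, 1.0), 0.0)
    E2 = intensity * x2[None, :]
    mrio2 = MRIOTable(
        A=mrio.A.copy(),
        Y=pd.DataFrame(Y2, index=mrio.Y.index, columns=mrio.Y.columns),
        x=pd.Series(x2, index=mrio.x.index, name="gross_output"),
        food_mask=mrio.food_mask.copy(),
    )
    ext2 = ExtensionSet(
        E=pd.DataFrame(E2, index=world.extensions.E.index, columns=world.extensions.E.columns),
        units=dict(world.extensions.units),
    )
    out = SyntheticWorld(
        mrio=mrio2,
        extensions=ext2,
        proxies=ProxyTable(world.proxies.table.copy()),
        planetary_boundaries=world.planetary_boundaries,
    )
    out.validate()
    return out


def duo_fixture() -> SyntheticWorld:
    """The fixed two-region, two-sector hand-checkable world.

    Regions R1, R2; sectors ``food`` and ``other``.  Each region's food
    sector uses 0.2 units of domestic "other" per unit output and sells
    only to final consumers: R1's food goes 80 to R1 and 20 to R2, R2's
    90 to R2 and 10 to R1; "other" has 50 of domestic final demand each.
    Gross outputs are therefore food 100/100 and other 70/70.  Water use
    is 300 km3 at R1's food sector and 100 km3 at R2's; the global water
    boundary of 250 km3 splits over water availability (100, 150) into
    national boundaries of 100 and 150 km3.  Populations are 10 and 20.
    The other three indicators carry no impacts.
    """
    regions = ["R1", "R2"]
    sectors = ["food", "other"]
    idx = region_sector_index(regions, sectors)
    A = pd.DataFrame(0.0, index=idx, columns=idx)
    A.loc[("R1", "other"), ("R1", "food")] = 0.2
    A.loc[("R2", "other"), ("R2", "food")] = 0.2
    Y = pd.DataFrame(0.0, index=idx, columns=pd.Index(regions, name="region"))
    Y.loc[("R1", "food"), "R1"] = 80.0
    Y.loc[("R1", "food"), "R2"] = 20.0
    Y.loc[("R2", "food"), "R2"] = 90.0
    Y.loc[("R2", "food"), "R1"] = 10.0
    Y.loc[("R1", "other"), "R1"] = 50.0
    Y.loc[("R2", "other"), "R2"] = 50.0
    x = pd.Series([100.0, 70.0, 100.0, 70.0], index=idx, name="gross_output")
    food_mask = pd.Series([True, False], index=sectors, name="is_food")
    E = pd.DataFrame(
        0.0, index=pd.Index(list(INDICATORS), name="indicator"), columns=idx
    )
    E.loc["water", ("R1", "food")] = 300.0
    E.loc["water", ("R2", "food")] = 100.0
    proxies = ProxyTable(
        pd.DataFrame(
            {
                "water_availability": [100.0, 150.0],
                "farmland_area": [1.0, 1.0],
                "population": [10.0, 20.0],
            },
            index=pd.Index(regions, name="region"),
        )
    )
    pb = PlanetaryBoundarySet(water=250.0, land=100.0, nitrogen=100.0, phosphorus=100.0)
    world = SyntheticWorld(
        mrio=MRIOTable(A=A, Y=Y, x=x, food_mask=food_mask),
        extensions=ExtensionSet(E=E),
        proxies=proxies,
        planetary_boundaries=pb,
    )
    world.validate()
    return world
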