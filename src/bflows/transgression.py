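"""National-boundary transgression and its bilateral virtual flows.

A region transgresses a national boundary when its production-based food
footprint exceeds it: ``T = max(F_prod - NB, 0)``.  The transgression
fraction ``tau = T / F_prod`` is the share of the region's direct food
impact that lies above the boundary.  Scaling each region's direct
intensities by its tau and embodying through the Leontief inverse yields
transgressed footprint coefficients, whose product with bilateral final
food demand gives the virtual flow of transgression from producing to
consuming regions:

    flow[r, s] = sum_{i in food} EFtran[(r, i)] * Y[(r, i), s]

Two attributions are supported: ``product_origin`` labels a flow by the
region producing the final food product (the formula above), while
``impact_source`` labels it by the region where the transgressed impact
physically occurs (relevant when intermediates cross borders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .core import INDICATORS, UNITS, ValidationError

ATTRIBUTION_MODES = ("product_origin", "impact_source")


@dataclass
class FlowMatrix:
    """Virtual transgression flows, indicator x origin region x destination region."""

    data: xr.DataArray  # dims: (indicator, origin, destination)
    attribution_mode: str
    units: dict[str, str]

    @property
    def regions(self) -> list[str]:
        return [str(r) for r in self.data.coords["origin"].values]

    def total(self) -> pd.Series:
        """Per-indicator grand total over all origin-destination pairs."""
        return self.data.sum(("origin", "destination")).to_series()

    def to_frame(self) -> pd.DataFrame:
        """Long edge list: indicator, origin, destination, value."""
        arr = self.data
        idx = pd.MultiIndex.from_product(
            [
                [str(v) for v in arr.coords["indicator"].values],
                [str(v) for v in arr.coords["origin"].values],
                [str(v) for v in arr.coords["destination"].values],
            ],
            names=["indicator", "origin", "destination"],
        )
        return (
            pd.DataFrame({"value": arr.values.ravel()}, index=idx)
            .reset_index()
        )


def compute_transgression(
    F_prod: pd.DataFrame, NB: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transgressed amount T = max(F_prod - NB, 0) and fraction tau = T / F_prod.

    tau is 0 where the footprint is 0 (nothing to transgress) and 1 where
    the boundary is 0 but the footprint is positive (all impact lies beyond
    the safe operating space).
    """
    NB = NB.reindex(index=F_prod.index, columns=F_prod.columns)
    F = F_prod.to_numpy(dtype=float)
    B = NB.to_numpy(dtype=float)
    T = np.maximum(F - B, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(F > 0, T / np.where(F > 0, F, 1.0), 0.0)
    Tdf = pd.DataFrame(T, index=F_prod.index, columns=F_prod.columns)
    taudf = pd.DataFrame(tau, index=F_prod.index, columns=F_prod.columns)
    return Tdf, taudf


def transgressed_intensities(D: pd.DataFrame, tau: pd.DataFrame) -> pd.DataFrame:
    """Scale each region's direct intensities by its per-indicator tau.

    Allocates a region's transgression proportionally over its direct
    impacts: a uniform fraction per region-indicator, so flow totals
    reproduce the transgression totals exactly.
    """
    regions = D.columns.get_level_values("region")
    scale = tau.reindex(columns=regions.unique())
    factors = scale.loc[:, regions].to_numpy(dtype=float)
    return pd.DataFrame(
        D.to_numpy() * factors, index=D.index, columns=D.columns
    )


def transgressed_coefficients(
    D: pd.DataFrame, tau: pd.DataFrame, L: pd.DataFrame
) -> pd.DataFrame:
    """Transgressed embodied coefficients EFtran = (tau o D) L <= EF."""
    return pd.DataFrame(
        transgressed_intensities(D, tau).to_numpy() @ L.to_numpy(),
        index=D.index,
        columns=L.columns,
    )


def bilateral_flows(
    Dtran: pd.DataFrame,
    L: pd.DataFrame,
    Y: pd.DataFrame,
    food_mask: pd.Series | None,
    mode: str = "product_origin",
) -> FlowMatrix:
    """Virtual flows of transgressed impact embodied in (food) final demand.

    Parameters
    ----------
    Dtran
        Transgression-scaled direct intensities (from
        :func:`transgressed_intensities`).
    L
        Leontief inverse.
    Y
        Bilateral final demand, (origin region, sector) x destination region.
    food_mask
        Restrict final demand to food sectors; ``None`` uses all final
        demand, under which flow totals equal transgression totals exactly.
    mode
        ``product_origin`` (default): flows labelled by the region selling
        the final product.  ``impact_source``: labelled by the region where
        the transgressed impact occurs.
    """
    if mode not in ATTRIBUTION_MODES:
        raise ValidationError(
            f"bilateral_flows: unknown attribution mode {mode!r}; "
            f"expected one of {ATTRIBUTION_MODES}"
        )
    Yv = Y.to_numpy(dtype=float)
    if food_mask is not None:
        sectors = Y.index.get_level_values("sector")
        keep = food_mask.reindex(sectors).to_numpy(dtype=bool)
        Yv = np.where(keep[:, None], Yv, 0.0)
    regions = list(Y.index.get_level_values("region").unique())
    dest = list(Y.columns)
    n_ind = Dtran.shape[0]
    R = len(regions)
    # group matrix G: region x region-sector membership
    row_regions = Y.index.get_level_values("region")
    G = np.asarray(
        [[1.0 if r == rr else 0.0 for rr in row_regions] for r in regions]
    )
    if mode == "product_origin":
        EFtran = Dtran.to_numpy() @ L.to_numpy()
        contrib = EFtran[:, :, None] * Yv[None, :, :]  # indicator x (r,i) x dest
    else:  # impact_source
        X = L.to_numpy() @ Yv  # output required per destination
        contrib = Dtran.to_numpy()[:, :, None] * X[None, :, :]
    flow = np.einsum("oj,ejs->eos", G, contrib)
    data = xr.DataArray(
        flow,
        dims=("indicator", "origin", "destination"),
        coords={"indicator": list(Dtran.index), "origin": regions, "destination": dest},
        name="transgression_flow",
    )
    return FlowMatrix(data=data, attribution_mode=mode, units=dict(UNITS))


def consumption_transgression(flows: FlowMatrix) -> pd.DataFrame:
    """Transgression embodied in each region's consumption: column sums of flows."""
    s = flows.data.sum("origin")
    out = s.to_pandas()
    out.columns.name = "region"
    out.index.name = "indicator"
    return out


def production_transgression_exports(flows: FlowMatrix) -> pd.DataFrame:
    """Per origin region, transgression exported to other regions (diagonal excluded)."""
    arr = flows.data
    R = arr.sizes["origin"]
    off = arr.values * (1.0 - np.eye(R))[None, :, :]
    return pd.DataFrame(
        off.sum(axis=2), index=list(arr.coords["indicator"].values), columns=flows.regions
    )


def top_links(
    flows: FlowMatrix, k: int, include_domestic: bool = True
) -> pd.DataFrame:
    """The k largest flows per indicator, descending; ties broken by labels.

    Zero flows are omitted; domestic (origin == destination) links are kept
    unless ``include_domestic=False``.
    """
    if k < 1:
        raise ValidationError(f"top_links: k must be >= 1, got {k}")
    df = flows.to_frame()
    if not include_domestic:
        df = df[df["origin"] != df["destination"]]
    df = df[df["value"] > 0]
    df = df.sort_values(
        ["indicator", "value", "origin", "destination"],
        ascending=[True, False, True, True],
        key=lambda col: col.map({i: n for n, i in enumerate(INDICATORS)})
        if col.name == "indicator"
        else col,
    )
    out = df.groupby("indicator", sort=False).head(k).reset_index(drop=True)
    return out[["indicator", "origin", "destination", "value"]]


@dataclass
class TransgressionResult:
    """Transgression accounts for one world."""

    T: pd.DataFrame  # indicator x region, transgressed production footprint
    tau: pd.DataFrame  # indicator x region, transgression fraction in [0, 1]
    EFtran: pd.DataFrame  # indicator x (region, sector) transgressed coefficients
    T_cons: pd.DataFrame  # indicator x region, consumption-based transgression
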