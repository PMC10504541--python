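"""No-trade counterfactual: self-sufficient food supply and trade's net effect.

The counterfactual assumes every region meets its total food final demand
``y_i^s = sum_r Y[(r,i), s]`` from domestic production.  Two variants ship:

``coefficient``
    Applies the region's own current transgressed coefficients to its total
    food demand, ``T_notrade[s] = sum_i EFtran[(s,i)] * y_i^s``.  Where a
    region does not produce a food sector, the output-weighted global
    average coefficient is substituted.
``recompute``
    Applies untransgressed coefficients to obtain the counterfactual
    footprint, then re-evaluates the boundary:
    ``T_notrade[s] = max(sum_i EF[(s,i)] * y_i^s - NB[s], 0)``.  This
    variant is internally consistent (self-sufficiency changes footprints,
    hence transgression) and depends only on demand totals, not on how
    current trade partitions them across origins.

Alleviation is ``delta = T_notrade - T_actual`` against the production-based
transgression: positive delta means trade relieved pressure on the region's
boundary; the per-indicator sum of delta is the global saving from trade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MRIOTable, ValidationError

COUNTERFACTUAL_MODES = ("coefficient", "recompute")


def domestic_food_demand(Y: pd.DataFrame, food_mask: pd.Series) -> pd.DataFrame:
    """Total food final demand per (food sector, consuming region), all origins.

    Returns a food-sector x region table; under self-sufficiency each entry
    is produced where it is consumed.
    """
    sectors = Y.index.get_level_values("sector")
    keep = food_mask.reindex(sectors).to_numpy(dtype=bool)
    food_sectors = [s for s in food_mask.index if food_mask[s]]
    totals = (
        Y.loc[keep]
        .groupby(level="sector", sort=False)
        .sum()
        .reindex(food_sectors, fill_value=0.0)
    )
    totals.index.name = "sector"
    return totals


def global_average_coefficient(
    coefficients: pd.DataFrame, x: pd.Series, sector: str
) -> pd.Series:
    """Output-weighted global mean coefficient for one sector, per indicator.

    ``sum_r c[(r,i)] x[(r,i)] / sum_r x[(r,i)]`` over producing regions.
    """
    cols = coefficients.columns
    in_sector = cols.get_level_values("sector") == sector
    if not in_sector.any():
        raise ValidationError(f"global_average_coefficient: unknown sector {sector!r}")
    w = x.to_numpy(dtype=float)[in_sector]
    total = w.sum()
    if total <= 0:
        raise ValidationError(
            f"global_average_coefficient: no region produces sector {sector!r}; "
            "cannot impute a global average"
        )
    C = coefficients.loc[:, in_sector].to_numpy(dtype=float)
    return pd.Series(C @ w / total, index=coefficients.index)


def _imputed_coefficients(
    coefficients: pd.DataFrame,
    x: pd.Series,
    food_sectors: list[str],
    regions: list[str],
    produced_threshold: float,
) -> dict[str, pd.DataFrame]:
    """Per food sector: indicator x region coefficient table with imputation.

    A region counts as producing sector i when its output share of the
    sector's global output exceeds ``produced_threshold`` (strictly greater
    than zero when the threshold is zero); otherwise the global average is
    substituted.
    """
    out: dict[str, pd.DataFrame] = {}
    for sector in food_sectors:
        cols = [(r, sector) for r in regions]
        xi = x.loc[cols].to_numpy(dtype=float)
        total = xi.sum()
        if total <= 0:
            raise ValidationError(
                f"no-trade counterfactual: no region produces food sector "
                f"{sector!r}; cannot impute a global average"
            )
        avg = global_average_coefficient(coefficients, x, sector)
        C = coefficients.loc[:, cols].to_numpy(dtype=float).copy()
        not_produced = (xi / total) <= produced_threshold if produced_threshold > 0 else xi <= 0
        C[:, not_produced] = avg.to_numpy()[:, None]
        out[sector] = pd.DataFrame(C, index=coefficients.index, columns=regions)
    return out


def no_trade_transgression(
    mrio: MRIOTable,
    NB: pd.DataFrame,
    EF: pd.DataFrame,
    EFtran: pd.DataFrame,
    mode: str = "coefficient",
    produced_threshold: float = 0.0,
) -> pd.DataFrame:
    """Counterfactual transgression under food self-sufficiency (indicator x region)."""
    if mode not in COUNTERFACTUAL_MODES:
        raise ValidationError(
            f"no_trade_transgression: unknown mode {mode!r}; "
            f"expected one of {COUNTERFACTUAL_MODES}"
        )
    regions = mrio.regions
    food_sectors = [s for s in mrio.sectors if mrio.food_mask[s]]
    y = domestic_food_demand(mrio.Y, mrio.food_mask)
    coeff = EFtran if mode == "coefficient" else EF
    per_sector = _imputed_coefficients(
        coeff, mrio.x, food_sectors, regions, produced_threshold
    )
    F = np.zeros((len(coeff.index), len(regions)))
    for sector in food_sectors:
        F += per_sector[sector].to_numpy() * y.loc[sector].to_numpy()[None, :]
    F = pd.DataFrame(F, index=coeff.index, columns=regions)
    F.columns.name = "region"
    if mode == "coefficient":
        return F
    NB = NB.reindex(index=F.index, columns=F.columns)
    return (F - NB).clip(lower=0.0)


def alleviation(
    T_actual: pd.DataFrame, T_notrade: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """delta = T_notrade - T_actual per region; global savings = sum of delta.

    Positive delta: trade alleviated the region's boundary transgression
    (self-sufficiency would have been worse).  Negative delta: the region's
    transgression supports exports (trade aggravates).
    """
    T_notrade = T_notrade.reindex(index=T_actual.index, columns=T_actual.columns)
    delta = T_notrade - T_actual
    return delta, delta.sum(axis=1)


@dataclass
class CounterfactualResult:
    """No-trade scenario outcome for one world."""

    T_notrade: pd.DataFrame  # indicator x region
    delta: pd.DataFrame  # indicator x region, alleviation (+) / aggravation (-)
    global_savings: pd.Series  # per indicator
    mode: str
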