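"""Core MRIO arithmetic: Leontief inverse and footprint accounting.

The embodied (life-cycle) footprint coefficient matrix is

    EF = D (I - A)^{-1}

where ``D`` holds direct impact intensities (impact per unit gross output)
and ``(I - A)^{-1}`` is the Leontief inverse of the technical-coefficient
matrix.  Production-based footprints attribute impacts to the territory
where they physically occur; consumption-based footprints attribute the
whole supply-chain impact of final food demand to the consuming region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExtensionSet, MRIOTable, ValidationError


def direct_intensities(extensions: ExtensionSet, x: pd.Series) -> pd.DataFrame:
    """Impact per unit gross output, D = E / x element-wise (0/0 -> 0).

    Raises
    ------
    ValidationError
        If any sector reports a positive impact with zero output.
    """
    E = extensions.E.to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    zero = xv == 0
    bad = np.argwhere((E > 0) & zero[None, :])
    if bad.size:
        e, j = bad[0]
        raise ValidationError(
            f"direct_intensities: impact without output for indicator "
            f"{extensions.E.index[e]} at {extensions.E.columns[j]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(zero[None, :], 0.0, E / np.where(zero, 1.0, xv)[None, :])
    return pd.DataFrame(D, index=extensions.E.index, columns=extensions.E.columns)


def restrict_to_food(D: pd.DataFrame, food_mask: pd.Series) -> pd.DataFrame:
    """Zero out non-food region-sector columns of an intensity matrix."""
    sectors = D.columns.get_level_values("sector")
    keep = food_mask.reindex(sectors).to_numpy(dtype=bool)
    out = D.copy()
    out.loc[:, ~keep] = 0.0
    return out


def leontief_inverse(A: pd.DataFrame, residual_tol: float = 1e-9) -> pd.DataFrame:
    """Solve (I - A) L = I for the Leontief inverse L.

    A linear solve is used rather than explicit inversion; the result is
    accepted only if the max-norm residual of ``(I - A) L - I`` is below
    ``residual_tol``.  A non-productive economy (spectral radius >= 1) is
    rejected.
    """
    n = A.shape[0]
    Av = A.to_numpy(dtype=float)
    # Column sums < 1 certify productivity cheaply; otherwise check the
    # spectral radius directly.
    if Av.sum(axis=0).max() >= 1.0:
        rho = float(np.abs(np.linalg.eigvals(Av)).max())
        if rho >= 1.0:
            raise ValidationError(
                f"leontief_inverse: non-productive economy (spectral radius {rho:.6g} >= 1)"
            )
    M = np.eye(n) - Av
    L = np.linalg.solve(M, np.eye(n))
    resid = float(np.abs(M @ L - np.eye(n)).max())
    if resid > residual_tol:
        raise ValidationError(
            f"leontief_inverse: residual {resid:.3g} exceeds {residual_tol:.1g} "
            "(ill-conditioned table)"
        )
    return pd.DataFrame(L, index=A.index, columns=A.columns)


def embodied_coefficients(D: pd.DataFrame, L: pd.DataFrame) -> pd.DataFrame:
    """Life-cycle footprint coefficients EF = D L (impact per unit final demand)."""
    return pd.DataFrame(
        D.to_numpy() @ L.to_numpy(), index=D.index, columns=L.columns
    )


def production_footprint(
    extensions: ExtensionSet, food_mask: pd.Series
) -> pd.DataFrame:
    """Direct food-sector impacts summed per producing region (indicator x region)."""
    E = extensions.E
    sectors = E.columns.get_level_values("sector")
    keep = food_mask.reindex(sectors).to_numpy(dtype=bool)
    masked = E.loc[:, keep]
    regions = list(E.columns.get_level_values("region").unique())
    F = masked.T.groupby(level="region", sort=False).sum().T
    F = F.reindex(columns=regions, fill_value=0.0)
    F.columns.name = "region"
    return F


def consumption_footprint(
    EF: pd.DataFrame, Y: pd.DataFrame, food_mask: pd.Series | None = None
) -> pd.DataFrame:
    """Supply-chain impacts of final demand, per consuming region.

    ``F_cons[e, s] = sum_{(r,i)} EF[e, (r,i)] * Y[(r,i), s]``, with the sum
    restricted to food sectors when ``food_mask`` is given.  With the mask
    disabled and a balanced table this reproduces total direct impacts
    (global conservation of the accounting identity D L Y 1 = E 1).
    """
    Yv = Y.to_numpy(dtype=float)
    if food_mask is not None:
        sectors = Y.index.get_level_values("sector")
        keep = food_mask.reindex(sectors).to_numpy(dtype=bool)
        Yv = np.where(keep[:, None], Yv, 0.0)
    F = EF.to_numpy() @ Yv
    out = pd.DataFrame(F, index=EF.index, columns=Y.columns)
    out.columns.name = "region"
    return out


def per_capita(values: pd.DataFrame, population: pd.Series) -> pd.DataFrame:
    """Divide per-region values by population (0 footprint / 0 people -> 0)."""
    pop = population.reindex(values.columns).to_numpy(dtype=float)
    v = values.to_numpy(dtype=float)
    zero_pop = pop == 0
    bad = np.argwhere((v != 0) & zero_pop[None, :])
    if bad.size:
        e, r = bad[0]
        raise ValidationError(
            f"per_capita: nonzero value for {values.index[e]!r} in region "
            f"{values.columns[r]!r} with zero population"
        )
    out = np.where(zero_pop[None, :], 0.0, v / np.where(zero_pop, 1.0, pop)[None, :])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


@dataclass
class FootprintResult:
    """Bundle of footprint accounts for one world.

    Attributes
    ----------
    D : indicator x (region, sector) direct intensities actually embodied
        (food-restricted unless non-food impacts were requested).
    EF : indicator x (region, sector) embodied coefficients, D L.
    F_prod : indicator x region production-based food footprints.
    F_cons : indicator x region consumption-based food footprints.
    """

    D: pd.DataFrame
    EF: pd.DataFrame
    F_prod: pd.DataFrame
    F_cons: pd.DataFrame


def compute_footprints(
    mrio: MRIOTable,
    extensions: ExtensionSet,
    *,
    include_nonfood_impacts: bool = False,
    L: pd.DataFrame | None = None,
) -> tuple[FootprintResult, pd.DataFrame]:
    """Run the full footprint account; returns (result, Leontief inverse).

    By default the embodied account is restricted to food-sector direct
    impacts so that the production- and consumption-based accounts describe
    the same impact pool; ``include_nonfood_impacts=True`` embodies every
    sector's impacts.
    """
    D_full = direct_intensities(extensions, mrio.x)
    D = D_full if include_nonfood_impacts else restrict_to_food(D_full, mrio.food_mask)
    if L is None:
        L = leontief_inverse(mrio.A)
    EF = embodied_coefficients(D, L)
    F_prod = production_footprint(extensions, mrio.food_mask)
    F_cons = consumption_footprint(EF, mrio.Y, mrio.food_mask)
    return FootprintResult(D=D, EF=EF, F_prod=F_prod, F_cons=F_cons), L
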