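"""End-to-end analysis: boundaries, footprints, transgression flows, counterfactual."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .boundaries import downscale_boundaries
from .core import (
    ExtensionSet,
    MRIOTable,
    NationalBoundarySet,
    PlanetaryBoundarySet,
    ProxyTable,
)
from .counterfactual import (
    CounterfactualResult,
    alleviation,
    no_trade_transgression,
)
from .footprint import FootprintResult, compute_footprints, per_capita
from .transgression import (
    FlowMatrix,
    TransgressionResult,
    bilateral_flows,
    compute_transgression,
    consumption_transgression,
    transgressed_coefficients,
    transgressed_intensities,
)


@dataclass
class AnalysisResult:
    """All pipeline outputs for one world."""

    boundaries: NationalBoundarySet
    footprints: FootprintResult
    transgression: TransgressionResult
    flows: FlowMatrix
    per_capita_T_cons: pd.DataFrame
    counterfactual: CounterfactualResult
    population: pd.Series


def run_analysis(
    mrio: MRIOTable,
    extensions: ExtensionSet,
    proxies: ProxyTable,
    pb: PlanetaryBoundarySet,
    *,
    include_nonfood_impacts: bool = False,
    attribution: str = "product_origin",
    counterfactual_mode: str = "coefficient",
    produced_threshold: float = 0.0,
    proxy_mapping: dict[str, str] | None = None,
    boundary_overrides: dict[str, dict[str, float]] | None = None,
) -> AnalysisResult:
    """Run the complete accounting chain on one world.

    Steps: downscale global boundaries by proxy ratio; build direct and
    embodied footprint coefficients; production- and consumption-based food
    footprints; boundary transgression and its bilateral virtual flows;
    per-capita consumption-based transgression; and the no-trade
    counterfactual with per-region alleviation and global savings.
    """
    nb = downscale_boundaries(
        pb, proxies, proxy_mapping=proxy_mapping, overrides=boundary_overrides
    )
    fps, L = compute_footprints(
        mrio, extensions, include_nonfood_impacts=include_nonfood_impacts
    )
    T, tau = compute_transgression(fps.F_prod, nb.NB)
    Dtran = transgressed_intensities(fps.D, tau)
    EFtran = transgressed_coefficients(fps.D, tau, L)
    flows = bilateral_flows(Dtran, L, mrio.Y, mrio.food_mask, mode=attribution)
    T_cons = consumption_transgression(flows)
    pc = per_capita(T_cons, proxies.population)
    T_notrade = no_trade_transgression(
        mrio,
        nb.NB,
        fps.EF,
        EFtran,
        mode=counterfactual_mode,
        produced_threshold=produced_threshold,
    )
    delta, savings = alleviation(T, T_notrade)
    return AnalysisResult(
        boundaries=nb,
        footprints=fps,
        transgression=TransgressionResult(T=T, tau=tau, EFtran=EFtran, T_cons=T_cons),
        flows=flows,
        per_capita_T_cons=pc,
        counterfactual=CounterfactualResult(
            T_notrade=T_notrade, delta=delta, global_savings=savings, mode=counterfactual_mode
        ),
        population=proxies.population,
    )
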