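"""Boundary transgression, transgressed coefficients and bilateral flows."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from bflows import (
    INDICATORS,
    ValidationError,
    autarky_variant,
    bilateral_flows,
    compute_transgression,
    consumption_transgression,
    direct_intensities,
    downscale_boundaries,
    embodied_coefficients,
    leontief_inverse,
    production_footprint,
    restrict_to_food,
    top_links,
    transgressed_coefficients,
    transgressed_intensities,
)
from bflows.core import UNITS
from bflows.transgression import FlowMatrix


def duo_parts(duo):
    D = restrict_to_food(
        direct_intensities(duo.extensions, duo.mrio.x), duo.mrio.food_mask
    )
    L = leontief_inverse(duo.mrio.A)
    nb = downscale_boundaries(duo.planetary_boundaries, duo.proxies)
    F = production_footprint(duo.extensions, duo.mrio.food_mask)
    T, tau = compute_transgression(F, nb.NB)
    return D, L, T, tau


def world_parts(w):
    D = restrict_to_food(direct_intensities(w.extensions, w.mrio.x), w.mrio.food_mask)
    L = leontief_inverse(w.mrio.A)
    nb = downscale_boundaries(w.planetary_boundaries, w.proxies)
    F = production_footprint(w.extensions, w.mrio.food_mask)
    T, tau = compute_transgression(F, nb.NB)
    return D, L, T, tau


class TestComputeTransgression:
    def test_duo_values(self, duo):
        _, _, T, tau = duo_parts(duo)
        assert T.loc["water"].tolist() == [200.0, 0.0]
        assert tau.loc["water"].tolist() == [200.0 / 300.0, 0.0]

    def test_footprint_equal_to_boundary_is_safe(self):
        F = pd.DataFrame([[5.0]], index=["water"], columns=["R1"])
        T, tau = compute_transgression(F, F.copy())
        assert T.loc["water", "R1"] == 0.0
        assert tau.loc["water", "R1"] == 0.0

    def test_zero_boundary_means_all_unsustainable(self):
        F = pd.DataFrame([[5.0]], index=["water"], columns=["R1"])
        NB = pd.DataFrame([[0.0]], index=["water"], columns=["R1"])
        T, tau = compute_transgression(F, NB)
        assert T.loc["water", "R1"] == 5.0
        assert tau.loc["water", "R1"] == 1.0

    def test_tau_bounded(self, make_world):
        w = make_world(8)
        _, _, _, tau = world_parts(w)
        assert ((tau.to_numpy() >= 0) & (tau.to_numpy() <= 1)).all()


class TestTransgressedCoefficients:
    def test_duo_scaled_intensities(self, duo):
        D, L, _, tau = duo_parts(duo)
        Dt = transgressed_intensities(D, tau)
        assert np.allclose(Dt.loc["water"].to_numpy(), [2.0, 0.0, 0.0, 0.0], rtol=1e-12)
        EFt = transgressed_coefficients(D, tau, L)
        assert EFt.loc["water", ("R1", "food")] == pytest.approx(2.0, rel=1e-12)
        assert EFt.loc["water", ("R2", "food")] == 0.0

    def test_no_transgression_means_zero(self, duo):
        D, L, _, tau = duo_parts(duo)
        EFt = transgressed_coefficients(D, tau * 0.0, L)
        assert (EFt.to_numpy() == 0).all()

    def test_full_transgression_recovers_ef(self, make_world):
        w = make_world(2)
        D, L, _, tau = world_parts(w)
        EF = embodied_coefficients(D, L)
        EFt = transgressed_coefficients(D, (tau * 0) + 1.0, L)
        assert np.allclose(EFt.to_numpy(), EF.to_numpy(), rtol=1e-12)

    def test_never_exceeds_ef(self, make_world):
        w = make_world(3)
        D, L, _, tau = world_parts(w)
        EF = embodied_coefficients(D, L)
        EFt = transgressed_coefficients(D, tau, L)
        assert (EFt.to_numpy() <= EF.to_numpy() * (1 + 1e-12)).all()


class TestBilateralFlows:
    def test_duo_product_origin(self, duo):
        D, L, T, tau = duo_parts(duo)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, duo.mrio.Y, duo.mrio.food_mask)
        w = fl.data.sel(indicator="water")
        assert float(w.sel(origin="R1", destination="R1")) == pytest.approx(160.0, rel=1e-12)
        assert float(w.sel(origin="R1", destination="R2")) == pytest.approx(40.0, rel=1e-12)
        assert float(np.abs(w.sel(origin="R2")).sum()) == 0.0
        assert float(w.sum()) == pytest.approx(float(T.loc["water"].sum()), rel=1e-12)

    def test_duo_modes_agree_without_cross_region_intermediates(self, duo):
        D, L, _, tau = duo_parts(duo)
        Dt = transgressed_intensities(D, tau)
        a = bilateral_flows(Dt, L, duo.mrio.Y, duo.mrio.food_mask, "product_origin")
        b = bilateral_flows(Dt, L, duo.mrio.Y, duo.mrio.food_mask, "impact_source")
        assert np.allclose(a.data.values, b.data.values, rtol=1e-12)

    def test_autarky_world_flows_are_diagonal(self, make_world):
        aw = autarky_variant(make_world(4))
        D, L, _, tau = world_parts(aw)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, aw.mrio.Y, aw.mrio.food_mask)
        off = fl.data.values * (1 - np.eye(fl.data.sizes["origin"]))[None]
        assert np.abs(off).max() < 1e-12 * max(1.0, fl.data.values.max())

    def test_unknown_mode_fatal(self, duo):
        D, L, _, tau = duo_parts(duo)
        with pytest.raises(ValidationError, match="unknown attribution mode"):
            bilateral_flows(transgressed_intensities(D, tau), L, duo.mrio.Y, None, "typo")

    @pytest.mark.parametrize("mode", ["product_origin", "impact_source"])
    def test_conservation_all_final_demand(self, make_world, mode):
        """With the food mask disabled, flow totals equal transgression totals."""
        w = make_world(5)
        D, L, T, tau = world_parts(w)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, w.mrio.Y, None, mode)
        assert np.allclose(fl.total().to_numpy(), T.sum(axis=1).to_numpy(), rtol=1e-8)

    def test_food_mask_only_drops_flow(self, make_world):
        w = make_world(5)
        D, L, T, tau = world_parts(w)
        masked = bilateral_flows(
            transgressed_intensities(D, tau), L, w.mrio.Y, w.mrio.food_mask
        )
        assert (
            masked.total().to_numpy() <= T.sum(axis=1).to_numpy() * (1 + 1e-8)
        ).all()

    def test_tightening_a_boundary_never_decreases_flows(self, duo):
        D, L, _, _ = duo_parts(duo)
        nb = downscale_boundaries(duo.planetary_boundaries, duo.proxies)
        F = production_footprint(duo.extensions, duo.mrio.food_mask)
        _, tau0 = compute_transgression(F, nb.NB)
        fl0 = bilateral_flows(transgressed_intensities(D, tau0), L, duo.mrio.Y, duo.mrio.food_mask)
        shrunk = nb.NB.copy()
        shrunk.loc["water", "R2"] *= 0.1
        _, tau1 = compute_transgression(F, shrunk)
        fl1 = bilateral_flows(transgressed_intensities(D, tau1), L, duo.mrio.Y, duo.mrio.food_mask)
        assert (fl1.data.values >= fl0.data.values - 1e-12).all()


class TestConsumptionTransgression:
    def test_duo_column_sums(self, duo):
        D, L, _, tau = duo_parts(duo)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, duo.mrio.Y, duo.mrio.food_mask)
        tc = consumption_transgression(fl)
        assert tc.loc["water", "R1"] == pytest.approx(160.0, rel=1e-12)
        assert tc.loc["water", "R2"] == pytest.approx(40.0, rel=1e-12)

    def test_autarky_consumption_equals_production(self, make_world):
        aw = autarky_variant(make_world(7))
        D, L, T, tau = world_parts(aw)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, aw.mrio.Y, aw.mrio.food_mask)
        tc = consumption_transgression(fl)
        assert np.allclose(tc.to_numpy(), T.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_partition_over_destinations(self, make_world):
        w = make_world(1)
        D, L, _, tau = world_parts(w)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, w.mrio.Y, w.mrio.food_mask)
        tc = consumption_transgression(fl)
        assert np.allclose(tc.sum(axis=1).to_numpy(), fl.total().to_numpy(), rtol=1e-12)


def make_flowmatrix(values, regions=("R1", "R2")):
    arr = np.zeros((len(INDICATORS), len(regions), len(regions)))
    arr[0] = values
    data = xr.DataArray(
        arr,
        dims=("indicator", "origin", "destination"),
        coords={
            "indicator": list(INDICATORS),
            "origin": list(regions),
            "destination": list(regions),
        },
    )
    return FlowMatrix(data=data, attribution_mode="product_origin", units=dict(UNITS))


class TestTopLinks:
    def test_duo_ranking_includes_domestic(self, duo):
        D, L, _, tau = duo_parts(duo)
        fl = bilateral_flows(transgressed_intensities(D, tau), L, duo.mrio.Y, duo.mrio.food_mask)
        ranked = top_links(fl, 20)
        water = ranked[ranked["indicator"] == "water"]
        assert list(map(tuple, water[["origin", "destination"]].to_numpy())) == [
            ("R1", "R1"),
            ("R1", "R2"),
        ]
        assert water["value"].tolist() == pytest.approx([160.0, 40.0], rel=1e-12)

    def test_k_one_returns_largest(self):
        fl = make_flowmatrix([[5.0, 1.0], [0.0, 3.0]])
        ranked = top_links(fl, 1)
        water = ranked[ranked["indicator"] == "water"]
        assert water.iloc[0][["origin", "destination"]].tolist() == ["R1", "R1"]

    def test_ties_broken_lexicographically(self):
        fl = make_flowmatrix([[0.0, 4.0], [4.0, 0.0]])
        ranked = top_links(fl, 2)
        water = ranked[ranked["indicator"] == "water"]
        assert list(map(tuple, water[["origin", "destination"]].to_numpy())) == [
            ("R1", "R2"),
            ("R2", "R1"),
        ]

    def test_exclude_domestic(self):
        fl = make_flowmatrix([[9.0, 1.0], [2.0, 8.0]])
        ranked = top_links(fl, 5, include_domestic=False)
        water = ranked[ranked["indicator"] == "water"]
        assert set(map(tuple, water[["origin", "destination"]].to_numpy())) == {
            ("R1", "R2"),
            ("R2", "R1"),
        }

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            top_links(make_flowmatrix([[1.0, 0.0], [0.0, 0.0]]), 0)
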