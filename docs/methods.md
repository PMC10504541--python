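# Methods

## Model

The package implements environmentally extended multi-regional input-output
(MRIO) accounting for food systems, specialised to four indicators — blue
water use, cropland use, nitrogen application and phosphorus application —
and to the question of national-boundary transgression.

An economy of R regions × S sectors is described by a technical-coefficient
matrix `A` (input per unit gross output, region-sector × region-sector),
bilateral final demand `Y` ((origin region, sector) × destination region)
and gross output `x`, satisfying the balance `x = A·x + Y·1`. Direct
impacts `E` per region-sector yield intensities `D = E ⊘ x` (0/0 → 0), and
the embodied coefficient matrix is `EF = D·(I − A)⁻¹`. The Leontief inverse
is obtained by a linear solve of `(I − A)·L = I`, never by explicit
inversion, with a max-norm residual bound of 1e-9; productivity is
certified by column sums < 1 where possible and by the spectral radius
otherwise.

Global boundaries are allocated to regions in proportion to a proxy —
renewable water availability for water, nitrogen and phosphorus, farmland
area for land — so the national boundaries sum exactly to the global value.
Nitrogen and phosphorus boundaries may be configured in Tg/yr and are
converted (1 Tg = 1e6 t) at load; no other unit conversion is ever silent.
The global water boundary has no built-in default and must be supplied in
configuration.

Transgression is `T = max(F_prod − NB, 0)` with fraction `τ = T/F_prod`
(τ = 0 where the footprint is zero, τ = 1 where the boundary is zero but the
footprint positive). The production-based footprint `F_prod` is the sum of
*direct* food-sector impacts per region — impacts are counted where farming
occurs, not embodied in food output; the embodied alternative is available
through the consumption account.

## Allocation of transgression to trade

Transgression is defined at country level, but attributing it to trade
requires per-sector coefficients. The package allocates a region's
transgression proportionally over its direct impacts — a uniform fraction τ
per region-indicator — giving scaled intensities `D̃ = τ∘D` and transgressed
coefficients `EFᵗʳ = D̃·L`. This choice preserves the conservation identity
`Σ_{r,s} flow = Σ_r T` exactly (over all final demand) and is agnostic
about which of a region's sectors "caused" the overshoot; marginal
attributions (charging specific sectors for impacts above the boundary)
would need a sector ordering the data does not provide and are not
implemented.

Two flow attributions are exposed because the consumption narrative is
genuinely ambiguous:

- `product_origin` (default): `flow_{r,s} = Σ_{i∈food} EFᵗʳ_{(r,i)}·Y_{(r,i),s}`
  — labelled by the region selling the final food product.
- `impact_source`: `flow_{r,s} = Σ_{j∈r} D̃_j·[L·Y_s]_j` — labelled by the
  region where the transgressed impact physically occurs.

The two coincide exactly when no intermediates cross borders. Domestic
flows (r = s) are computed and kept; exporter/importer rankings can exclude
the diagonal (`top_links(..., include_domestic=False)`). Ties in the
ranking break lexicographically by (origin, destination) so output is
deterministic.

By default `D` is restricted to food-sector rows before embodiment
(`include_nonfood_impacts=False`), so the production- and consumption-based
accounts describe the same impact pool; the four indicators are treated as
agricultural. The switch embodies all sectors' impacts instead.

## No-trade counterfactual

The scenario assumes each region meets its total food final demand
`y_i^s = Σ_r Y_{(r,i),s}` from domestic production, holding the
intermediate-input structure fixed (only final-demand sourcing is
domesticised — the scenario operates on final consumption). Where a region
does not produce a food sector (output exactly zero by default; a relative
output-share threshold is configurable because real tables contain
numerical dust), the output-weighted global average coefficient of that
sector is imputed.

Two modes ship:

- `coefficient` (default): prices `y_i^s` at the region's current
  transgressed coefficients, `T_notrade^s = Σ_i EFᵗʳ_{(s,i)}·y_i^s`. This
  is the simplest reading of scenario accounting with fixed coefficients,
  but ignores that self-sufficiency changes footprints and hence
  transgression.
- `recompute`: builds the counterfactual footprint from untransgressed
  coefficients and re-evaluates the boundary,
  `T_notrade^s = max(Σ_i EF_{(s,i)}·y_i^s − NB^s, 0)`. Internally
  consistent, and invariant to how current trade partitions demand across
  origins. Each mode imputes global averages of its own coefficient kind.

Alleviation is `δ = T_notrade − T` against *production-based* actual
transgression: this makes a region whose transgression supports exports
show aggravation, and makes the global saving `Σ_r δ` equal the difference
of global transgression totals between the scenario and reality. On a world
that is already autarkic, coefficient-mode δ is identically zero (the
"autarky null", asserted in the acceptance suite).

## Synthetic worlds

The generator (`generate_world(WorldSpec)`) emulates the structure of a
food-focused MRIO with extensions at desk scale. Defaults describe the
study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_regions` × `n_sectors` | 6 × 8 | world size (the structure, not the scale, of a ~190×160 database) |
| `food_sector_ids` | (0, 1, 2) | flagged food sectors |
| `trade_openness` | 0.25 | share of final demand sourced abroad, split over partners by Dirichlet weights |
| `intensity_dispersion` | 1.0 | log-SD of lognormal impact intensities (heavy-tailed heterogeneity) |
| `boundary_tightness` | 0.7 | global boundary ÷ global direct food impact; < 1 forces at least one transgressor per indicator |
| `population_range` | 1e6–1e8 | uniform integer draws, used only for per-capita reporting |

Technical coefficients are sparse gamma draws rescaled to column sums in
(0.2, 0.65) — capped well below 1 so `(I − A)` stays well conditioned.
Gross output solves the balance identity, so generated worlds are balanced
to machine precision. Proxies are lognormal with correlation ≈ 0.5 to
regional food output, which makes boundaries plausible while leaving both
safe and transgressing regions in play.

One structural choice matters: **food sectors sell only to final demand**
(their rows of `A` are zero; non-food sectors supply intermediates to
everything, across borders). Food products are modelled as final consumer
goods whose supply chains draw on non-food inputs. Under this structure
every unit of food-sector impact reaches final food demand, so the
food-masked consumption account conserves the production-based total
exactly and the autarky null holds to solver precision. With food used as
an intermediate (re-enabled via `food_intermediate_share > 0`), part of the
transgressed impact is embodied in non-food final products and escapes the
food mask; the conservation then weakens to an inequality, which the writer
layer reports as a warning rather than an error.

What the generator does **not** emulate: gravity-style trade structure,
calibration to real trade statistics or FAO magnitudes, sectoral
heterogeneity in trade openness, and year-to-year dynamics. Passing tests
therefore demonstrate the correctness of the accounting arithmetic and its
invariances, not agreement with any observed economy; runs on real MRIO
data enter through the same world-directory layout via an external adapter.

`autarky_variant` re-sources all final demand domestically, conserving each
(consumer, sector) total exactly, re-balances gross output, and rescales
impacts at fixed intensities to the new output (so impact-without-output
states cannot arise).

The fixed `duo_fixture` (2 regions × 2 sectors, water only) is the
hand-checkable anchor: all of its pipeline outputs are exact rational
numbers, and the test suite derives them independently with
`fractions.Fraction`.

## Numerical choices and degenerate inputs

- Leontief solve residual bound 1e-9 (max norm); synthetic-world balance
  asserted at 1e-9 relative; real-data balance checked at 1e-6 and
  *warned*, since published tables carry rounding imbalances.
- 0/0 conventions: intensity 0 where output 0; τ = 0 where footprint 0;
  per-capita 0 where both value and population are 0. Impact with zero
  output, and nonzero value with zero population, are hard errors.
- Zero-proxy regions get a zero boundary (the literal ratio), not a floor;
  per-region overrides in `boundaries.yaml` can replace downscaled values.
- CSV writers print shortest round-trip decimals and readers parse with
  round-trip precision, so world directories serialise losslessly.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; equal seeds give bit-identical worlds.

## Problem sizes

Tests and the acceptance script run on worlds of up to 6 regions × 8
sectors — large enough to exercise cross-border intermediates, imputation
and every conservation identity, while the whole suite completes in
seconds. The identities they assert (exact partition, conservation,
monotonicity, the autarky null) are scale-free, so nothing about them is
specific to these sizes.

## Known limitations

- Sector-average intensities: a region's τ applies uniformly to all its
  food sectors; crop-level attribution is out of scope.
- The counterfactual holds the intermediate structure fixed; no price or
  substitution response, and no partial-liberalisation scenarios.
- Monetary units of the MRIO are treated as opaque; only physical
  extensions carry units.
- Boundaries themselves are taken as given constants; the uncertainty zone
  around each boundary is not modelled.
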