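# bflows

National planetary-boundary footprint accounting for food systems.

Food production is the dominant user of freshwater, cropland and nutrient
(N, P) application worldwide, and in many countries it already exceeds the
share of the global safe operating space that the country's own resource
endowment can support. `bflows` quantifies this at the national scale and
traces it through trade: who transgresses their boundary to grow food, whose
consumption drives that transgression, and whether the global food trade
system relieves or worsens the pressure. It is a library for industrial
ecologists and sustainability researchers working with multi-regional
input-output (MRIO) data, usable from Python or, for batch runs on world
directories, through a thin `bflows` command line.

## The accounting

Four indicators are carried throughout, each with one internal unit:
blue water use (km³/yr), cropland use (km²), nitrogen application (t/yr)
and phosphorus application (t/yr).

**National boundaries.** Each global food-system boundary `PB_e` is
allocated to countries by a proxy ratio,

    NB_e^r = PB_e · proxy_r / Σ_r' proxy_r'

with long-run renewable water availability as the proxy for water, N and P,
and national farmland area for land. The national boundaries partition the
global boundary exactly.

**Footprints.** With technical coefficients `A`, direct impact intensities
`D` (impact per unit gross output) and bilateral final demand `y_i^{r,s}`,
embodied footprint coefficients are

    EF = D (I − A)⁻¹

Production-based footprints sum direct food-sector impacts per producing
region; consumption-based footprints sum `EF · y` over food final demand per
consuming region.

**Transgression and its virtual flows.** A region's transgression is
`T = max(F_prod − NB, 0)` and its transgression fraction `τ = T / F_prod`.
Scaling each region's intensities by its τ and embodying through the
Leontief inverse gives transgressed coefficients `EFᵗʳ`, and

    flow_{r,s} = Σ_{i∈food} EFᵗʳ_{(r,i)} · y_i^{r,s}

is the virtual flow of unsustainable impact from producer `r` to consumer
`s`. Flow totals reproduce transgression totals; `top_links` ranks the
largest bilateral transfers.

**No-trade counterfactual.** Assuming every region meets its total food
demand `y_i^s = Σ_r y_i^{r,s}` domestically (global-average coefficients
imputed where a food is not produced locally), the package computes the
counterfactual transgression, per-region alleviation (+) or aggravation (−)
`δ = T_notrade − T`, and the global savings from trade `Σ_r δ`.

## Worked example

The package ships a fixed two-region fixture (`duo_fixture`) small enough to
check by hand; `examples/duo_walkthrough.py` runs it end to end:

```python
from bflows import duo_fixture, run_analysis

world = duo_fixture()
res = run_analysis(world.mrio, world.extensions, world.proxies,
                   world.planetary_boundaries)
```

prints (abridged):

```
Production vs consumption water footprints (km3/yr):
  production : {'R1': 300.0, 'R2': 100.0}
  consumption: {'R1': 250.0, 'R2': 150.0}
Transgression:
  T  : {'R1': 200.0, 'R2': 0.0}
  tau: {'R1': 0.6667, 'R2': 0.0}
Bilateral virtual flows of transgressed water (km3/yr):
    water     R1          R1  160.0
    water     R1          R2   40.0
```

R1's farms use 300 km³ against a 100 km³ boundary, so two thirds of every
unit of its water use is unsustainable; R2's food imports make it
responsible for 40 of R1's 200 km³ transgression. In the no-trade
counterfactual R1 only covers its own 90 units of food demand, so trade
*aggravates* its transgression by 20 km³ (`examples/no_trade_counterfactual.py`).

Other examples: `synthetic_pipeline.py` (a random six-region world with
ranked transgression flows) and `world_directory_io.py` (the plain-text
world-directory layout shared by synthetic worlds, real-data adapters and
the CLI).

## Synthetic worlds

Real MRIO databases are large downloads; `bflows.generate_world(WorldSpec(...))`
draws desk-scale economies with the structure the method assumes — a
productive coefficient matrix, controlled trade openness, heavy-tailed
food-sector impact intensities, proxies correlated with food output, and
boundaries tight enough that transgression is guaranteed. Equal seeds give
bit-identical worlds. See `docs/methods.md` for what the generator does and
does not emulate.

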