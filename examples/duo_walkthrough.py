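"""Walk through the full accounting chain on the two-region toy world.

R1 and R2 each run a food sector (selling to final consumers at home and
abroad) and an "other" sector supplying it.  R1's farms use 300 km3 of
water against a 100 km3 national boundary; R2 uses 100 km3 against 150.
Every number below is reproducible by hand.
"""

from bflows import duo_fixture, run_analysis, top_links

world = duo_fixture()
res = run_analysis(
    world.mrio, world.extensions, world.proxies, world.planetary_boundaries
)

print("National water boundaries (km3/yr), downscaled from a 250 km3 global")
print("boundary by water availability (100 vs 150):")
print(res.boundaries.NB.loc[["water"]].to_string(), "\n")

print("Production vs consumption water footprints (km3/yr):")
print("  production :", res.footprints.F_prod.loc["water"].to_dict())
print("  consumption:", res.footprints.F_cons.loc["water"].to_dict())
print("R1 produces 300 but its consumers only require 250; 50 km3 of its")
print("water use serves R2's food demand.\n")

print("Transgression (production footprint above the boundary):")
print("  T  :", res.transgression.T.loc["water"].to_dict())
print("  tau:", res.transgression.tau.loc["water"].round(4).to_dict())
print("R1 exceeds its boundary by 200 km3; two thirds of every unit of its")
print("water use is unsustainable.  R2 stays within its boundary.\n")

print("Bilateral virtual flows of transgressed water (km3/yr):")
print(top_links(res.flows, 20).to_string(index=False))
print("R2's food imports make it responsible for 40 of R1's 200 km3")
print("transgression; consumption-based transgression is therefore")
print(f"{res.transgression.T_cons.loc['water'].to_dict()} "
      f"(per capita: {res.per_capita_T_cons.loc['water'].to_dict()}).")
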