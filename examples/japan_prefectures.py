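"""Word ages on the gravity-built network of 46 Japanese prefectures.

Uses the bundled prefecture table (offices' coordinates, 2018 populations,
Kyoto as the inventing centre, Okinawa excluded) with half-decay distance
gamma = 10 km.  In the population-dependent mode, transmission is weighted
by the product of prefecture populations, so the populous Tokyo area acts as
a conservative barrier: words diffuse westward faster than eastward, and the
Tokyo area and northern Tohoku both end up with mean word ages between 550
and 600 steps.  The population-independent mode restores near east/west
symmetry.
"""

import wordage as w

table = w.japan_prefectures()
kyoto = tuple(table.nodes.set_index("label").loc["Kyoto", ["lat", "lon"]])

for mode in ("population_dependent", "population_independent"):
    net = w.build_geo_network(table, w.GravityConfig(gamma=10.0, mode=mode))
    ages = dict(zip(net.labels, w.equilibrium_mean(net)))
    print(f"\n{mode}, gamma = 10 km")
    for label in ("Osaka", "Hiroshima", "Fukuoka", "Shizuoka", "Tokyo",
                  "Aomori", "Hokkaido"):
        row = table.nodes.set_index("label").loc[label]
        d = w.great_circle_distance(kyoto, (row["lat"], row["lon"]))
        print(f"  {label:<10} {d:7.0f} km from Kyoto   mean word age {ages[label]:7.1f}")
    youngest = min(ages, key=ages.get)
    oldest = max(ages, key=ages.get)
    print(f"  youngest: {youngest} ({ages[youngest]:.0f}); "
          f"oldest: {oldest} ({ages[oldest]:.0f})")

print("\nwith population weighting, western prefectures are younger than")
print("eastern ones at the same distance - heavy Tokyo-area populations")
print("absorb their own learners and slow the arrival of new words.")
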