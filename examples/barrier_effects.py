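"""What a transmission barrier does to word age and diversity.

A bidirectional chain of nine populations (a = 0.1) is cut between P5 and P6
by a barrier crossed at a reduced rate b.  The run prints the equilibrium
mean, SD and heterozygosity with and without the barrier: means beyond the
barrier grow, means before it are exactly unchanged, while the SD rises on
BOTH sides and heterozygosity splits — down near the centre, up beyond.
"""

import numpy as np

import wordage as w

n, a, h = 9, 0.1, 5
plain = w.build_bidirectional_chain(n, a)

print(f"{'k':>2} " + " ".join(f"{f'b={b}':>24}" for b in (a, 0.05, 0.01)))
rows = {}
for b in (a, 0.05, 0.01):
    net = plain if b == a else w.build_chain_with_barrier(n, a, b=b, h=h)
    r = w.equilibrium_mean(net)
    s = w.equilibrium_sd(net)
    H = w.heterozygosity(w.equilibrium_age_distribution(net, rho_max=10000))
    rows[b] = (r, s, H)

for k in range(n):
    cells = " ".join(
        f"{rows[b][0][k]:>8.1f} {rows[b][1][k]:>7.1f} {rows[b][2][k]:>7.4f}"
        for b in (a, 0.05, 0.01)
    )
    marker = " <-- barrier" if k + 1 == h else ""
    print(f"{k + 1:>2} {cells}{marker}")

print("\ncolumns per b: mean age, SD, heterozygosity.  Means for k <= 5 are")
print("identical across b (influx of old words and insulation cancel); the")
print("SD grows on both sides because rare, very old variants linger near")
print("the centre once a barrier exists.")
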