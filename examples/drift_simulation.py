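"""Finite-population drift versus the deterministic large-population limit.

Runs the agent-based simulator on a three-population unidirectional chain
(a = 0.1) with 10 000 agents per population for 3000 steps, five replicates,
and compares the time-averaged mean word ages (after a 500-step burn-in)
with the deterministic equilibrium (10, 20, 30).  Standard errors are across
replicates.  With populations this large, drift is small and the simulation
sits within a fraction of a percent of the exact values.
"""

import numpy as np

import wordage as w

net = w.build_unidirectional_chain(3, 0.1)
cfg = w.AbmConfig(sizes=[10_000] * 3, horizon=3000, replicates=5, seed=0)
run = w.run_abm(net, cfg)
summary = w.abm_summaries(run, burn_in=500)
exact = w.equilibrium_mean(net)

print("node   simulated mean (SE)    exact   heterozygosity (SE)")
for k, row in summary.iterrows():
    print(f"{row['node']:<5} {row['mean_age']:>9.3f} ({row['mean_age_se']:.3f})"
          f"  {exact[k]:>7.1f}   {row['heterozygosity']:.4f} "
          f"({row['heterozygosity_se']:.5f})")

dev = np.abs(summary["mean_age"].to_numpy() - exact)
print(f"\nmax deviation from the deterministic limit: {dev.max():.3f} steps "
      f"({100 * (dev / exact).max():.2f}%)")
print("shrinking the populations would inflate drift; growing them recovers")
print("the deterministic model exactly.")
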