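"""Signaling-gradient formation in the 2D embryo geometry.

Runs a reduced-scale default condition (basolateral receptors and
secretion), prints the bound-receptor fraction per distance from the
epiblast edge, and the gradient half-depth. High occupancy at d_edge = 1-2
falling to near zero beyond ~6 cell widths is the edge-organized gradient;
d_half is where occupancy drops below half of the edge value.
"""

from morphograd import (SimulationConfig, run, occupancy_profile,
                        gradient_depth)

config = SimulationConfig(n_ligands=200, duration=1800.0,
                          snapshot_interval=450.0, n_replicates=3, seed=7)
result = run(config)

profile = occupancy_profile(result, at_time=1800.0)
print("bound-receptor fraction by d_edge (cell widths) at t = 30 min:")
for d, frac in sorted(profile.by_d_edge.items()):
    bar = "#" * int(round(frac * 40))
    print(f"  d_edge {d:2d}: {frac:6.3f} +- {profile.sem[d]:.3f}  {bar}")

depth = gradient_depth(profile)
print(f"\ngradient half-depth d_1/2 = {depth.d_half:.2f} cell widths"
      f"{' (saturated)' if depth.saturated else ''}")
print("ligands bind receptors near the open ExE-epiblast channel far more"
      " often than deep in the tissue: the gradient forms from the edge.")
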