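"""Proficiency: how well a coordinate predicts a cell's readout.

Builds a synthetic segmented-colony table whose marker is driven by
distance from the colony edge (d_edge), then computes the uncertainty
coefficient U(marker | X) = I(X; marker) / H(marker) for d_edge, d_source
and the joint pair, with a bootstrap confidence interval. The edge-driven
construction makes U(marker | d_edge) the largest.
"""

from morphograd import (BinningScheme, bootstrap_proficiency, paper_schemes,
                        synthetic_colony_table)

table = synthetic_colony_table(n_cells=2000, edge_effect_depth=5.0,
                               noise_sd=0.05, seed=21)
schemes = paper_schemes()
schemes["marker"] = BinningScheme("marker", method="percentile", n_bins=2)

for predictor in ("d_source", "d_edge", ["d_source", "d_edge"]):
    res = bootstrap_proficiency(table, predictor, "marker", schemes,
                                n_boot=1000, seed=0)
    name = "+".join(predictor) if isinstance(predictor, list) else predictor
    print(f"U(marker | {name:16s}) = {100 * res.point:5.1f}%  "
          f"[{100 * res.ci_low:.1f}, {100 * res.ci_high:.1f}]%")
print("d_edge carries most of the predictable information about the marker.")
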