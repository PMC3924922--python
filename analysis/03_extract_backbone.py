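#!/usr/bin/env python
"""Extract the information backbone and compare it with a global cutoff.

Sweeps the disparity-filter significance level, picks the α whose
retained-edge fraction is closest to 8%, filters under the AND rule,
matches a global weight cutoff to the same edge fraction, and writes
both backbones plus the statistical comparison under results/backbone/.
A sweep plot goes to scratch/ when matplotlib is available.
"""

import json
from pathlib import Path

from phenonet.backbone import (compare_filters, default_grid, extract_backbone,
                               global_weight_filter, match_edge_fraction,
                               pick_alpha, sweep)
from phenonet.netbuild import read_net, write_net

ROOT = Path(__file__).resolve().parent.parent
TARGET = 0.08


def main() -> None:
    net = read_net(ROOT / "results" / "network" / "unfiltered.tsv")
    out = ROOT / "results" / "backbone"
    out.mkdir(parents=True, exist_ok=True)

    table = sweep(net, default_grid(101), "AND")
    table.to_csv(out / "sweep.tsv", sep="\t", index=False)
    alpha = pick_alpha(table, TARGET)
    dfn = extract_backbone(net, alpha, "AND")
    frac = dfn.number_of_edges() / net.number_of_edges()
    cutoff, achieved = match_edge_fraction(net, frac if frac > 0 else 1.0)
    gwn = global_weight_filter(net, cutoff)
    write_net(dfn, out / "backbone_df.tsv", "tsv")
    write_net(gwn, out / "backbone_gw.tsv", "tsv")
    comp = compare_filters(net, dfn, gwn)
    (out / "comparison.json").write_text(json.dumps(comp, indent=2,
                                                    sort_keys=True) + "\n")

    print(f"alpha = {alpha:g} retains {100 * frac:.1f}% of edges, "
          f"{comp['disparity']['pct_nodes']:.1f}% of vertices, "
          f"{comp['disparity']['pct_weight']:.1f}% of weight")
    print(f"global cutoff {cutoff:g} at the same edge budget retains "
          f"{comp['global_weight']['pct_nodes']:.1f}% of vertices")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    for col in ("frac_vertices", "frac_weight", "avg_cc"):
        ax.plot(table["frac_edges"], table[col], label=col)
    ax.set_xlabel("fraction of edges retained")
    ax.legend()
    fig.tight_layout()
    fig.savefig(scratch / "sweep.png", dpi=120)
    print(f"sweep plot: {scratch / 'sweep.png'}")


if __name__ == "__main__":
    main()
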