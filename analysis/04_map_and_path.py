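#!/usr/bin/env python
"""Directional correlation map and downstream-correlated path recovery.

What this finds: on a synthetic protein with a planted directed chain of
phi-dihedral couplings (residue 1 -> 2 -> ... -> 5), the residue-residue
TDCF map built with the block-shuffle significance threshold marks the
planted edges as significant with the correct direction, and the greedy
closest-downstream-residue walk recovers the full chain.  On the same map
the peak amplitudes cluster at small distance variance (the planted pairs
are spatially quiet) and track the equal-time correlation strength.

Writes results/map_edges.tsv, results/map_matrix.tsv, results/path.tsv,
results/amplitude_vs_variance.tsv and results/peak_vs_pearson.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from tdca import pathmap, synthdata
from tdca.experiments import (CHAIN_DOFS, CHAIN_DT_NS, CHAIN_LENGTH_NS,
                              CHAIN_MAX_LAG_NS, CHAIN_RELAX_NS, CHAIN_STRENGTH)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-res", type=int, default=5)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    residues = list(range(1, args.n_res + 1))
    edges = synthdata.chain_edges(residues, dof="phi", strength=CHAIN_STRENGTH)
    # two extra uncoupled residues with large positional jitter: spatially
    # noisy dihedrals should not enter the significant map
    n_total = args.n_res + 2
    sys_ = synthdata.make_system(n_total, edges, seed=args.seed,
                                 dofs=CHAIN_DOFS, relax_ns=CHAIN_RELAX_NS,
                                 jitter_nm=0.08, quiet_coupled_jitter_nm=0.01)
    ds = synthdata.generate(sys_, CHAIN_LENGTH_NS, CHAIN_DT_NS, seed=args.seed)
    cmap = pathmap.build_map(
        ds.series, config=pathmap.MapConfig(max_lag=CHAIN_MAX_LAG_NS,
                                            seed=args.seed))
    pathmap.write_edge_table(cmap, OUT / "map_edges.tsv")
    pathmap.write_matrix(cmap, OUT / "map_matrix.tsv")
    et = cmap.edge_table()
    sig = et[et["significant"]]
    print(f"{len(sig)} of {len(et)} cells significant at the "
          f"{cmap.config.sig_level:.0%} shuffle-null level:")
    print(sig[["i", "j", "dof_i", "dof_j", "upstream", "downstream",
               "f_fwd", "f_rev", "tau_fwd_ns", "pearson"]].to_string(index=False))

    dist = {k[:2]: v for k, v in ds.all_distance_stats().items()
            if k[2] == "alpha-alpha"}
    path = pathmap.build_path(cmap, dist, start=residues[0])
    path.steps.to_csv(OUT / "path.tsv", sep="\t", index=False,
                      float_format="%.6g")
    planted = "recovered exactly" if path.residues == residues else "NOT recovered"
    print(f"\ndownstream-correlated path from residue 1: "
          f"{' -> '.join(map(str, path.residues))}  ({planted})")

    av = pathmap.amplitude_vs_variance(cmap, ds.all_distance_stats())
    av.to_csv(OUT / "amplitude_vs_variance.tsv", sep="\t", index=False,
              float_format="%.6g")
    pp, stats = pathmap.peak_vs_pearson(cmap)
    pp.to_csv(OUT / "peak_vs_pearson.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(f"\npeak strength vs |C(0)| rank correlation over significant "
          f"cells: {stats['rho_fmax_pearson']:+.2f}")
    if not av.empty:
        print("amplitude vs distance variance (significant cells):")
        print(av.to_string(index=False))


if __name__ == "__main__":
    main()
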