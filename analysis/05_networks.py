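"""Relationship networks: mutual k-nearest-neighbour graphs (k=10) from the
genotype IBS distance matrix and from the pedigree kinship matrix, with their
connected components summarised by cohort status.
"""

import argparse
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from carriergwas import genio, relatedness
from carriergwas.pedigree import additive_relationship, build_pedigree


def edge_frame(g: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(
        [{"ID1": a, "ID2": b, "distance": d["distance"]} for a, b, d in g.edges(data=True)]
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("-k", type=int, default=10)
    args = ap.parse_args()
    base = Path(args.out)
    data = base / "data"

    gm = genio.read_ped_map(data / "genotypes.ped", data / "genotypes.map")
    gm, _ = genio.qc_filter(gm, mind=0.2, geno=0.25, maf=0.02)
    status = dict(
        zip(*pd.read_csv(base / "status.tsv", sep="\t", dtype=str)[["id", "status"]].T.values)
    )

    dist = relatedness.ibs_distance_matrix(gm)
    g = relatedness.mknn_graph(dist, k=args.k)
    edge_frame(g).to_csv(base / "network_edges.tsv", sep="\t", index=False, float_format="%.5f")

    ped = build_pedigree(pd.read_csv(data / "pedigree.csv"))
    kin = additive_relationship(ped, gm.samples) / 2.0
    kd = 1.0 - kin
    np.fill_diagonal(kd.values, 0.0)
    gk = relatedness.mknn_graph(kd, k=args.k)
    edge_frame(gk).to_csv(
        base / "network_edges_pedigree.tsv", sep="\t", index=False, float_format="%.5f"
    )

    for name, graph in (("genotype IBS", g), ("pedigree kinship", gk)):
        comps = sorted(nx.connected_components(graph), key=len, reverse=True)
        print(f"{name} network: {graph.number_of_edges()} edges, "
              f"{len(comps)} components (sizes {[len(c) for c in comps[:6]]}...)")
        main_comp = comps[0]
        in_main = sum(1 for s in main_comp if status.get(s) == "case")
        total_cases = sum(1 for s in graph.nodes if status.get(s) == "case")
        print(f"  cases in the main component: {in_main}/{total_cases}")


if __name__ == "__main__":
    main()
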