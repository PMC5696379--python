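"""DE-overlaid protein-interaction subnetwork.

Maps DE genes from a two-type bulk comparison to (synthetic) human
orthologs, takes the induced subgraph of a (synthetic) curated edge list,
classifies nodes as signal transduction / transcription factor, and
exports node/edge/SIF files to results/network/.
"""

import argparse

from mamlin import pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/network")
    args = ap.parse_args()

    out = pipeline.run_network_workflow(outdir=args.out, seed=args.seed)
    net, view = out["network"], out["st_tf"]
    print(f"DE subnetwork: {net.graph.number_of_nodes()} nodes, "
          f"{net.graph.number_of_edges()} edges")
    print(f"ST/TF view: {view.graph.number_of_nodes()} nodes, "
          f"{view.graph.number_of_edges()} edges")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
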