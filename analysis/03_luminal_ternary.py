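"""Ternary lineage analysis of the luminal series.

Derives basal/LP/ML signatures from synthetic bulk, scores each cell's
ternary lineage composition, classifies cells, and computes the
luminal-intermediate monotone-trend and elevated-gene statistics.
Tables land in results/luminal/.
"""

import argparse

from mamlin import pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/luminal")
    args = ap.parse_args()

    out = pipeline.run_luminal_workflow(outdir=args.out, seed=args.seed)
    sigs = out["signatures"]
    print("derived signature sizes:",
          {n: len(sigs.genes(n)) for n in sigs.names()})

    tern = out["ternary"]
    core = tern[tern.true_label.isin(["basal", "LP", "ML"])]
    acc = (core.label == core.true_label).mean()
    print(f"ternary classification accuracy on basal/LP/ML cells: {acc:.3f}")

    mono = out["monotone"]
    print(f"{mono.n_monotone} of {mono.n_de_genes} DE genes "
          f"({100 * mono.fraction_monotone:.1f}%) change monotonically "
          "from LP through Lum Int to ML")
    print(f"{len(out['elevated'].genes)} DE genes are >=20% higher in Lum Int "
          "than both LP and ML")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
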