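"""Generate the four synthetic study datasets with planted truth.

Writes 10X-style MTX directories plus truth tables under results/data/:
bulk basal/LP/ML replicates, three single-cell populations, the luminal
series with a Lum Int population, and the sorted-basal compartment with a
5% mixed-lineage subset.
"""

import argparse

import pandas as pd

from mamlin import synthetic
from mamlin.iofmt import write_counts, write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    designs = {
        "bulk_three_type": (synthetic.simulate_bulk,
                            synthetic.bulk_three_type_design(seed=args.seed)),
        "cells_three_population": (synthetic.simulate_cells,
                                   synthetic.cells_three_population_design(seed=args.seed)),
        "cells_luminal": (synthetic.simulate_cells,
                          synthetic.cells_luminal_design(seed=args.seed)),
        "cells_basal_compartment": (synthetic.simulate_cells,
                                    synthetic.cells_basal_compartment_design(seed=args.seed)),
    }
    for name, (fn, design) in designs.items():
        cm, truth = fn(design)
        outdir = f"{args.out}/{name}"
        write_counts(cm, outdir)
        write_table(pd.DataFrame({
            "sample_id": list(truth.cell_labels),
            "population": list(truth.cell_labels.values()),
            "is_mixed": [s in set(truth.mixed_cells) for s in truth.cell_labels],
        }), f"{outdir}/truth_labels.tsv")
        print(f"{name}: {cm.n_genes} genes x {cm.n_samples} samples -> {outdir}")


if __name__ == "__main__":
    main()
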