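#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes paired mRNA/protein abundance matrices (32 cell lines x 3000 genes),
the ten hallmark gene sets, the growth table (nominal division rates and a
101-drug inhibition panel) and the generator's ground truth under
``results/cohort/``.  All later steps start from these files.
"""

import argparse
from pathlib import Path

from hallmarktasks.cohort import CohortParams, generate_cohort
from hallmarktasks.io import write_abundance, write_gmt, write_growth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = CohortParams(seed=args.seed)
    mrna, protein, sets, growth, truth = generate_cohort(params)
    write_abundance(mrna, args.outdir / "mrna.tsv")
    write_abundance(protein, args.outdir / "protein.tsv")
    write_gmt(sets, args.outdir / "hallmarks.gmt")
    write_growth(growth, args.outdir / "growth.tsv")
    truth.to_json(args.outdir / "truth.json")

    sizes = sets.sizes()
    print(f"cohort: {params.n_genes} genes x {params.n_cells} cells, seed {args.seed}")
    print(f"hallmark sets: {len(sizes)} (sizes {min(sizes.values())}-{max(sizes.values())})")
    print(f"translation-selective hallmarks: {', '.join(truth.withheld_sets)}")
    print(f"division rates: {growth.division_rate.min():.2f}-{growth.division_rate.max():.2f}")
    print(f"outputs in {args.outdir}")


if __name__ == "__main__":
    main()
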