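#!/usr/bin/env python
"""Relate the decoupling statistics to division rate and drug response.

Correlates the delta and range statistics with nominal division rates and
per-(cell, drug) growth inhibition, fits the hallmark-fixed-factor OLS for
the common slope of division rate on delta (plus per-hallmark models), and
compares the range ECDFs between modalities.
"""

import argparse
from pathlib import Path

import pandas as pd

from hallmarktasks.association import (
    division_associations,
    ecdf_compare,
    effects_to_frame,
    fixed_effect_model,
    inhibition_associations,
    per_hallmark_effects,
    records_to_frame,
)
from hallmarktasks.io import read_growth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--taskstats", type=Path, default=Path("results/taskstats"))
    parser.add_argument("--growth", type=Path, default=Path("results/cohort/growth.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results/associations"))
    parser.add_argument("--plots", action="store_true")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    delta = pd.read_csv(args.taskstats / "delta.tsv", sep="\t")
    range_df = pd.read_csv(args.taskstats / "range.tsv", sep="\t")
    growth = read_growth(args.growth)

    records = division_associations(delta, range_df, growth)
    records += inhibition_associations(delta, range_df, growth)
    records_to_frame(records).to_csv(args.outdir / "associations.tsv", sep="\t",
                                     index=False, float_format="%.6g")

    effects = [fixed_effect_model(delta, growth)] + per_hallmark_effects(delta, growth)
    effects_to_frame(effects).to_csv(args.outdir / "effects.tsv", sep="\t",
                                     index=False, float_format="%.6g")

    fe = effects[0]
    print(f"fixed effect of delta on division rate: {fe.estimate:+.3f} "
          f"(SE {fe.std_error:.3f}, p = {fe.p_value:.3g}, "
          f"95% CI [{fe.ci_low:.2f}, {fe.ci_high:.2f}])")
    signs = [e.estimate < 0 for e in effects[1:]]
    print(f"per-hallmark slopes negative: {sum(signs)}/{len(signs)}")
    pooled = next(r for r in records if r.hallmark is None and r.response == "division_rate")
    print(f"pooled delta-division PCC = {pooled.pcc:+.3f} (p = {pooled.p_value:.3g})")
    inh = next(r for r in records
               if r.hallmark is None and r.response == "growth_inhibition")
    print(f"pooled delta-inhibition PCC = {inh.pcc:+.3f} (p = {inh.p_value:.3g}; "
          "descriptive: inhibition values repeat across hallmarks)")
    rng_m = range_df.loc[range_df["modality"] == "mrna", "range"]
    rng_p = range_df.loc[range_df["modality"] == "protein", "range"]
    ks = ecdf_compare(rng_p, rng_m)
    print(f"range ECDF protein vs mrna: D = {ks.statistic:.3f} "
          f"(scaled {ks.scaled_statistic:.2f}, p = {ks.p_value:.3g})")
    if args.plots:
        from hallmarktasks.association import plot_delta_division
        plot_delta_division(delta, growth, args.outdir / "delta_division.png")
    print(f"outputs in {args.outdir}")


if __name__ == "__main__":
    main()
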