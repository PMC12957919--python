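#!/usr/bin/env python
"""Recover glial elevations around plaques from a synthetic glia cohort.

The transgenic generator raises in-plaque microglial soma density 4-fold
(with smaller gains out to 20 µm, echoing the 5-month pattern around
plaques).  This driver measures cell density, coverage and intensity in
concentric annuli on the maximum projections, normalizes to the wild-type
mean across distances, and reports the recovered in-plaque fold.
"""

from pathlib import Path

from periplaque.glia import region_order
from periplaque.studies import glia_fold_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = glia_fold_study(seed=101)
    table = res["table"]
    table.to_csv(RESULTS / "glia_metric_table.csv", index=False)

    order = region_order("microglia_10um")
    for metric in ("cell_density", "coverage", "intensity"):
        sub = table[table.metric == metric]
        piv = sub.pivot_table(index="bin_label", columns="genotype",
                              values="normalized_pct")
        piv = piv.loc[sorted(piv.index, key=order.get)]
        print(f"\n{metric} (% of WT mean across distances):")
        print(piv.round(1).to_string())

    print(f"\nin-plaque cell density, transgenic: "
          f"{res['in_plaque_density_norm']:.0f}% (generator imposed 400%)")


if __name__ == "__main__":
    main()
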