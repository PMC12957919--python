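#!/usr/bin/env python
"""Recover the plaque-proximal synapse deficit from one synthetic cohort.

Runs the full measurement chain — plaque detection, crop placement along a
random ray, 3D puncta detection, pre/post co-localization counting,
WT-mean normalization — on one cohort (n = 6 per genotype, 2 slices ×
3 images each) with a generator-imposed 50% deficit confined to the
(0–10] µm bin, then applies the genotype × distance factorial test.
"""

from pathlib import Path

from periplaque.studies import synapse_deficit_cohort_result

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = synapse_deficit_cohort_result(cohort_seed=101)

    table = res["table"]
    table.to_csv(RESULTS / "synapse_density_table.csv", index=False)
    res["result"].posthoc.to_csv(RESULTS / "synapse_posthoc.csv", index=False)

    print("normalized synapse density (% of WT mean), transgenic group:")
    print(res["tg_norm_by_bin"].round(1).to_string())
    print(f"\ndeficit bin (0-10]: {res['deficit_bin_norm']:.1f}% "
          f"(generator imposed 50%)")
    print(f"unaffected bins:    {res['other_bins_norm']:.1f}%")
    r = res["result"]
    print(f"\n{r.test_name}: interaction F = {r.statistic:.2f}, "
          f"df = {tuple(round(d, 2) for d in r.df)}, p = {r.p_value:.2g}")
    print("\nper-bin genotype comparisons (family-adjusted):")
    print(r.posthoc.round(4).to_string(index=False))
    print(f"\npost-hoc difference confined to (0-10]: {res['confined']}")


if __name__ == "__main__":
    main()
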