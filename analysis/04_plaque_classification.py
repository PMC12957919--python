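#!/usr/bin/env python
"""Classify synthetic plaques as diffuse vs non-diffuse from Thio-S cores.

Generates 50 transgenic fields whose plaque is diffuse with probability
0.6, segments each plaque from its 6E10-like channel, classifies it by
thresholded Thio-S overlap, and compares the recovered diffuse fraction
with the generating one.
"""

from pathlib import Path

import pandas as pd

from periplaque.studies import plaque_class_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = plaque_class_study(seed=101, n_images=50, p_diffuse=0.6)
    pd.DataFrame([res]).drop(columns=[]).to_csv(
        RESULTS / "plaque_classification.csv", index=False
    )
    print(f"fields with a detected plaque: {res['n_images']}/50")
    print(f"generated diffuse fraction:  {res['true_diffuse_frac']:.2f}")
    print(f"recovered diffuse fraction:  {res['recovered_diffuse_frac']:.2f} "
          f"(binomial s.e. {res['binomial_se']:.3f})")
    print(f"per-plaque classification accuracy: {res['accuracy']:.2f}")


if __name__ == "__main__":
    main()
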