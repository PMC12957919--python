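"""Comparative-Ct (2^−ΔΔCt) fold changes with multi-gene housekeeping normalization.

Input is a long-format table of raw Ct values (gene × sample × replicate).
Technical replicates are collapsed by arithmetic mean; each sample's ΔCt is
the target Ct minus the mean Ct of the three reference genes (Gapdh, Gusb,
Pgk1 by default — arithmetically averaging reference Cts equals geometric-
mean normalization of expression, since Ct is log2 expression); ΔΔCt
subtracts the control-group mean ΔCt, and fold change is 2^−ΔΔCt with an
amplification efficiency of 2 (an efficiency-corrected base is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_GENES = ("Gapdh", "Gusb", "Pgk1")

CT_COLUMNS = ["gene", "sample", "group", "replicate", "ct"]


def collapse_replicates(ct: pd.DataFrame, sd_flag: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (gene, sample) with replicate SD; SD > ``sd_flag`` cycles flagged.

    Flagged wells stay in the data — flags are for auditing, not exclusion.
    """
    g = ct.groupby(["gene", "sample", "group"], sort=False)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n_replicates="count").reset_index()
    out["ct_sd"] = out.ct_sd.fillna(0.0)
    out["high_sd_flag"] = out.ct_sd > sd_flag
    return out


def fold_change(
    ct: pd.DataFrame,
    control_group: str = "WT",
    reference_genes: tuple[str, ...] = REFERENCE_GENES,
    efficiency_base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample ΔCt, ΔΔCt versus the control-group mean, and fold change.

    Samples missing any reference gene are excluded (with a reason column in
    the attached ``excluded`` attribute) because their normalizer is
    undefined.  By construction the control group's geometric-mean fold is 1
    for every gene.
    """
    if control_group not in set(ct.group):
        raise ValueError(f"control group {control_group!r} not present")
    means = collapse_replicates(ct)
    refs = means[means.gene.isin(reference_genes)]
    ref_counts = refs.groupby("sample")["gene"].nunique()
    complete = set(ref_counts[ref_counts == len(reference_genes)].index)
    excluded = sorted(set(means["sample"]) - complete)
    means = means[means["sample"].isin(complete)]
    ref_ct = (
        means[means.gene.isin(reference_genes)]
        .groupby("sample")["ct_mean"]
        .mean()
        .rename("ref_ct")
    )
    targets = means[~means.gene.isin(reference_genes)].merge(ref_ct, on="sample")
    targets["delta_ct"] = targets.ct_mean - targets.ref_ct
    ctrl = (
        targets[targets.group == control_group]
        .groupby("gene")["delta_ct"]
        .mean()
        .rename("ctrl_delta_ct")
    )
    targets = targets.merge(ctrl, on="gene")
    targets["delta_delta_ct"] = targets.delta_ct - targets.ctrl_delta_ct
    targets["fold"] = efficiency_base ** (-targets.delta_delta_ct)
    out = targets[
        ["gene", "sample", "group", "delta_ct", "delta_delta_ct", "fold"]
    ].reset_index(drop=True)
    out.attrs["excluded_samples"] = excluded
    return out


def group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean fold ± SEM per gene per group (matching per-animal dot plots)."""
    g = folds.groupby(["gene", "group"], sort=False)["fold"]
    out = g.agg(mean_fold="mean", n="count")
    out["sem"] = g.sem()
    return out.reset_index()


def simulate_ct_table(
    fold_by_gene: dict[str, float],
    n_per_group: int = 6,
    n_replicates: int = 3,
    replicate_sd: float = 0.15,
    sample_sd: float = 0.25,
    control_group: str = "WT",
    test_group: str = "NLGF",
    reference_genes: tuple[str, ...] = REFERENCE_GENES,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table with known injected fold changes per target gene.

    Each sample draws a global offset (RNA input / efficiency shift,
    ``sample_sd`` cycles) applied to every gene — the comparative-Ct method
    must cancel it.  The test group's target Cts are shifted by
    −log2(fold); replicate wells add ``replicate_sd`` cycles of noise.
    """
    rng = np.random.default_rng(seed)
    base_ct = {"Gapdh": 18.0, "Gusb": 24.0, "Pgk1": 20.0}
    for i, gene in enumerate(fold_by_gene):
        base_ct.setdefault(gene, 23.0 + (i % 5))
    rows = []
    for group in (control_group, test_group):
        for s in range(n_per_group):
            sample = f"{group}{s + 1}"
            offset = rng.normal(0, sample_sd)
            for gene, base in base_ct.items():
                ct0 = base + offset
                if group == test_group and gene in fold_by_gene:
                    ct0 -= np.log2(fold_by_gene[gene])
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "gene": gene,
                            "sample": sample,
                            "group": group,
                            "replicate": rep + 1,
                            "ct": ct0 + rng.normal(0, replicate_sd),
                        }
                    )
    return pd.DataFrame(rows, columns=CT_COLUMNS)
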