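"""Normality-gated two-group tests and genotype × distance factorial inference.

Two-group comparisons follow the published convention: Shapiro–Wilk on each
group at α = 0.05 decides between an unpaired two-tailed t-test and a
Mann-Whitney U test, and the gate decision is recorded alongside the result.

For genotype × distance designs (one between-subject factor, one repeated
within-subject factor — the F1-LD-F1 layout) two branches are always
computed and reported:

* parametric — repeated-measures (mixed) two-way ANOVA with per-bin
  genotype comparisons adjusted across the bin family (Holm), the
  multiple-comparisons style of the original analyses;
* rank-based — the ANOVA-type statistic (ATS) on global mid-ranks with
  relative treatment effects and a Box-type degrees-of-freedom
  approximation, followed by Dunn's rank comparisons per bin (Bonferroni
  within the procedure).

A Shapiro–Wilk gate on cell-centered residuals marks which branch is
primary; both are kept for auditability.  Ranks are invariant under any
strictly monotone transform of the response, so the rank branch is too.
The unit of analysis is the animal: slices and images must be averaged
before these tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One inferential result with its audit trail."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    gate: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "gate": self.gate,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def two_group_test(x, y, alpha_gate: float = 0.05) -> StatResult:
    """Shapiro-gated unpaired comparison of two independent groups.

    Both groups normal at ``alpha_gate`` → unpaired two-tailed t-test;
    otherwise a two-tailed Mann-Whitney U.  Groups need ≥ 3 values for the
    gate; with exactly 2 the nonparametric branch is used and the gate is
    recorded as unavailable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    gate: dict = {}
    if len(x) >= 3 and len(y) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        px = float(sps.shapiro(x).pvalue)
        py = float(sps.shapiro(y).pvalue)
        parametric = px > alpha_gate and py > alpha_gate
        gate = {"shapiro_p": (px, py), "parametric": parametric}
    else:
        parametric = False
        gate = {"shapiro_p": None, "parametric": False}
    if parametric:
        res = sps.ttest_ind(x, y)
        return StatResult(
            "t_unpaired", float(res.statistic), (float(len(x) + len(y) - 2),),
            float(res.pvalue), gate,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult("mann_whitney_u", float(res.statistic), (), float(res.pvalue), gate)


# ---------------------------------------------------------------------------
# rank-based ANOVA-type statistic for the F1-LD-F1 design


def _pivot_design(
    table: pd.DataFrame, value_col: str, bin_order: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(subjects × bins) response matrix, group index per subject, dropped animals."""
    wide = table.pivot_table(
        index=["genotype", "animal"], columns="bin_label", values=value_col
    )
    cols = [b for b in bin_order if b in wide.columns]
    wide = wide[cols]
    dropped = [a for (g, a) in wide.index[wide.isna().any(axis=1)]]
    wide = wide.dropna()
    groups = np.array([g for (g, a) in wide.index])
    return wide.to_numpy(float), groups, dropped


def relative_effects(data: np.ndarray, group_idx: np.ndarray) -> np.ndarray:
    """Relative treatment effects p̂_ik per (group, bin) cell from global mid-ranks.

    p̂_ik estimates P(random observation < cell distribution) + ½P(=); the
    mean over all cells weighted by group sizes is ½ by construction.
    """
    n, t = data.shape
    ranks = sps.rankdata(data.ravel()).reshape(n, t)
    levels = np.unique(group_idx)
    p = np.empty((len(levels), t))
    for gi, g in enumerate(levels):
        p[gi] = (ranks[group_idx == g].mean(axis=0) - 0.5) / (n * t)
    return p


def _ats(
    M: np.ndarray, p_hat: np.ndarray, V: np.ndarray, n: int,
    group_sizes: np.ndarray, blocks: list[slice],
) -> tuple[float, float, float]:
    """ANOVA-type statistic, numerator df, and Box-approximation denominator df."""
    trMV = float(np.trace(M @ V))
    if trMV <= 0:
        return 0.0, 1.0, np.inf
    stat = n * float(p_hat @ M @ p_hat) / trMV
    MV = M @ V
    f_num = trMV**2 / float(np.trace(MV @ MV))
    denom = 0.0
    for gi, blk in enumerate(blocks):
        lam = float(np.trace(M[blk, blk] @ V[blk, blk]))
        denom += lam**2 / (group_sizes[gi] - 1)
    f_den = trMV**2 / denom if denom > 0 else np.inf
    return stat, f_num, f_den


def rank_factorial_test(
    table: pd.DataFrame, bin_order: list[str], value_col: str = "normalized_pct"
) -> dict:
    """Rank-based F1-LD-F1 analysis: group, time (distance) and interaction ATS."""
    data, groups, dropped = _pivot_design(table, value_col, bin_order)
    levels = list(np.unique(groups))
    a, t = len(levels), data.shape[1]
    n = data.shape[0]
    if a < 2 or t < 2 or n < a + 1:
        raise ValueError("need ≥2 groups, ≥2 bins and enough subjects")
    group_sizes = np.array([np.sum(groups == g) for g in levels])
    ranks = sps.rankdata(data.ravel()).reshape(n, t) / (n * t)
    p_hat = np.empty(a * t)
    V = np.zeros((a * t, a * t))
    blocks = []
    for gi, g in enumerate(levels):
        Y = ranks[groups == g]  # n_i × t
        blk = slice(gi * t, (gi + 1) * t)
        blocks.append(blk)
        p_hat[blk] = Y.mean(axis=0)
        ni = len(Y)
        S = np.cov(Y, rowvar=False, ddof=1) if ni > 1 else np.zeros((t, t))
        V[blk, blk] = (n / ni) * np.atleast_2d(S)
    Pa = np.eye(a) - np.ones((a, a)) / a
    Pt = np.eye(t) - np.ones((t, t)) / t
    Jt = np.ones((t, t)) / t
    Ja = np.ones((a, a)) / a
    effects = {}
    for name, M in (
        ("group", np.kron(Pa, Jt)),
        ("distance", np.kron(Ja, Pt)),
        ("interaction", np.kron(Pa, Pt)),
    ):
        stat, f1, f0 = _ats(M, p_hat, V, n, group_sizes, blocks)
        if name == "group":
            p = float(sps.f.sf(stat, f1, f0))
            df = (f1, f0)
        else:  # within-subject effects: F(f̂, ∞) reference
            p = float(sps.chi2.sf(stat * f1, f1))
            df = (f1, np.inf)
        effects[name] = {"statistic": stat, "df": df, "p": p}
    return {
        "effects": effects,
        "relative_effects": pd.DataFrame(
            p_hat.reshape(a, t), index=levels, columns=bin_order[:t]
        ),
        "dropped_animals": dropped,
        "group_levels": levels,
    }


def dunn_posthoc(
    table: pd.DataFrame, bin_order: list[str], value_col: str = "normalized_pct"
) -> pd.DataFrame:
    """Dunn's rank comparison of the two genotypes within each bin.

    Within each bin, all animals are ranked jointly (mid-ranks, tie
    correction); the z statistic compares mean ranks, with Bonferroni
    adjustment across the bin family — the multiplicity handling internal to
    the procedure, with no further correction on top.
    """
    rows = []
    bins = [b for b in bin_order if b in set(table.bin_label)]
    for b in bins:
        sub = table[table.bin_label == b]
        groups = sorted(sub.genotype.unique())
        if len(groups) != 2:
            continue
        vals = sub[value_col].to_numpy(float)
        ranks = sps.rankdata(vals)
        N = len(vals)
        g0 = sub.genotype.to_numpy() == groups[0]
        n1, n2 = int(g0.sum()), int((~g0).sum())
        _, counts = np.unique(vals, return_counts=True)
        tie_corr = (counts**3 - counts).sum() / (12 * (N - 1)) if N > 1 else 0.0
        var = (N * (N + 1) / 12 - tie_corr) * (1 / n1 + 1 / n2)
        z = (ranks[g0].mean() - ranks[~g0].mean()) / np.sqrt(var) if var > 0 else 0.0
        p = 2 * float(sps.norm.sf(abs(z)))
        rows.append(
            {"bin_label": b, "comparison": f"{groups[0]} vs {groups[1]}",
             "z": float(z), "p_unadj": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.minimum(out.p_unadj * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# parametric branch


def parametric_factorial_test(
    table: pd.DataFrame, bin_order: list[str], value_col: str = "normalized_pct"
) -> dict:
    """Repeated-measures two-way (mixed) ANOVA with Holm-adjusted per-bin comparisons."""
    import pingouin as pg

    data, groups, dropped = _pivot_design(table, value_col, bin_order)
    keep = table[["animal", "genotype", "bin_label", value_col]].copy()
    keep = keep[~keep.animal.isin(dropped)]
    aov = pg.mixed_anova(
        data=keep, dv=value_col, within="bin_label", subject="animal",
        between="genotype", correction=False,
    )
    inter = aov[aov.Source == "Interaction"].iloc[0]
    effects = {}
    for src, name in (
        ("genotype", "group"), ("bin_label", "distance"), ("Interaction", "interaction")
    ):
        row = aov[aov.Source == src].iloc[0]
        effects[name] = {
            "statistic": float(row.F),
            "df": (float(row.DF1), float(row.DF2)),
            "p": float(row["p_unc"]),
        }
    bins = [b for b in bin_order if b in set(keep.bin_label)]
    rows = []
    for b in bins:
        sub = keep[keep.bin_label == b]
        gs = sorted(sub.genotype.unique())
        x = sub[sub.genotype == gs[0]][value_col].to_numpy(float)
        y = sub[sub.genotype == gs[1]][value_col].to_numpy(float)
        res = sps.ttest_ind(x, y)
        rows.append(
            {"bin_label": b, "comparison": f"{gs[0]} vs {gs[1]}",
             "t": float(res.statistic), "p_unadj": float(res.pvalue)}
        )
    post = pd.DataFrame(rows)
    if len(post):  # Holm step-down across the bin family
        order = np.argsort(post.p_unadj.to_numpy())
        m = len(post)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * post.p_unadj.iloc[idx])
            adj[idx] = min(running, 1.0)
        post["p_adj"] = adj
    return {
        "effects": effects,
        "posthoc": post,
        "dropped_animals": dropped,
        "interaction_p": float(inter["p_unc"]),
    }


def factorial_distance_test(
    table: pd.DataFrame,
    bin_order: list[str],
    value_col: str = "normalized_pct",
    alpha_gate: float = 0.05,
) -> StatResult:
    """Genotype × distance inference with both branches and a residual-normality gate.

    The returned :class:`StatResult` carries the primary branch's interaction
    test; ``extra`` holds both full branches.  Animals with missing bins are
    dropped (listed in the gate trail).
    """
    data, groups, dropped = _pivot_design(table, value_col, bin_order)
    # residuals about each genotype × bin cell mean
    resid = []
    for g in np.unique(groups):
        sub = data[groups == g]
        resid.append(sub - sub.mean(axis=0))
    resid = np.concatenate([r.ravel() for r in resid])
    if len(resid) >= 3 and np.ptp(resid) > 0:
        shapiro_p = float(sps.shapiro(resid).pvalue)
    else:
        shapiro_p = np.nan
    parametric = bool(shapiro_p > alpha_gate) if np.isfinite(shapiro_p) else False

    rank_res = rank_factorial_test(table, bin_order, value_col)
    rank_post = dunn_posthoc(table, bin_order, value_col)
    para_res = parametric_factorial_test(table, bin_order, value_col)

    gate = {
        "residual_shapiro_p": shapiro_p,
        "parametric": parametric,
        "dropped_animals": dropped,
    }
    if parametric:
        eff = para_res["effects"]["interaction"]
        name, post = "rm_two_way_anova", para_res["posthoc"]
    else:
        eff = rank_res["effects"]["interaction"]
        name, post = "rank_ats_f1_ld_f1", rank_post
    return StatResult(
        test_name=name,
        statistic=eff["statistic"],
        df=tuple(eff["df"]),
        p_value=eff["p"],
        gate=gate,
        posthoc=post,
        extra={"parametric": para_res, "rank": rank_res, "rank_posthoc": rank_post},
    )
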