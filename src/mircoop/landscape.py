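"""Group-wise genomic and expression comparisons across tumor subgroups.

Per-feature one-way ANOVA across the a/b/c/PTEN-positive groups, two-group
Welch t-tests, per-sample copy-number burden (total gains = codes +1/+2,
total losses = codes -1/-2), mutation-presence comparisons (Fisher exact for
two groups, chi-square for more), and top-k differential feature selection.
Feature-wise p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix
from .diffexp import bh_adjust

__all__ = [
    "GroupComparisonResult",
    "CnaBurden",
    "anova_by_group",
    "t_by_mask",
    "cna_burden",
    "mutation_compare",
    "top_k_by_anova",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-feature statistics for a group comparison.

    ``table`` is indexed by feature id and holds per-group means, the test
    statistic (F or t), p and BH q. ``kind`` is "anova" or "t"."""

    table: pd.DataFrame
    kind: str
    group_levels: tuple[str, ...]


def anova_by_group(m: ExpressionMatrix, groups: pd.Series) -> GroupComparisonResult:
    """One-way fixed-effects ANOVA per feature across group labels.

    Levels with fewer than 2 samples are dropped with a warning. Missing
    entries are excluded per feature. A feature constant everywhere gets
    F = 0, p = 1.
    """
    if list(groups.index) != m.sample_ids:
        raise ValueError("groups must be indexed by the matrix sample ids, in order")
    counts = groups.value_counts()
    levels = sorted(counts.index[counts >= 2])
    dropped = sorted(set(counts.index) - set(levels))
    if dropped:
        warnings.warn(f"group level(s) {dropped} have < 2 samples; dropped", stacklevel=2)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels with >= 2 samples")

    X = m.values.to_numpy(dtype=float)
    fin = np.isfinite(X)
    Xz = np.where(fin, X, 0.0)
    level_masks = [(groups == lev).to_numpy() for lev in levels]
    n_l = np.stack([(fin[:, msk]).sum(axis=1) for msk in level_masks], axis=1).astype(float)
    sum_l = np.stack([Xz[:, msk].sum(axis=1) for msk in level_masks], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_l = sum_l / n_l
    n_tot = n_l.sum(axis=1)
    grand = sum_l.sum(axis=1) / n_tot
    ss_between = (n_l * (mean_l - grand[:, None]) ** 2).sum(axis=1)
    sq_l = np.stack([(Xz[:, msk] ** 2).sum(axis=1) for msk in level_masks], axis=1)
    ss_within = (sq_l - n_l * mean_l**2).sum(axis=1)
    ss_within = np.maximum(ss_within, 0.0)  # guard tiny negative round-off
    df_b = len(levels) - 1
    df_w = n_tot - len(levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ss_between / df_b
        msw = ss_within / df_w
        F = msb / msw
    p = stats.f.sf(F, df_b, df_w)
    # degenerate: no within- or between-group variation at all
    const = (ss_within <= 0) & (ss_between <= 1e-12)
    F = np.where(const, 0.0, F)
    p = np.where(const, 1.0, p)
    q = bh_adjust(np.nan_to_num(p, nan=1.0))
    table = pd.DataFrame(
        {f"mean_{lev}": mean_l[:, i] for i, lev in enumerate(levels)}
        | {"F": F, "p": p, "q": q},
        index=pd.Index(m.feature_ids, name="feature"),
    )
    return GroupComparisonResult(table=table, kind="anova", group_levels=tuple(levels))


def t_by_mask(
    m: ExpressionMatrix, mask, equal_var: bool = False
) -> GroupComparisonResult:
    """Two-group t-test per feature (Welch by default; pooled optional).

    ``mask`` = 1 marks group 1; t > 0 means higher in group 1. A feature
    with zero variance in both groups and equal means gets t = 0, p = 1.
    """
    g = np.asarray(mask)
    if not np.isin(g, [0, 1]).all():
        raise ValueError("mask must be binary (0/1)")
    g = g.astype(bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    X1 = np.where(g[None, :], X, np.nan)
    X0 = np.where(~g[None, :], X, np.nan)
    with np.errstate(invalid="ignore"):
        n1 = np.isfinite(X1).sum(axis=1).astype(float)
        n0 = np.isfinite(X0).sum(axis=1).astype(float)
        m1, m0 = np.nanmean(X1, axis=1), np.nanmean(X0, axis=1)
        v1, v0 = np.nanvar(X1, axis=1, ddof=1), np.nanvar(X0, axis=1, ddof=1)
    diff = m1 - m0
    if equal_var:
        df = n1 + n0 - 2.0
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    else:
        se2 = v1 / n1 + v0 / n0
        with np.errstate(invalid="ignore", divide="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0
    t = np.where(degenerate & (np.abs(diff) <= 1e-12), 0.0, t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1.0)), np.nan)
    p = np.where(t == 0.0, 1.0, p)
    q = bh_adjust(np.nan_to_num(p, nan=1.0))
    table = pd.DataFrame(
        {"mean_1": m1, "mean_0": m0, "t": t, "df": df, "p": p, "q": q},
        index=pd.Index(m.feature_ids, name="feature"),
    )
    return GroupComparisonResult(table=table, kind="t", group_levels=("1", "0"))


@dataclass(frozen=True)
class CnaBurden:
    """Per-sample totals of gained (codes +1/+2) and lost (codes -1/-2) genes."""

    table: pd.DataFrame  # index sample_id, columns gain/loss


def cna_burden(cna: pd.DataFrame) -> CnaBurden:
    arr = cna.to_numpy()
    bad = ~np.isin(arr, [-2, -1, 0, 1, 2])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"CNA code {arr[i, j]!r} out of range at gene {cna.index[i]!r}, "
            f"sample {cna.columns[j]!r}"
        )
    gain = (arr >= 1).sum(axis=0)
    loss = (arr <= -1).sum(axis=0)
    return CnaBurden(
        table=pd.DataFrame(
            {"gain": gain, "loss": loss}, index=pd.Index(cna.columns, name="sample_id")
        )
    )


def mutation_compare(mut: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene mutated counts per group with Fisher (2 groups) or chi-square p.

    Genes mutated nowhere are excluded (mirroring "at least one mutated
    gene" reporting). Returns counts, group sizes, p and BH q per gene.
    """
    if list(groups.index) != list(mut.columns):
        raise ValueError("groups must be indexed by the mutation-matrix samples, in order")
    arr = mut.to_numpy()
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("mutation matrix must be binary")
    keep = arr.sum(axis=1) > 0
    mut = mut.loc[keep]
    levels = sorted(groups.unique())
    sizes = {lev: int((groups == lev).sum()) for lev in levels}
    rows = []
    for gene, row in mut.iterrows():
        counts = {lev: int(row[(groups == lev).to_numpy()].sum()) for lev in levels}
        table = np.array(
            [[counts[lev] for lev in levels], [sizes[lev] - counts[lev] for lev in levels]]
        )
        if len(levels) == 2:
            _, p = stats.fisher_exact(table, alternative="two-sided")
            test = "fisher_exact"
        else:
            if table.sum(axis=0).min() == 0 or (table.sum(axis=1) == 0).any():
                p, test = np.nan, "chi2_contingency"
            else:
                p = stats.chi2_contingency(table)[1]
                test = "chi2_contingency"
        rows.append({"gene": gene, **{f"n_mut_{lev}": counts[lev] for lev in levels}, "p": p, "test": test})
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["p", "test"], index=pd.Index([], name="gene")
    )
    if len(out):
        out["q"] = bh_adjust(np.nan_to_num(out["p"].to_numpy(dtype=float), nan=1.0))
    return out


def top_k_by_anova(
    result: GroupComparisonResult, k: int = 20, alpha: float = 0.05
) -> list[str]:
    """Features with p < alpha, sorted ascending by p (ties by id), first k."""
    tab = result.table
    passing = tab[tab["p"] < alpha]
    order = sorted(passing.index, key=lambda f: (passing.at[f, "p"], f))
    return order[:k]
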