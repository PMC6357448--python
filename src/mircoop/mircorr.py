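"""Anchor-gene vs miRNA correlation ranking across random subgroups.

The discovery procedure: the cohort is split into b independent random
bipartitions; together with the full cohort this yields 2b + 1 groups (the
default b = 3 gives 7 groups per cohort class, 14 across a breast-cancer and
a triple-negative class). Within each group every miRNA is Pearson-correlated
with the anchor gene (pairwise-complete observations), ranked in a positive
or negative direction, and the per-group ranks are averaged; the candidates
with the smallest average rank are the anchor-cooperating miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "SubgroupScheme",
    "RankingTable",
    "make_subgroup_scheme",
    "correlate_anchor",
    "average_ranking",
    "top_candidates",
]


@dataclass(frozen=True)
class SubgroupScheme:
    """Ordered (label, sample-id tuple) groups: full cohort + bipartition halves."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]
    n_bipartitions: int
    seed: int

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    def __len__(self) -> int:
        return len(self.groups)


def make_subgroup_scheme(
    sample_ids: Sequence[str], n_bipartitions: int = 3, seed: int = 0
) -> SubgroupScheme:
    """Full cohort plus ``n_bipartitions`` independent random half-splits.

    Each bipartition's halves are disjoint, cover the cohort, and differ in
    size by at most 1. Deterministic given ``seed``.
    """
    ids = list(sample_ids)
    if len(ids) < 6:
        raise ValueError(f"need at least 6 samples to build subgroups, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    groups: list[tuple[str, tuple[str, ...]]] = [("all", tuple(ids))]
    half = len(ids) // 2
    for b in range(n_bipartitions):
        perm = rng.permutation(len(ids))
        a_idx, b_idx = np.sort(perm[:half]), np.sort(perm[half:])
        groups.append((f"split{b + 1}A", tuple(ids[i] for i in a_idx)))
        groups.append((f"split{b + 1}B", tuple(ids[i] for i in b_idx)))
    return SubgroupScheme(groups=tuple(groups), n_bipartitions=n_bipartitions, seed=seed)


def correlate_anchor(
    anchor_values: pd.Series,
    features: ExpressionMatrix,
    group: Sequence[str],
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of the anchor against every feature in one group.

    Missing entries are excluded pairwise. Returns a DataFrame indexed by
    feature id with columns ``r``, ``n_used`` and ``reason`` (empty when the
    record is valid). Features with fewer than ``min_n`` pairwise-complete
    observations or zero variance are flagged with r = NaN, never dropped.
    """
    ids = list(group)
    unknown = set(ids) - set(features.sample_ids)
    if unknown:
        raise KeyError(f"group contains samples absent from matrix: {sorted(unknown)[:5]}")
    a = anchor_values.loc[ids].to_numpy(dtype=float)
    X = features.values.loc[:, ids].to_numpy(dtype=float)
    valid = np.isfinite(X) & np.isfinite(a)[None, :]
    n_used = valid.sum(axis=1)

    Xm = np.where(valid, X, 0.0)
    Am = np.where(valid, a[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.maximum(n_used, 1)
        mx = Xm.sum(axis=1) / n
        ma = Am.sum(axis=1) / n
        sxx = (Xm**2).sum(axis=1) - n * mx**2
        saa = (Am**2).sum(axis=1) - n * ma**2
        sxa = (Xm * Am).sum(axis=1) - n * mx * ma
        r = sxa / np.sqrt(sxx * saa)
    r = np.clip(r, -1.0, 1.0)

    reason = np.full(X.shape[0], "", dtype=object)
    too_few = n_used < min_n
    reason[too_few] = f"fewer than {min_n} pairwise-complete observations"
    zero_var = ~too_few & ((sxx <= 0) | (saa <= 0))
    reason[zero_var & (saa <= 0)] = "zero-variance anchor in group"
    reason[zero_var & (sxx <= 0)] = "zero-variance feature in group"
    r[too_few | zero_var] = np.nan
    return pd.DataFrame(
        {"r": r, "n_used": n_used, "reason": reason},
        index=pd.Index(features.feature_ids, name="mirna_id"),
    )


@dataclass(frozen=True)
class RankingTable:
    """Per-group correlation ranks and their average, sorted by average rank.

    ``table`` is indexed by feature id, sorted ascending by ``avg_rank`` with
    ties broken by mean |r| (larger first) then lexicographic id; columns are
    ``r_<group>`` and ``rank_<group>`` per group plus ``avg_rank``, ``mean_r``
    and ``n_groups_used``.
    """

    table: pd.DataFrame
    direction: str
    group_labels: tuple[str, ...]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)


def average_ranking(
    per_group_records: Mapping[str, pd.DataFrame], direction: str = "positive"
) -> RankingTable:
    """Rank each group's correlations and average the ranks across groups.

    ``direction='positive'`` ranks descending r (rank 1 = most positive);
    ``'negative'`` ranks ascending r. Ties receive average ranks. Features
    whose r is missing in more than half the groups are excluded with a
    warning; otherwise missing groups are skipped in the average.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    labels = list(per_group_records)
    if not labels:
        raise ValueError("no groups supplied")
    feature_sets = [tuple(df.index) for df in per_group_records.values()]
    if len(set(feature_sets)) != 1:
        raise ValueError("all groups must cover the same feature set, in the same order")

    r_cols = pd.DataFrame(
        {lab: per_group_records[lab]["r"] for lab in labels}
    )
    ranks = r_cols.rank(ascending=(direction == "negative"), method="average")
    n_ok = r_cols.notna().sum(axis=1)
    excluded = n_ok < len(labels) / 2.0
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} feature(s) missing r in >50% of groups; excluded",
            stacklevel=2,
        )
    table = pd.DataFrame(index=r_cols.index)
    for lab in labels:
        table[f"r_{lab}"] = r_cols[lab]
        table[f"rank_{lab}"] = ranks[lab]
    table["avg_rank"] = ranks.mean(axis=1, skipna=True)
    table["mean_r"] = r_cols.mean(axis=1, skipna=True)
    table["n_groups_used"] = n_ok
    table = table.loc[~excluded]
    order = sorted(
        table.index,
        key=lambda f: (table.at[f, "avg_rank"], -abs(table.at[f, "mean_r"]), f),
    )
    return RankingTable(
        table=table.loc[order], direction=direction, group_labels=tuple(labels)
    )


def top_candidates(table: RankingTable, k: int) -> list[str]:
    """First k features by average rank (tie-breaks applied in the table sort)."""
    if k > len(table.table):
        raise ValueError(f"k={k} exceeds feature count {len(table.table)}")
    return list(table.table.index[:k])
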