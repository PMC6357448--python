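"""Binary low/high calls and the rule-based a/b/c tumor subgrouping.

PTEN-low is a fixed rule — twofold below the cohort median, i.e. a
median-centered log2 value <= -1 (boundary inclusive). miRNA low/high calls
use per-miRNA cutoffs (typically survival-optimized). Among PTEN-low
triple-negative samples, group "a" has at least k of the n panel miRNAs low
(default 4 of 5), group "c" has at least k high, and group "b" is the rest;
PTEN-high TNBC samples are labelled pten_positive and everything else
non_tnbc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LowCallSet",
    "GroupAssignment",
    "call_pten_low",
    "make_low_calls",
    "assign_groups",
    "composite_stratify",
]

PTEN_LOW_CUTOFF = -1.0  # log2 median-centered: twofold below median


@dataclass(frozen=True)
class LowCallSet:
    """Per-sample low/high calls with the cutoff and its provenance."""

    calls: pd.DataFrame  # samples x features, boolean: True = low
    cutoffs: pd.Series  # per-feature threshold (call low iff value <= cutoff)
    provenance: pd.Series  # per-feature: "fixed" or "optimized"


def call_pten_low(pten_values: pd.Series, tol: float = 1e-6) -> pd.Series:
    """Low iff median-centered log2 value <= -1 (twofold below median).

    The input must be centered over the cohort on which the median was
    taken: a median beyond ``tol`` is rejected rather than silently
    re-centered.
    """
    v = pten_values.astype(float)
    med = float(np.nanmedian(v.to_numpy()))
    if abs(med) > tol:
        raise ValueError(
            f"PTEN values not median-centered (median {med:.4g}); center over "
            "the full cohort before calling"
        )
    return v <= PTEN_LOW_CUTOFF


def make_low_calls(
    values: pd.DataFrame, cutoffs: pd.Series, provenance: str = "optimized"
) -> LowCallSet:
    """Threshold a samples x features value table at per-feature cutoffs."""
    missing = set(values.columns) - set(cutoffs.index)
    if missing:
        raise KeyError(f"no cutoff recorded for features {sorted(missing)[:5]}")
    calls = values.le(cutoffs[values.columns], axis=1)
    prov = pd.Series(provenance, index=values.columns)
    return LowCallSet(calls=calls, cutoffs=cutoffs[values.columns], provenance=prov)


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sample label in {a, b, c, pten_positive, non_tnbc} plus rule params."""

    labels: pd.Series
    k_of_n: int
    n_panel: int

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def assign_groups(
    pten_low: pd.Series,
    mir_low: pd.DataFrame,
    is_tnbc: pd.Series,
    k_of_n: int = 4,
) -> GroupAssignment:
    """Apply the a/b/c rule over PTEN-low TNBC samples.

    ``mir_low`` is a samples x panel boolean matrix (True = low). With the
    default 4-of-5 rule: >= 4 miRNAs low -> "a"; >= 4 high (<= 1 low) -> "c";
    otherwise "b". Labels a/b/c are only assigned within PTEN-low TNBC;
    ``k_of_n`` must exceed half the panel so "a" and "c" cannot overlap.
    """
    n_panel = mir_low.shape[1]
    if n_panel == 0:
        raise ValueError("empty miRNA panel")
    k = k_of_n
    if not n_panel / 2 < k <= n_panel:
        raise ValueError(f"k_of_n={k} must lie in (n/2, n] for a panel of {n_panel}")
    samples = list(pten_low.index)
    if list(mir_low.index) != samples or list(is_tnbc.index) != samples:
        raise ValueError("pten_low, mir_low and is_tnbc must share sample order")

    n_low = mir_low.sum(axis=1).astype(int)
    tnbc = is_tnbc.astype(bool)
    plow = pten_low.astype(bool)
    labels = pd.Series("non_tnbc", index=pd.Index(samples, name="sample_id"))
    labels[tnbc & ~plow] = "pten_positive"
    in_rule = tnbc & plow
    labels[in_rule & (n_low >= k)] = "a"
    labels[in_rule & (n_low <= n_panel - k)] = "c"
    labels[in_rule & (n_low < k) & (n_low > n_panel - k)] = "b"
    # impossible for k > n/2; internal assertion per the rule contract
    assert not ((n_low >= k) & (n_low <= n_panel - k)).any(), "a/c overlap"
    return GroupAssignment(labels=labels, k_of_n=k, n_panel=n_panel)


def composite_stratify(call1: pd.Series, call2: pd.Series) -> pd.Series:
    """Label samples 'both' where both binary calls hold, else 'other'.

    Used for PTEN-low x miR-low and PTEN-low x pathway-high survival splits.
    """
    if list(call1.index) != list(call2.index):
        raise ValueError("calls must share sample order")
    both = call1.astype(bool) & call2.astype(bool)
    return pd.Series(np.where(both, "both", "other"), index=call1.index)
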