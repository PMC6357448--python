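"""Survival machinery implemented from first principles.

Kaplan-Meier product-limit curves, the two-group log-rank (Mantel-Cox) test
with its observed/expected hazard-ratio estimate, and minimal-p biomarker
cutoff optimization. The hazard ratio is the O/E ratio from the log-rank
2x2 tables, hr = (O1/E1)/(O2/E2) — the estimator paired with the Mantel-Cox
test in standard survival software — not a regression coefficient.

Conventions: censored subjects at time t remain at risk for events at t;
the log-rank statistic uses the hypergeometric variance
V_j = d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1) at each distinct
event time, and p comes from the chi-square distribution with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "SurvivalComparison",
    "CutoffResult",
    "km_estimate",
    "logrank_compare",
    "optimize_cutoff",
    "plot_km",
]

DEFAULT_CUTOFF_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.901, 0.05), 10))


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and non-negative")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be binary (0/1)")
    return t, e.astype(int)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""

    times: np.ndarray  # ordered distinct event times
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )
        if self.greenwood_var is not None:
            df["greenwood_var"] = self.greenwood_var
        return df


def km_estimate(times, events, greenwood: bool = False) -> KMCurve:
    """Kaplan-Meier estimate. Censored-only data yields S identically 1."""
    t, e = _as_surv_arrays(times, events)
    ut = np.unique(t[e == 1])
    ts = np.sort(t)
    n_risk = t.size - np.searchsorted(ts, ut, side="left")
    te = np.sort(t[e == 1])
    d = np.searchsorted(te, ut, side="right") - np.searchsorted(te, ut, side="left")
    surv = np.cumprod(1.0 - d / n_risk)
    gv = None
    if greenwood:
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = d / (n_risk * (n_risk - d))
        gv = surv**2 * np.cumsum(np.where(np.isfinite(inc), inc, np.inf))
    return KMCurve(times=ut, n_risk=n_risk, n_event=d, survival=surv, greenwood_var=gv)


@dataclass(frozen=True)
class SurvivalComparison:
    """Log-rank statistic, p, and O/E hazard ratio for a two-group split."""

    chi2: float
    p: float
    hr: float  # group1 vs group2; NaN when undefined (see hr_reason)
    o1: float
    e1: float
    o2: float
    e2: float
    n1: int
    n2: int
    hr_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "p": self.p,
            "hr": self.hr,
            "o1": self.o1,
            "e1": self.e1,
            "o2": self.o2,
            "e2": self.e2,
            "n1": self.n1,
            "n2": self.n2,
            "hr_reason": self.hr_reason,
        }


def logrank_compare(labels, times, events) -> SurvivalComparison:
    """Two-group log-rank (Mantel-Cox) test with O/E hazard ratio.

    ``labels`` is binary per sample: 1 marks group 1. chi2 =
    (sum_j (d_1j - E_1j))^2 / sum_j V_j over distinct event times, and
    hr = (O1/E1)/(O2/E2). Swapping labels inverts hr and leaves chi2
    unchanged; chi2 is invariant to strictly monotone time transforms.
    """
    t, e = _as_surv_arrays(times, events)
    g = np.asarray(labels)
    if not np.isin(g, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    g = g.astype(bool)
    n1, n2 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    ut = np.unique(t[e == 1])
    ts = np.sort(t)
    t1s = np.sort(t[g])
    n_at = t.size - np.searchsorted(ts, ut, side="left")
    n1_at = t1s.size - np.searchsorted(t1s, ut, side="left")
    te = np.sort(t[e == 1])
    te1 = np.sort(t[(e == 1) & g])
    d = (np.searchsorted(te, ut, side="right") - np.searchsorted(te, ut, side="left")).astype(
        float
    )
    d1 = (
        np.searchsorted(te1, ut, side="right") - np.searchsorted(te1, ut, side="left")
    ).astype(float)

    frac1 = n1_at / n_at
    e1_j = d * frac1
    with np.errstate(divide="ignore", invalid="ignore"):
        v_j = np.where(
            n_at > 1, d * frac1 * (1.0 - frac1) * (n_at - d) / (n_at - 1.0), 0.0
        )
    o1 = float(d1.sum())
    e1 = float(e1_j.sum())
    o_total = float(d.sum())
    o2, e2 = o_total - o1, o_total - e1
    v = float(v_j.sum())
    if v > 0:
        chi2 = float((d1 - e1_j).sum() ** 2 / v)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = np.nan, np.nan

    hr, reason = np.nan, ""
    if e1 <= 0 or e2 <= 0:
        reason = "a group has zero expected events"
    elif o2 == 0:
        reason = "no observed events in group 2 (O/E ratio diverges)"
    else:
        hr = float((o1 / e1) / (o2 / e2))
    return SurvivalComparison(
        chi2=chi2, p=p, hr=hr, o1=o1, e1=e1, o2=o2, e2=e2, n1=n1, n2=n2, hr_reason=reason
    )


@dataclass(frozen=True)
class CutoffResult:
    """Best low/high threshold for a biomarker by minimal log-rank p.

    ``grid_evaluated`` lists every candidate (quantile level, threshold,
    group sizes, feasibility, chi2, p) so the multiplicity of the search is
    visible to callers; ``n_candidates`` counts the feasible ones.
    """

    label: str
    cutoff: float
    quantile: float
    comparison: SurvivalComparison
    n_low: int
    n_high: int
    grid_evaluated: pd.DataFrame
    n_candidates: int


def optimize_cutoff(
    values,
    times,
    events,
    grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    min_group_frac: float = 0.10,
    label: str = "",
) -> CutoffResult:
    """Scan quantile thresholds; return the split with the smallest log-rank p.

    Candidate thresholds are sample quantiles of ``values`` at the grid
    levels; a candidate is feasible only if both the low (value <= threshold)
    and high side hold at least ``min_group_frac`` of the samples. Ties on p
    go to the threshold nearest the sample median.
    """
    v = np.asarray(values, dtype=float)
    t, e = _as_surv_arrays(times, events)
    if v.shape != t.shape:
        raise ValueError("values and times must have equal length")
    grid = list(grid)
    if not all(0.0 < q < 1.0 for q in grid):
        raise ValueError("grid quantile levels must lie in (0, 1)")
    if not 0.0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in (0, 0.5)")

    n = v.size
    median = float(np.median(v))
    rows = []
    comparisons: dict[int, SurvivalComparison] = {}
    for i, q in enumerate(grid):
        thr = float(np.quantile(v, q))
        low = v <= thr
        n_low, n_high = int(low.sum()), int((~low).sum())
        feasible = min(n_low, n_high) >= min_group_frac * n
        chi2 = p = np.nan
        if feasible:
            cmp_ = logrank_compare(low.astype(int), t, e)
            comparisons[i] = cmp_
            chi2, p = cmp_.chi2, cmp_.p
        rows.append(
            {
                "quantile": q,
                "threshold": thr,
                "n_low": n_low,
                "n_high": n_high,
                "feasible": feasible,
                "chi2": chi2,
                "p": p,
            }
        )
    grid_df = pd.DataFrame(rows)
    ok = grid_df["feasible"] & grid_df["p"].notna()
    if not ok.any():
        raise ValueError(
            f"no feasible cutoff candidate for {label or 'biomarker'} under "
            f"min_group_frac={min_group_frac}"
        )
    pmin = grid_df.loc[ok, "p"].min()
    tied = grid_df.index[ok & np.isclose(grid_df["p"], pmin, rtol=1e-12, atol=0.0)]
    best = min(tied, key=lambda i: (abs(grid_df.at[i, "threshold"] - median), i))
    row = grid_df.loc[best]
    return CutoffResult(
        label=label,
        cutoff=float(row["threshold"]),
        quantile=float(row["quantile"]),
        comparison=comparisons[int(best)],
        n_low=int(row["n_low"]),
        n_high=int(row["n_high"]),
        grid_evaluated=grid_df,
        n_candidates=int(ok.sum()),
    )


def plot_km(curves: dict[str, KMCurve], path=None, title: str = ""):
    """Basic Kaplan-Meier step plot for one or more labelled groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, curve in curves.items():
        x = np.concatenate([[0.0], curve.times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=lab)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
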