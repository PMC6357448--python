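"""Gene-set pathway-activity scoring and pathway-high calls.

The score is a z-score/logistic surrogate for probability-of-activity
frameworks trained on external cohorts: each signature gene is z-scored
across samples, multiplied by its direction weight (+1/-1), averaged over
the genes present, and the raw score is squashed through a logistic with
scale equal to the cohort standard deviation of the raw score. The result is
monotone in aggregate signature expression — the property all downstream
group comparisons and high/low calls consume — and is clearly labelled as a
surrogate in outputs.

Signature files are GMT-style: name, description, then tab-separated gene
symbols, optionally prefixed with "+" or "-" for direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "PathwaySignature",
    "PathwayActivity",
    "read_gmt",
    "score_signature",
    "call_pathway_high",
]


@dataclass(frozen=True)
class PathwaySignature:
    """A named gene set with per-gene direction weights in {+1, -1}."""

    name: str
    genes: tuple[str, ...]
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if len(self.weights) != len(self.genes):
            raise ValueError(f"signature {self.name!r}: weights/genes length mismatch")
        if not set(self.weights) <= {-1, 1}:
            raise ValueError(f"signature {self.name!r}: weights must be +1/-1")

    @classmethod
    def from_genes(cls, name: str, genes, weights=None) -> "PathwaySignature":
        genes = tuple(genes)
        if weights is None:
            weights = tuple(1 for _ in genes)
        return cls(name=name, genes=genes, weights=tuple(int(w) for w in weights))

    def flipped(self) -> "PathwaySignature":
        return PathwaySignature(
            name=self.name, genes=self.genes, weights=tuple(-w for w in self.weights)
        )


def read_gmt(path: str | Path) -> list[PathwaySignature]:
    """Parse GMT lines: name <tab> description <tab> gene ["+"/"-" prefixed]..."""
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 3:
                if line.strip() == "":
                    continue
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, genes_raw = parts[0], parts[2:]
            genes, weights = [], []
            for tok in genes_raw:
                tok = tok.strip()
                if not tok:
                    continue
                if tok[0] in "+-":
                    weights.append(-1 if tok[0] == "-" else 1)
                    genes.append(tok[1:])
                else:
                    weights.append(1)
                    genes.append(tok)
            sigs.append(PathwaySignature(name=name, genes=tuple(genes), weights=tuple(weights)))
    return sigs


@dataclass(frozen=True)
class PathwayActivity:
    """Per-sample raw score and probability-like activity in [0, 1].

    activity = logistic(raw / scale); ``scale`` is the cohort standard
    deviation of the raw score, recorded so the mapping is reproducible.
    ``fraction_present`` reports how much of the signature the matrix covered.
    """

    name: str
    raw: pd.Series
    activity: pd.Series
    scale: float
    fraction_present: float
    method: str = "zscore-logistic surrogate"


def score_signature(m: ExpressionMatrix, sig: PathwaySignature) -> PathwayActivity:
    """Direction-weighted mean of z-scored expression, logistic-squashed.

    Genes absent from the matrix, or with zero variance across samples, are
    dropped (the covered fraction is reported); an entirely absent signature
    is an error naming it.
    """
    present = [(g, w) for g, w in zip(sig.genes, sig.weights) if g in m.values.index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} present in matrix")
    genes = [g for g, _ in present]
    w = np.array([wt for _, wt in present], dtype=float)
    X = m.values.loc[genes].to_numpy(dtype=float)
    mu = np.nanmean(X, axis=1)
    sd = np.nanstd(X, axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError(f"all genes of signature {sig.name!r} are constant")
    if not usable.all():
        warnings.warn(
            f"signature {sig.name!r}: {int((~usable).sum())} constant gene(s) dropped",
            stacklevel=2,
        )
    Z = (X[usable] - mu[usable, None]) / sd[usable, None]
    raw = np.nanmean(Z * w[usable, None], axis=0)
    scale = float(np.std(raw, ddof=1)) if raw.size > 1 else 0.0
    if scale == 0.0:
        warnings.warn(f"signature {sig.name!r}: constant raw score; scale set to 1", stacklevel=2)
        scale = 1.0
    activity = 1.0 / (1.0 + np.exp(-raw / scale))
    idx = pd.Index(m.sample_ids, name="sample_id")
    return PathwayActivity(
        name=sig.name,
        raw=pd.Series(raw, index=idx),
        activity=pd.Series(activity, index=idx),
        scale=scale,
        fraction_present=len(genes) / len(sig.genes),
    )


def call_pathway_high(activity: PathwayActivity, cutoff_quantile: float = 0.5) -> pd.Series:
    """High iff activity at or above the cohort quantile (ties to high).

    ``cutoff_quantile=1.0`` deliberately yields an empty high group (only
    values strictly above the maximum would qualify); downstream survival
    comparisons then refuse with their empty-group error.
    """
    act = activity.activity
    if not 0.0 <= cutoff_quantile <= 1.0:
        raise ValueError("cutoff_quantile must lie in [0, 1]")
    c = float(np.quantile(act.to_numpy(), cutoff_quantile))
    if cutoff_quantile >= 1.0:
        high = act > c
    else:
        high = act >= c
    if act.nunique() == 1:
        warnings.warn(
            f"signature {activity.name!r}: constant activity; all ties resolve to high",
            stacklevel=2,
        )
    return high
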