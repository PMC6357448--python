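"""Connectivity-map drug repurposing: query signatures, KS and weighted-
Spearman connectivity scores, permutation p-values, and hit intersection.

A query signature holds equal numbers of significantly up- and downregulated
genes from a differential-expression contrast. Each drug perturbation
signature ranks the common gene universe by its effect estimate; the GSEA-KS
connectivity score combines the signed Kolmogorov-Smirnov enrichment of the
up and down sets ((ES_up - ES_down)/2, zeroed when the two enrichments share
a sign), and the genome-wide connectivity (GWC) score is a significance-
weighted Pearson correlation of rank-transformed query and drug statistics.
Strongly negative scores mark drugs predicted to reverse the query state.

The KS enrichment uses the running empirical-CDF difference
D(i) = (#set genes at rank <= i)/t - i/n evaluated over the whole ranking:
ES is the signed maximum deviation (exact ties between the positive and
negative extremes give 0). This form is exactly antisymmetric under reversal
of the drug ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .diffexp import DEResult
from .syndata import DrugSignatureSet

__all__ = [
    "QuerySignature",
    "DrugSignature",
    "ConnectivityResult",
    "build_query_signature",
    "ks_enrichment_score",
    "ks_connectivity",
    "gwc_connectivity",
    "permutation_p",
    "score_drug_set",
    "rank_and_intersect",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class QuerySignature:
    """Equal-sized up/down gene sets with the statistics behind them."""

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    stats: pd.Series  # per signature gene, the moderated t (or analogue)
    pvals: pd.Series

    def __post_init__(self) -> None:
        if len(self.up_genes) != len(self.down_genes):
            raise ValueError("up and down sets must have equal size")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down sets must be disjoint")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes


@dataclass(frozen=True)
class DrugSignature:
    """One drug's per-gene effect estimates (and p-values, for GWC)."""

    drug_id: str
    effects: pd.Series
    pvals: pd.Series | None = None


@dataclass(frozen=True)
class ConnectivityResult:
    drug_id: str
    method: str  # "gsea_ks" or "gwc"
    score: float
    n_genes_common: int
    es_up: float | None = None
    es_down: float | None = None
    p: float | None = None


def build_query_signature(de: DEResult | pd.DataFrame, size: int, alpha: float = 0.05) -> QuerySignature:
    """Top size/2 significant genes by moderated t in each direction.

    Genes must pass FDR < ``alpha``; an error reports the available counts
    per direction when either side is short.
    """
    table = de.table if isinstance(de, DEResult) else de
    if size % 2 != 0 or size < 2:
        raise ValueError("signature size must be a positive even integer")
    half = size // 2
    sig = table[table["q"] < alpha]
    up_pool = sig[sig["t"] > 0].sort_values("t", ascending=False, kind="stable")
    down_pool = sig[sig["t"] < 0].sort_values("t", ascending=True, kind="stable")
    if len(up_pool) < half or len(down_pool) < half:
        raise ValueError(
            f"insufficient significant genes for size {size}: "
            f"{len(up_pool)} up / {len(down_pool)} down available, {half} needed per side"
        )
    up = tuple(up_pool.index[:half])
    down = tuple(down_pool.index[:half])
    genes = list(up) + list(down)
    return QuerySignature(
        up_genes=up,
        down_genes=down,
        stats=table.loc[genes, "t"].copy(),
        pvals=table.loc[genes, "p"].copy(),
    )


def ks_enrichment_score(positions: np.ndarray, n: int) -> float:
    """Signed max deviation of D(i) = (#set genes <= i)/t - i/n over i = 0..n.

    ``positions`` are the 1-based ascending ranks of the t set genes within
    the n-gene ranking. The positive extreme occurs at a set-gene position,
    the negative extreme just before one; an exact tie between the two
    extremes returns 0.
    """
    pos = np.asarray(positions, dtype=np.int64)
    t = pos.size
    if t == 0:
        raise ValueError("empty gene set")
    j = np.arange(1, t + 1, dtype=np.int64)
    # integer lattice (deviations scaled by n*t) so extreme ties compare exactly
    a = max(int(np.max(j * n - pos * t)), 0)
    b = max(int(np.max((pos - 1) * t - (j - 1) * n)), 0)
    if a > b:
        return a / (n * t)
    if b > a:
        return -b / (n * t)
    return 0.0


def _combine_es(es_up: float, es_down: float) -> float:
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def _drug_ranking(effects: pd.Series) -> pd.Series:
    """1-based rank of each gene, descending effect; ties broken by gene id."""
    eff = effects[np.isfinite(effects.to_numpy(dtype=float))]
    if eff.empty:
        raise ValueError("drug signature has no finite effects")
    order = np.lexsort((np.array(eff.index, dtype=object), -eff.to_numpy(dtype=float)))
    ranks = np.empty(len(eff), dtype=int)
    ranks[order] = np.arange(1, len(eff) + 1)
    return pd.Series(ranks, index=eff.index)


def ks_connectivity(q: QuerySignature, d: DrugSignature) -> ConnectivityResult:
    """GSEA-KS connectivity of a query signature against one drug ranking.

    Restricted to genes common to the query and the drug signature; requires
    at least one up and one down query gene (and two in total) in the common
    universe. Exactly antisymmetric under reversal of the drug ranking.
    """
    ranks = _drug_ranking(d.effects)
    n = len(ranks)
    up = [g for g in q.up_genes if g in ranks.index]
    down = [g for g in q.down_genes if g in ranks.index]
    if len(up) + len(down) < 2 or not up or not down:
        raise ValueError(
            f"query signature barely overlaps drug universe "
            f"({len(up)} up, {len(down)} down genes in common)"
        )
    es_up = ks_enrichment_score(np.sort(ranks[up].to_numpy()), n)
    es_down = ks_enrichment_score(np.sort(ranks[down].to_numpy()), n)
    return ConnectivityResult(
        drug_id=d.drug_id,
        method="gsea_ks",
        score=_combine_es(es_up, es_down),
        n_genes_common=len(up) + len(down),
        es_up=es_up,
        es_down=es_down,
    )


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def gwc_connectivity(q: QuerySignature, d: DrugSignature) -> ConnectivityResult:
    """Genome-wide connectivity: significance-weighted Spearman correlation.

    Over the common universe, each gene is weighted by the average of the
    query's and the drug's -log10 p; the score is the weighted Pearson
    correlation of the rank-transformed query and drug statistics.
    """
    if d.pvals is None:
        raise ValueError("GWC requires drug p-values")
    common = [g for g in q.stats.index if g in d.effects.index]
    if len(common) < 10:
        raise ValueError(f"common universe too small for GWC ({len(common)} genes)")
    qs = q.stats[common].to_numpy(dtype=float)
    ds = d.effects[common].to_numpy(dtype=float)
    qp = np.clip(q.pvals[common].to_numpy(dtype=float), _P_FLOOR, 1.0)
    dp = np.clip(d.pvals[common].to_numpy(dtype=float), _P_FLOOR, 1.0)
    w = 0.5 * (-np.log10(qp) - np.log10(dp))
    if not (w > 0).any():
        raise ValueError("degenerate GWC weights (all zero)")
    score = _weighted_pearson(sstats.rankdata(qs), sstats.rankdata(ds), w)
    return ConnectivityResult(
        drug_id=d.drug_id, method="gwc", score=score, n_genes_common=len(common)
    )


def permutation_p(
    score_fn: Callable[[QuerySignature, DrugSignature], ConnectivityResult],
    q: QuerySignature,
    d: DrugSignature,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p: gene labels of the drug signature are permuted.

    p = (1 + #{|score_perm| >= |score_obs|}) / (n_perm + 1); deterministic
    given ``seed``. The query's structure is preserved.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    obs = abs(score_fn(q, d).score)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = np.array(d.effects.index, dtype=object)
    eff = d.effects.to_numpy()
    pv = None if d.pvals is None else d.pvals.to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(genes))
        dp = DrugSignature(
            drug_id=d.drug_id,
            effects=pd.Series(eff[perm], index=genes),
            pvals=None if pv is None else pd.Series(pv[perm], index=genes),
        )
        if abs(score_fn(q, dp).score) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def score_drug_set(
    queries: Mapping[int, QuerySignature],
    drugs: DrugSignatureSet,
    methods: Sequence[str] = ("gsea_ks", "gwc"),
) -> pd.DataFrame:
    """Score every drug against every query size with every method.

    Returns a tidy DataFrame (drug, method, size, score, n_common). Shares
    the per-drug ranking across sizes for the KS method.
    """
    genes = np.array(drugs.effects.index, dtype=object)
    gene_row = {g: i for i, g in enumerate(genes)}
    E = drugs.effects.to_numpy(dtype=float)
    P = drugs.pvals.to_numpy(dtype=float)
    n = len(genes)
    rows = []
    size_info = {}
    for size, q in queries.items():
        up_rows = np.array([gene_row[g] for g in q.up_genes if g in gene_row])
        down_rows = np.array([gene_row[g] for g in q.down_genes if g in gene_row])
        sig_rows = np.concatenate([up_rows, down_rows])
        qs = np.concatenate(
            [
                q.stats[[genes[i] for i in up_rows]].to_numpy(dtype=float),
                q.stats[[genes[i] for i in down_rows]].to_numpy(dtype=float),
            ]
        )
        qlp = -np.log10(
            np.clip(
                np.concatenate(
                    [
                        q.pvals[[genes[i] for i in up_rows]].to_numpy(dtype=float),
                        q.pvals[[genes[i] for i in down_rows]].to_numpy(dtype=float),
                    ]
                ),
                _P_FLOOR,
                1.0,
            )
        )
        size_info[size] = (up_rows, down_rows, sig_rows, sstats.rankdata(qs), qlp)

    gene_codes = np.arange(n)  # index order as deterministic tie-break
    for j, drug_id in enumerate(drugs.drug_ids):
        eff = E[:, j]
        order = np.lexsort((gene_codes, -eff))
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(1, n + 1)
        dlp = -np.log10(np.clip(P[:, j], _P_FLOOR, 1.0))
        for size, (up_rows, down_rows, sig_rows, q_ranks, qlp) in size_info.items():
            if "gsea_ks" in methods:
                es_up = ks_enrichment_score(np.sort(ranks[up_rows]), n)
                es_down = ks_enrichment_score(np.sort(ranks[down_rows]), n)
                rows.append(
                    {
                        "drug": drug_id,
                        "method": "gsea_ks",
                        "size": size,
                        "score": _combine_es(es_up, es_down),
                        "n_common": sig_rows.size,
                    }
                )
            if "gwc" in methods:
                w = 0.5 * (qlp + dlp[sig_rows])
                score = _weighted_pearson(
                    q_ranks, sstats.rankdata(eff[sig_rows]), w
                )
                rows.append(
                    {
                        "drug": drug_id,
                        "method": "gwc",
                        "size": size,
                        "score": score,
                        "n_common": sig_rows.size,
                    }
                )
    return pd.DataFrame(rows)


def rank_and_intersect(
    results: pd.DataFrame, cutoff: float | Mapping[str, float] = -0.5
) -> dict:
    """Per-method hit lists (score below cutoff in ALL sizes) and their
    cross-method intersection.

    ``cutoff`` may be a single value or a per-method mapping (e.g. a relaxed
    GWC cutoff of -0.45 when nothing clears -0.5 across all runs).
    """
    required = {"drug", "method", "size", "score"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    methods = sorted(results["method"].unique())
    drug_sets = {
        (m, s): frozenset(g["drug"])
        for (m, s), g in results.groupby(["method", "size"])
    }
    if len(set(drug_sets.values())) != 1:
        raise ValueError("all method/size result sets must cover identical drugs")
    hits: dict[str, list[str]] = {}
    for m in methods:
        cut = cutoff[m] if isinstance(cutoff, Mapping) else cutoff
        sub = results[results["method"] == m]
        below = sub.assign(hit=sub["score"] < cut).groupby("drug")["hit"].all()
        mean_score = sub.groupby("drug")["score"].mean()
        hit_drugs = below.index[below].tolist()
        hits[m] = sorted(hit_drugs, key=lambda d: (mean_score[d], d))
    common: set[str] = set.intersection(*(set(v) for v in hits.values())) if hits else set()
    return {
        "hits": hits,
        "common": sorted(common),
        "cutoffs": {
            m: (cutoff[m] if isinstance(cutoff, Mapping) else cutoff) for m in methods
        },
    }
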