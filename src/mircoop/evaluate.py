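"""Recovery evaluations of the analysis stages on synthetic ground truth.

Each function regenerates cohorts (or drug sets) under the planted study
conditions across many seeds, runs the corresponding stage of the analysis,
and measures how reliably the planted structure is recovered: the planted
miRNAs by the correlation ranking, the planted high-hazard subgroup by the
a/b/c rule with survival-optimized cutoffs, and the planted reversal drugs
by the connectivity scores. These back the package's calibration claims and
feed the acceptance report.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cmap as cmap_mod
from . import mircorr, stratify, survstats
from .datamodel import median_center
from .syndata import GroundTruth, SyntheticConfig, generate_cohort, generate_drug_signatures

__all__ = [
    "discovery_recovery",
    "prognosis_recovery",
    "reversal_recovery",
    "synthetic_de_table",
]

# small expression sidecar: discovery/prognosis runs only need the anchor
# gene and the miRNA matrix, so the mRNA program is kept minimal for speed
_LEAN = dict(n_genes=40, n_pathway_genes=5, n_de_genes=10, n_cna_genes=5, n_mutation_genes=5)


def discovery_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_samples: int = 600,
    n_mirnas: int = 300,
    planted_correlation: float = 0.5,
    n_bipartitions: int = 3,
    top_k: int = 10,
) -> dict:
    """Fraction of seeds in which all planted miRNAs land in the
    positive-direction top ``top_k`` of the average correlation ranking."""
    hits = 0
    for i in range(n_seeds):
        seed = int(base_seed + i)
        cfg = SyntheticConfig(
            n_samples=n_samples,
            n_mirnas=n_mirnas,
            planted_correlation=planted_correlation,
            seed=seed,
            **_LEAN,
        )
        bundle, truth = generate_cohort(cfg)
        scheme = mircorr.make_subgroup_scheme(
            bundle.sample_ids, n_bipartitions=n_bipartitions, seed=seed
        )
        records = {
            lab: mircorr.correlate_anchor(
                bundle.mrna.feature(truth.anchor_gene_id), bundle.mirna, grp
            )
            for lab, grp in scheme.groups
        }
        table = mircorr.average_ranking(records, direction="positive")
        top = set(mircorr.top_candidates(table, top_k))
        hits += set(truth.planted_mirna_ids) <= top
    return {"recovery_fraction": hits / n_seeds, "n_seeds": n_seeds}


def _stratify_one(cfg: SyntheticConfig) -> tuple[survstats.SurvivalComparison, float]:
    """Run the stratification machinery on one cohort; returns the group-a
    log-rank comparison and the recall of planted aggressive samples."""
    bundle, truth = generate_cohort(cfg)
    mrna = median_center(bundle.mrna)
    tnbc_ids = [s for s, v in bundle.clinical.is_tnbc.items() if v]
    times = bundle.clinical.os_time[tnbc_ids].to_numpy()
    events = bundle.clinical.os_event[tnbc_ids].to_numpy()
    pten_low = stratify.call_pten_low(mrna.feature(truth.anchor_gene_id))[tnbc_ids]
    mir_low = {}
    for m in truth.planted_mirna_ids:
        vals = bundle.mirna.feature(m)[tnbc_ids]
        res = survstats.optimize_cutoff(vals.to_numpy(), times, events, label=m)
        mir_low[m] = vals <= res.cutoff
    assignment = stratify.assign_groups(
        pten_low,
        pd.DataFrame(mir_low),
        bundle.clinical.is_tnbc[tnbc_ids].astype(bool),
    )
    mask = (assignment.labels == "a").to_numpy().astype(int)
    cmp_ = survstats.logrank_compare(mask, times, events)
    group_a = set(assignment.samples("a"))
    recall = len(group_a & set(truth.aggressive_sample_ids)) / len(truth.aggressive_sample_ids)
    return cmp_, recall


def prognosis_recovery(
    n_reps: int = 200,
    base_seed: int = 0,
    n_samples: int = 1000,
    true_hr: float = 4.0,
    aggressive_fraction: float = 0.10,
) -> dict:
    """Mean estimated O/E hazard ratio of group "a" vs the remaining TNBC
    samples, and the log-rank rejection rate at alpha = 0.05, over replicate
    all-TNBC cohorts with the planted hazard ratio."""
    hrs, rejections, recalls = [], 0, []
    for i in range(n_reps):
        cfg = SyntheticConfig(
            n_samples=n_samples,
            tnbc_fraction=1.0,
            aggressive_fraction=aggressive_fraction,
            true_hr=true_hr,
            n_mirnas=5,
            seed=int(base_seed + i),
            **_LEAN,
        )
        cmp_, recall = _stratify_one(cfg)
        hrs.append(cmp_.hr)
        rejections += cmp_.p < 0.05
        recalls.append(recall)
    return {
        "mean_hr": float(np.mean(hrs)),
        "rejection_rate": rejections / n_reps,
        "mean_recall": float(np.mean(recalls)),
        "n_reps": n_reps,
    }


def synthetic_de_table(
    n_genes: int = 1000, n_per_direction: int = 200, effect_t: float = 6.0, seed: int = 0
) -> pd.DataFrame:
    """A deterministic stand-in DE table (t, p, q per gene) with strong
    up/down programs, for exercising signature building and drug scoring
    without rerunning differential expression."""
    from .diffexp import bh_adjust

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    t = rng.standard_normal(n_genes)
    t[:n_per_direction] = effect_t + rng.standard_normal(n_per_direction)
    t[n_per_direction : 2 * n_per_direction] = -effect_t + rng.standard_normal(n_per_direction)
    p = 2.0 * stats.norm.sf(np.abs(t))
    q = bh_adjust(p)
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=pd.Index(genes, name="gene"))


def reversal_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_drugs: int = 100,
    n_reversal: int = 3,
    n_genes: int = 1000,
    sizes: tuple[int, ...] = (100, 150, 200, 298),
    top_k: int = 5,
    cutoff: float = -0.5,
) -> dict:
    """Fraction of seeds in which all planted reversal drugs rank in the
    ``top_k`` most-negative scores for both methods and appear in the
    cross-method hit intersection (score below ``cutoff`` in all sizes)."""
    empty_truth = GroundTruth(
        aggressive_sample_ids=(),
        planted_mirna_ids=(),
        anchor_gene_id="PTEN",
        true_hr=1.0,
        pathway_signature_gene_ids=(),
        de_up_gene_ids=(),
        de_down_gene_ids=(),
        tnbc_sample_ids=(),
    )
    both_top = in_common = 0
    for i in range(n_seeds):
        seed = int(base_seed + i)
        de = synthetic_de_table(n_genes=n_genes, seed=seed)
        queries = {s: cmap_mod.build_query_signature(de, s) for s in sizes}
        drug_set, truth = generate_drug_signatures(
            n_drugs, empty_truth, de["t"], n_reversal, seed=seed
        )
        scores = cmap_mod.score_drug_set(queries, drug_set)
        planted = set(truth.planted_reversal_drug_ids)
        ok_top = True
        for method in ("gsea_ks", "gwc"):
            mean_scores = (
                scores[scores["method"] == method].groupby("drug")["score"].mean()
            )
            top = set(mean_scores.sort_values().index[:top_k])
            ok_top &= planted <= top
        both_top += ok_top
        hits = cmap_mod.rank_and_intersect(scores, cutoff=cutoff)
        in_common += ok_top and planted <= set(hits["common"])
    return {
        "both_methods_top_fraction": both_top / n_seeds,
        "intersection_fraction": in_common / n_seeds,
        "n_seeds": n_seeds,
    }
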