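"""End-to-end orchestration from a config to a structured report directory.

Stages run in a fixed order — cohort assembly (or synthetic generation),
median centering, anchor-miRNA correlation ranking over 14 subgroups,
candidate selection, per-miRNA survival-cutoff optimization, per-pair and
group a/b/c survival analysis, differential expression of group "a",
connectivity-map scoring, pathway scoring with composite stratification, and
genomic landscape comparisons — with every stage's outputs and parameters
written as TSV/JSON under the output directory. Stages communicate only via
typed artifacts on disk, so each is independently re-runnable. A failure
halts the run naming the stage; partial outputs are retained. Identical
config and seeds produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmap as cmap_mod
from . import diffexp, landscape, mircorr, pathscore, stratify, survstats
from .datamodel import (
    CohortBundle,
    assemble_cohort,
    load_clinical_table,
    load_expression_matrix,
    load_integer_matrix,
)
from .syndata import SyntheticConfig, generate_cohort, generate_drug_signatures

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger("mircoop.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; seeds are recorded verbatim in the report."""

    output_dir: str
    synthetic: SyntheticConfig | None = None
    mrna_path: str | None = None
    mirna_path: str | None = None
    clinical_path: str | None = None
    cna_path: str | None = None
    mutations_path: str | None = None
    drug_effects_path: str | None = None
    drug_pvals_path: str | None = None
    anchor_gene: str = "PTEN"
    n_bipartitions: int = 3
    seed: int = 0
    k_candidates: int = 5
    k_of_n: int = 4
    cutoff_grid: tuple[float, ...] = survstats.DEFAULT_CUTOFF_GRID
    min_group_frac: float = 0.10
    signature_sizes: tuple[int, ...] = (100, 150, 200, 298)
    ks_cutoff: float = -0.5
    gwc_cutoff: float = -0.5
    n_perm: int = 0  # permutation p-values per drug; 0 skips them
    n_drugs: int = 100
    n_reversal: int = 3
    drug_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.synthetic is None and not (
            self.mrna_path and self.mirna_path and self.clinical_path
        ):
            raise ValueError("either synthetic config or input paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            for key in ("cna_gain_prob", "cna_loss_prob", "mutation_prob", "tp53_mutation_prob"):
                if key in syn:
                    syn[key] = dict(syn[key])
            syn = SyntheticConfig(**syn)
        for key in ("cutoff_grid", "signature_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.bool_):
        return bool(x)
    return x


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")


def _comparison_row(label: str, cmp_: survstats.SurvivalComparison) -> dict:
    return {"label": label, **cmp_.to_dict()}


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole analysis; returns the machine-readable summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "params": _jsonable(
            {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("synthetic", "output_dir")
            }
        ),
    }
    if config.synthetic is not None:
        summary["params"]["synthetic"] = _jsonable(dataclasses.asdict(config.synthetic))

    stage = "assemble"
    try:
        logger.info("stage %s: seed=%d", stage, config.seed)
        truth = None
        if config.synthetic is not None:
            bundle, truth = generate_cohort(config.synthetic)
            inputs = out / "00_inputs"
            inputs.mkdir(parents=True, exist_ok=True)
            bundle.mrna.to_tsv(inputs / "mrna.tsv")
            bundle.mirna.to_tsv(inputs / "mirna.tsv")
            bundle.clinical.to_tsv(inputs / "clinical.tsv")
            if bundle.cna is not None:
                _write_tsv(bundle.cna, inputs / "cna.tsv")
            if bundle.mutations is not None:
                _write_tsv(bundle.mutations, inputs / "mutations.tsv")
            truth.to_text(inputs / "truth.txt")
        else:
            bundle = assemble_cohort(
                load_expression_matrix(config.mrna_path),
                load_expression_matrix(config.mirna_path),
                load_clinical_table(config.clinical_path),
                cna=None
                if config.cna_path is None
                else load_integer_matrix(config.cna_path, [-2, -1, 0, 1, 2], "CNA code"),
                mutations=None
                if config.mutations_path is None
                else load_integer_matrix(config.mutations_path, [0, 1], "mutation flag"),
            )
            summary["dropped_samples"] = _jsonable(dict(bundle.dropped))
        bundle = bundle.center_expression()
        clinical = bundle.clinical
        is_tnbc = clinical.is_tnbc.astype(bool)
        tnbc_ids = [s for s in bundle.sample_ids if is_tnbc[s]]
        summary["cohort"] = {
            "n_samples": bundle.n_samples,
            "n_tnbc": len(tnbc_ids),
            "n_genes": bundle.mrna.shape[0],
            "n_mirnas": bundle.mirna.shape[0],
        }

        stage = "correlation_ranking"
        anchor = bundle.mrna.feature(config.anchor_gene)
        rank_dir = out / "01_ranking"
        rankings = {}
        for cls_label, ids in (("bc", bundle.sample_ids), ("tnbc", tnbc_ids)):
            scheme = mircorr.make_subgroup_scheme(
                ids, n_bipartitions=config.n_bipartitions, seed=config.seed
            )
            records = {
                lab: mircorr.correlate_anchor(anchor, bundle.mirna, grp)
                for lab, grp in scheme.groups
            }
            for direction in ("positive", "negative"):
                table = mircorr.average_ranking(records, direction=direction)
                rankings[(cls_label, direction)] = table
                _write_tsv(table.table, rank_dir / f"ranking_{cls_label}_{direction}.tsv")
        tnbc_pos = rankings[("tnbc", "positive")]
        candidates = mircorr.top_candidates(tnbc_pos, config.k_candidates)
        (rank_dir / "candidates.txt").write_text("\n".join(candidates) + "\n")
        summary["candidates"] = candidates
        summary["n_groups_per_class"] = 2 * config.n_bipartitions + 1

        stage = "cutoff_optimization"
        tnbc = bundle.subset_samples(tnbc_ids)
        times = tnbc.clinical.os_time.to_numpy()
        events = tnbc.clinical.os_event.to_numpy()
        cut_dir = out / "02_cutoffs"
        cutoffs = {}
        for mir in candidates:
            res = survstats.optimize_cutoff(
                tnbc.mirna.feature(mir).to_numpy(),
                times,
                events,
                grid=config.cutoff_grid,
                min_group_frac=config.min_group_frac,
                label=mir,
            )
            cutoffs[mir] = res
            _write_tsv(res.grid_evaluated, cut_dir / f"grid_{mir}.tsv")
        cut_df = pd.DataFrame(
            {
                "cutoff": {m: r.cutoff for m, r in cutoffs.items()},
                "quantile": {m: r.quantile for m, r in cutoffs.items()},
                "p": {m: r.comparison.p for m, r in cutoffs.items()},
                "n_candidates": {m: r.n_candidates for m, r in cutoffs.items()},
            }
        )
        cut_df.index.name = "mirna_id"
        _write_tsv(cut_df, cut_dir / "cutoffs.tsv")
        summary["mir_cutoffs"] = _jsonable(cut_df["cutoff"].to_dict())

        stage = "pair_survival"
        pten_low_all = stratify.call_pten_low(bundle.mrna.feature(config.anchor_gene))
        pten_low = pten_low_all[tnbc_ids]
        surv_dir = out / "03_survival"
        pair_rows = []
        pair_rows.append(
            _comparison_row(
                "pten_low_alone",
                survstats.logrank_compare(pten_low.astype(int).to_numpy(), times, events),
            )
        )
        mir_low = pd.DataFrame(
            {
                m: tnbc.mirna.feature(m) <= cutoffs[m].cutoff
                for m in candidates
            }
        )
        for m in candidates:
            both = stratify.composite_stratify(pten_low, mir_low[m])
            pair_rows.append(
                _comparison_row(
                    f"pten_low_and_{m}_low",
                    survstats.logrank_compare((both == "both").astype(int).to_numpy(), times, events),
                )
            )
        pairs_df = pd.DataFrame(pair_rows).set_index("label")
        _write_tsv(pairs_df, surv_dir / "pair_comparisons.tsv")
        summary["pair_hr"] = _jsonable(pairs_df["hr"].to_dict())

        stage = "group_assignment"
        assignment = stratify.assign_groups(
            pten_low, mir_low, tnbc.clinical.is_tnbc[tnbc_ids].astype(bool), k_of_n=config.k_of_n
        )
        labels = assignment.labels
        groups_df = pd.DataFrame(
            {
                "label": labels,
                "pten_low": pten_low.astype(int),
                **{f"{m}_low": mir_low[m].astype(int) for m in candidates},
            }
        )
        _write_tsv(groups_df, surv_dir / "group_assignment.tsv")
        summary["group_counts"] = _jsonable(assignment.counts())
        group_a_mask = (labels == "a").astype(int).to_numpy()
        if group_a_mask.sum() == 0:
            raise ValueError("group 'a' is empty under the current rule")
        cmp_a = survstats.logrank_compare(group_a_mask, times, events)
        _write_tsv(
            pd.DataFrame([_comparison_row("group_a_vs_rest", cmp_a)]).set_index("label"),
            surv_dir / "group_a_vs_rest.tsv",
        )
        summary["group_a_vs_rest"] = _jsonable(cmp_a.to_dict())

        stage = "diffexp"
        de = diffexp.moderated_t_test(tnbc.mrna, group_a_mask)
        (out / "04_diffexp").mkdir(parents=True, exist_ok=True)
        de.to_tsv(out / "04_diffexp" / "de_table.tsv")
        n_sig = int((de.table["q"] < 0.05).sum())
        summary["diffexp"] = {
            "n_genes_tested": len(de.table),
            "n_fdr05": n_sig,
            "prior_d0": _jsonable(de.prior.d0),
            "prior_s0_sq": de.prior.s0_sq,
        }

        stage = "connectivity"
        cmap_dir = out / "05_cmap"
        queries = {
            size: cmap_mod.build_query_signature(de, size)
            for size in config.signature_sizes
        }
        if config.synthetic is not None:
            de_profile = de.table["t"].reindex(tnbc.mrna.feature_ids).fillna(0.0)
            drug_seed = (config.seed + 1) % (2**31)
            drug_set, truth = generate_drug_signatures(
                config.n_drugs,
                truth,
                de_profile,
                config.n_reversal,
                seed=drug_seed,
                noise_sd=config.drug_noise_sd,
            )
            truth.to_text(out / "00_inputs" / "truth.txt")
        elif config.drug_effects_path and config.drug_pvals_path:
            from .syndata import DrugSignatureSet

            eff = pd.read_csv(config.drug_effects_path, sep="\t", index_col=0)
            pvs = pd.read_csv(config.drug_pvals_path, sep="\t", index_col=0)
            drug_set = DrugSignatureSet(effects=eff, pvals=pvs, reversal_drug_ids=())
        else:
            drug_set = None
        if drug_set is not None:
            scores = cmap_mod.score_drug_set(queries, drug_set)
            _write_tsv(scores.set_index("drug"), cmap_dir / "scores.tsv")
            hits = cmap_mod.rank_and_intersect(
                scores, cutoff={"gsea_ks": config.ks_cutoff, "gwc": config.gwc_cutoff}
            )
            (cmap_dir / "hits.json").write_text(
                json.dumps(_jsonable(hits), indent=2, sort_keys=True) + "\n"
            )
            summary["connectivity"] = _jsonable(
                {
                    "hits": hits["hits"],
                    "common": hits["common"],
                    "sizes": list(config.signature_sizes),
                }
            )
        else:
            summary["connectivity"] = "skipped (no drug signatures supplied)"

        stage = "pathway"
        path_dir = out / "06_pathway"
        if truth is not None and truth.pathway_signature_gene_ids:
            sig = pathscore.PathwaySignature.from_genes(
                "planted_pathway", truth.pathway_signature_gene_ids
            )
            activity = pathscore.score_signature(tnbc.mrna, sig)
            act_df = pd.DataFrame({"raw": activity.raw, "activity": activity.activity})
            _write_tsv(act_df, path_dir / "activity_planted_pathway.tsv")
            high = pathscore.call_pathway_high(activity)
            both = stratify.composite_stratify(pten_low, high)
            cmp_path = survstats.logrank_compare(
                (both == "both").astype(int).to_numpy(), times, events
            )
            _write_tsv(
                pd.DataFrame(
                    [_comparison_row("pten_low_and_pathway_high", cmp_path)]
                ).set_index("label"),
                path_dir / "composite_comparison.tsv",
            )
            summary["pathway_composite"] = _jsonable(cmp_path.to_dict())
        else:
            summary["pathway_composite"] = "skipped (no pathway signature)"

        stage = "landscape"
        land_dir = out / "07_landscape"
        anova = landscape.anova_by_group(tnbc.mrna, labels)
        _write_tsv(anova.table, land_dir / "anova_by_group.tsv")
        topk = landscape.top_k_by_anova(anova, k=20)
        (land_dir / "top20_anova.txt").write_text("\n".join(topk) + "\n")
        summary["landscape"] = {"anova_top20": topk, "anova_levels": list(anova.group_levels)}
        if tnbc.cna is not None:
            burden = landscape.cna_burden(tnbc.cna)
            _write_tsv(burden.table, land_dir / "cna_burden.tsv")
            gain_t = landscape.t_by_mask(
                _burden_matrix(burden), group_a_mask
            )
            _write_tsv(gain_t.table, land_dir / "cna_burden_t_a_vs_rest.tsv")
            summary["landscape"]["cna_burden_p"] = _jsonable(gain_t.table["p"].to_dict())
        if tnbc.mutations is not None:
            mut_cmp = landscape.mutation_compare(
                tnbc.mutations, pd.Series(np.where(group_a_mask, "a", "rest"), index=labels.index)
            )
            _write_tsv(mut_cmp, land_dir / "mutation_compare_a_vs_rest.tsv")
            top_mut = mut_cmp.sort_values("p").head(5)
            summary["landscape"]["top_mutated_genes"] = _jsonable(
                {g: top_mut.at[g, "p"] for g in top_mut.index}
            )
    except Exception as exc:  # noqa: BLE001 — halt with stage name, keep partials
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    summary_text = json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    (out / "summary.json").write_text(summary_text)
    logger.info("run complete; summary at %s", out / "summary.json")
    return summary


def _burden_matrix(burden: landscape.CnaBurden):
    from .datamodel import ExpressionMatrix

    return ExpressionMatrix(burden.table.T.astype(float))
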