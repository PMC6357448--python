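"""Synthetic cohorts with planted PTEN-miRNA structure, and drug signatures.

The generator emulates the structure the downstream analysis assumes: a
breast-cancer cohort with matched mRNA/miRNA matrices in which a small set of
miRNAs co-varies with the PTEN anchor gene at a configured Pearson
correlation; a planted "aggressive" subgroup of triple-negative samples with
PTEN and the planted miRNAs shifted down, an elevated proportional hazard,
group-specific copy-number / mutation / pathway-signature alterations, and a
planted differential-expression program; plus a drug-perturbation signature
set containing planted "reversal" drugs whose effects oppose that program.

Survival is exponential (so the configured hazard ratio is the exact rate
ratio) with independent exponential censoring calibrated to the requested
censoring fraction. Everything is deterministic given the seed: one global
seed feeds a hierarchical stream-splitting scheme so each sub-generator is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import ClinicalTable, CohortBundle, ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "DrugSignatureSet",
    "GenerationError",
    "generate_cohort",
    "generate_drug_signatures",
    "planted_coupling",
]


class GenerationError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Shifts are additive on the log2 scale. ``anchor_shift`` (default 3.0) and
    ``mirna_shift`` (default 2.0) size the aggressive-group downshifts of the
    anchor gene and the planted miRNAs so that the twofold-below-median rule
    and optimized miR cutoffs capture aggressive samples with high
    probability. ``baseline_hazard`` is in events per month.
    """

    n_samples: int = 600
    tnbc_fraction: float = 0.16
    n_genes: int = 1000
    n_mirnas: int = 300
    n_planted_mirnas: int = 5
    planted_correlation: float = 0.5
    aggressive_fraction: float = 0.10
    true_hr: float = 4.0
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.4
    anchor_shift: float = 3.0
    mirna_shift: float = 2.5
    pathway_shift: float = 1.0
    n_pathway_genes: int = 30
    n_de_genes: int = 200
    de_shift: float = 1.5
    n_cna_genes: int = 60
    n_mutation_genes: int = 40
    cna_gain_prob: dict = field(
        default_factory=lambda: {"aggressive": 0.15, "other": 0.05}
    )
    cna_loss_prob: dict = field(
        default_factory=lambda: {"aggressive": 0.15, "other": 0.05}
    )
    mutation_prob: dict = field(
        default_factory=lambda: {"aggressive": 0.10, "other": 0.03}
    )
    tp53_mutation_prob: dict = field(
        default_factory=lambda: {"aggressive": 1.0, "other": 0.3}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("tnbc_fraction", "aggressive_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if not -1.0 < self.planted_correlation < 1.0:
            raise GenerationError("planted_correlation must be in (-1, 1)")
        if self.true_hr <= 0:
            raise GenerationError("true_hr must be positive")
        if self.n_planted_mirnas > self.n_mirnas:
            raise GenerationError("n_planted_mirnas exceeds n_mirnas")
        reserved = 1 + self.n_pathway_genes + 2 * self.n_de_genes
        if self.n_genes < reserved:
            raise GenerationError(
                f"n_genes={self.n_genes} too small for anchor + pathway + DE "
                f"program ({reserved} genes)"
            )
        n_aggr = int(round(self.aggressive_fraction * round(self.tnbc_fraction * self.n_samples)))
        if n_aggr < 2:
            raise GenerationError(
                "infeasible config: aggressive_fraction x tnbc_fraction x "
                f"n_samples yields {n_aggr} aggressive samples (< 2)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Record of the planted structure, for recovery tests."""

    aggressive_sample_ids: tuple[str, ...]
    planted_mirna_ids: tuple[str, ...]
    anchor_gene_id: str
    true_hr: float
    pathway_signature_gene_ids: tuple[str, ...]
    de_up_gene_ids: tuple[str, ...]
    de_down_gene_ids: tuple[str, ...]
    tnbc_sample_ids: tuple[str, ...]
    planted_reversal_drug_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.aggressive_sample_ids) <= set(self.tnbc_sample_ids):
            raise ValueError("aggressive samples must be a subset of TNBC samples")

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"anchor_gene_id\t{self.anchor_gene_id}\n")
            fh.write(f"true_hr\t{self.true_hr!r}\n")
            for name in (
                "aggressive_sample_ids",
                "planted_mirna_ids",
                "pathway_signature_gene_ids",
                "de_up_gene_ids",
                "de_down_gene_ids",
                "tnbc_sample_ids",
                "planted_reversal_drug_ids",
            ):
                fh.write(f"{name}\t{','.join(getattr(self, name))}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "GroundTruth":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, _, val = line.rstrip("\n").partition("\t")
                kv[key] = val
        lists = {
            name: tuple(x for x in kv[name].split(",") if x)
            for name in (
                "aggressive_sample_ids",
                "planted_mirna_ids",
                "pathway_signature_gene_ids",
                "de_up_gene_ids",
                "de_down_gene_ids",
                "tnbc_sample_ids",
                "planted_reversal_drug_ids",
            )
        }
        return cls(
            anchor_gene_id=kv["anchor_gene_id"],
            true_hr=float(kv["true_hr"]),
            **lists,
        )


def planted_coupling(
    r: float, anchor_shift: float, mirna_shift: float, aggressive_prob: float
) -> float:
    """Coupling coefficient ``a`` so the population Pearson correlation
    between anchor and a planted miRNA equals ``r``.

    The anchor is x = z - anchor_shift*B and the miRNA y = a*x + e -
    mirna_shift*B, with z, e standard normal and B ~ Bernoulli(p) the
    aggressive indicator (so planted miRNAs inherit the anchor's aggressive
    downshift through a*x and receive their own on top). The shared
    downshift contributes extra covariance, so ``a`` solves a quadratic:
    with u = Var(x) = 1 + anchor_shift^2 pq, c = anchor_shift*mirna_shift*pq
    and v = 1 + mirna_shift^2 pq,

        a = (-c + sign(r) sqrt(r^2 (u v - c^2) / (1 - r^2))) / u.

    With no shifts this reduces to the closed form a = r / sqrt(1 - r^2).
    """
    pq = aggressive_prob * (1.0 - aggressive_prob)
    c = anchor_shift * mirna_shift * pq
    u = 1.0 + anchor_shift**2 * pq
    v = 1.0 + mirna_shift**2 * pq
    k = r**2
    if k >= 1.0:
        raise GenerationError("planted_correlation must lie strictly inside (-1, 1)")
    if r == 0.0:
        return -c / u
    disc = k * (u * v - c**2) / (1.0 - k)
    return (-c + np.sign(r) * np.sqrt(disc)) / u


def _censoring_rate_to_hazard(
    hazards: np.ndarray, censoring_rate: float
) -> float:
    """Exponential censoring rate c with mean P(censored) = censoring_rate.

    For a subject with event rate lam, P(censor first) = c / (lam + c).
    """
    if censoring_rate <= 0:
        return 0.0

    def f(c: float) -> float:
        return float(np.mean(c / (hazards + c))) - censoring_rate

    hi = hazards.max() * 1e6
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-12))


def _receptor_status(rng: np.random.Generator, is_tnbc: np.ndarray) -> pd.DataFrame:
    n = is_tnbc.size
    er = np.where(is_tnbc, "neg", np.where(rng.random(n) < 0.75, "pos", "neg"))
    pr = np.where(is_tnbc, "neg", np.where(rng.random(n) < 0.6, "pos", "neg"))
    her2 = np.where(is_tnbc, "neg", np.where(rng.random(n) < 0.2, "pos", "neg"))
    # non-TNBC samples must have at least one positive receptor
    all_neg = (~is_tnbc) & (er == "neg") & (pr == "neg") & (her2 == "neg")
    er = np.where(all_neg, "pos", er)
    return pd.DataFrame({"er": er, "pr": pr, "her2": her2})


def generate_cohort(config: SyntheticConfig) -> tuple[CohortBundle, GroundTruth]:
    """Generate one cohort plus its ground-truth record.

    Deterministic given ``config.seed``. The returned expression matrices are
    uncentered (``centered=False``); callers normalise with
    :func:`mircoop.datamodel.median_center` as they would for real data.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (ss_groups, ss_expr, ss_mirna, ss_surv, ss_cna, ss_mut, ss_clin) = root.spawn(7)

    n = config.n_samples
    sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    rng_g = np.random.default_rng(ss_groups)
    n_tnbc = int(round(config.tnbc_fraction * n))
    tnbc_idx = np.sort(rng_g.choice(n, size=n_tnbc, replace=False))
    n_aggr = int(round(config.aggressive_fraction * n_tnbc))
    aggr_idx = np.sort(rng_g.choice(tnbc_idx, size=n_aggr, replace=False))
    is_tnbc = np.zeros(n, dtype=bool)
    is_tnbc[tnbc_idx] = True
    is_aggr = np.zeros(n, dtype=bool)
    is_aggr[aggr_idx] = True

    # --- mRNA -------------------------------------------------------------
    rng_e = np.random.default_rng(ss_expr)
    gene_ids = ["PTEN"] + [f"G{i + 1:05d}" for i in range(config.n_genes - 1)]
    pathway_genes = gene_ids[1 : 1 + config.n_pathway_genes]
    de_up = gene_ids[
        1 + config.n_pathway_genes : 1 + config.n_pathway_genes + config.n_de_genes
    ]
    de_down = gene_ids[
        1 + config.n_pathway_genes + config.n_de_genes :
        1 + config.n_pathway_genes + 2 * config.n_de_genes
    ]
    expr = rng_e.standard_normal((config.n_genes, n))
    expr[0, is_aggr] -= config.anchor_shift
    anchor_expression = expr[0].copy()
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for g in pathway_genes:
        expr[gidx[g], is_aggr] += config.pathway_shift
    for g in de_up:
        expr[gidx[g], is_aggr] += config.de_shift
    for g in de_down:
        expr[gidx[g], is_aggr] -= config.de_shift
    mrna = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))

    # --- miRNA ------------------------------------------------------------
    rng_m = np.random.default_rng(ss_mirna)
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    planted = mirna_ids[: config.n_planted_mirnas]
    mir = rng_m.standard_normal((config.n_mirnas, n))
    a = planted_coupling(
        config.planted_correlation,
        config.anchor_shift,
        config.mirna_shift,
        n_aggr / n,
    )
    for i in range(config.n_planted_mirnas):
        mir[i] = a * anchor_expression + mir[i]
        mir[i, is_aggr] -= config.mirna_shift
    mirna = ExpressionMatrix(pd.DataFrame(mir, index=mirna_ids, columns=sample_ids))

    # --- survival ---------------------------------------------------------
    rng_s = np.random.default_rng(ss_surv)
    hazards = config.baseline_hazard * np.where(is_aggr, config.true_hr, 1.0)
    event_times = rng_s.exponential(1.0 / hazards)
    c_rate = _censoring_rate_to_hazard(hazards, config.censoring_rate)
    if c_rate > 0:
        censor_times = rng_s.exponential(1.0 / c_rate, size=n)
        os_time = np.minimum(event_times, censor_times)
        os_event = (event_times <= censor_times).astype(int)
    else:
        os_time, os_event = event_times, np.ones(n, dtype=int)

    rng_c = np.random.default_rng(ss_clin)
    receptors = _receptor_status(rng_c, is_tnbc)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time_months": os_time,
                "os_event": os_event,
                "er": receptors["er"].to_numpy(),
                "pr": receptors["pr"].to_numpy(),
                "her2": receptors["her2"].to_numpy(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- CNA --------------------------------------------------------------
    rng_cna = np.random.default_rng(ss_cna)
    cna_genes = gene_ids[: config.n_cna_genes]
    p_gain = np.where(is_aggr, config.cna_gain_prob["aggressive"], config.cna_gain_prob["other"])
    p_loss = np.where(is_aggr, config.cna_loss_prob["aggressive"], config.cna_loss_prob["other"])
    u = rng_cna.random((config.n_cna_genes, n))
    deep = rng_cna.random((config.n_cna_genes, n)) < 0.3
    cna = np.zeros((config.n_cna_genes, n), dtype=int)
    cna[u < p_loss] = -1
    cna[(u < p_loss) & deep] = -2
    gain_mask = (u >= p_loss) & (u < p_loss + p_gain)
    cna[gain_mask] = 1
    cna[gain_mask & deep] = 2
    cna_df = pd.DataFrame(cna, index=cna_genes, columns=sample_ids)

    # --- mutations --------------------------------------------------------
    rng_mut = np.random.default_rng(ss_mut)
    mut_genes = ["TP53"] + [f"MUT{i + 1:03d}" for i in range(config.n_mutation_genes - 1)]
    p_mut = np.where(is_aggr, config.mutation_prob["aggressive"], config.mutation_prob["other"])
    mut = (rng_mut.random((config.n_mutation_genes, n)) < p_mut).astype(int)
    p_tp53 = np.where(
        is_aggr, config.tp53_mutation_prob["aggressive"], config.tp53_mutation_prob["other"]
    )
    mut[0] = (rng_mut.random(n) < p_tp53).astype(int)
    mut_df = pd.DataFrame(mut, index=mut_genes, columns=sample_ids)

    bundle = CohortBundle(
        mrna=mrna, mirna=mirna, clinical=clinical, cna=cna_df, mutations=mut_df
    )
    truth = GroundTruth(
        aggressive_sample_ids=tuple(sample_ids[is_aggr]),
        planted_mirna_ids=tuple(planted),
        anchor_gene_id="PTEN",
        true_hr=config.true_hr,
        pathway_signature_gene_ids=tuple(pathway_genes),
        de_up_gene_ids=tuple(de_up),
        de_down_gene_ids=tuple(de_down),
        tnbc_sample_ids=tuple(sample_ids[is_tnbc]),
    )
    return bundle, truth


@dataclass(frozen=True)
class DrugSignatureSet:
    """Gene-by-drug perturbation effect estimates with pseudo p-values."""

    effects: pd.DataFrame
    pvals: pd.DataFrame
    reversal_drug_ids: tuple[str, ...]

    @property
    def drug_ids(self) -> list[str]:
        return list(self.effects.columns)

    def drug(self, drug_id: str) -> tuple[pd.Series, pd.Series]:
        return self.effects[drug_id], self.pvals[drug_id]


def generate_drug_signatures(
    n_drugs: int,
    truth: GroundTruth,
    de_profile: pd.Series,
    n_reversal: int,
    seed: int,
    noise_sd: float = 0.3,
) -> tuple[DrugSignatureSet, GroundTruth]:
    """Synthetic drug-perturbation signatures with planted reversal drugs.

    Reversal drugs carry effects anti-correlated with ``de_profile``
    (sign-flipped plus Gaussian noise of sd ``noise_sd`` times the profile
    scale); the remaining drugs are independent noise on the profile's scale.
    Pseudo p-values come from a normal reference on the standardized effects.
    Returns the signature set and a copy of ``truth`` with the planted drug
    ids recorded.
    """
    if n_reversal > n_drugs:
        raise GenerationError(f"n_reversal={n_reversal} exceeds n_drugs={n_drugs}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = de_profile.index
    scale = float(de_profile.std(ddof=0)) or 1.0
    drug_ids = [f"drug-{i + 1:04d}" for i in range(n_drugs)]
    reversal = tuple(sorted(rng.choice(drug_ids, size=n_reversal, replace=False)))
    effects = np.empty((len(genes), n_drugs))
    for j, d in enumerate(drug_ids):
        if d in reversal:
            effects[:, j] = -de_profile.to_numpy() + noise_sd * scale * rng.standard_normal(
                len(genes)
            )
        else:
            effects[:, j] = scale * rng.standard_normal(len(genes))
    z = effects / scale
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    eff_df = pd.DataFrame(effects, index=genes, columns=drug_ids)
    p_df = pd.DataFrame(pvals, index=genes, columns=drug_ids)
    sig_set = DrugSignatureSet(effects=eff_df, pvals=p_df, reversal_drug_ids=reversal)
    return sig_set, replace(truth, planted_reversal_drug_ids=reversal)
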