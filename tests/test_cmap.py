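import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from mircoop.cmap import (
    DrugSignature,
    QuerySignature,
    build_query_signature,
    gwc_connectivity,
    ks_connectivity,
    ks_enrichment_score,
    permutation_p,
    rank_and_intersect,
    score_drug_set,
)
from mircoop.evaluate import synthetic_de_table
from mircoop.syndata import generate_drug_signatures


def _query(up, down, stats_vals=None, pvals=None):
    genes = list(up) + list(down)
    s = pd.Series(
        stats_vals if stats_vals is not None else [1.0] * len(up) + [-1.0] * len(down),
        index=genes,
    )
    p = pd.Series(pvals if pvals is not None else [0.01] * len(genes), index=genes)
    return QuerySignature(tuple(up), tuple(down), s, p)


def _drug(effects: dict, drug_id="d", pvals=None):
    eff = pd.Series(effects, dtype=float)
    pv = None if pvals is None else pd.Series(pvals, dtype=float)
    return DrugSignature(drug_id, eff, pv)


class TestBuildQuerySignature:
    def _de(self):
        return pd.DataFrame(
            {
                "t": [5.0, 3.0, -2.0, -4.0, -6.0],
                "p": [1e-5] * 5,
                "q": [1e-4] * 5,
            },
            index=pd.Index(["gA", "gB", "gC", "gD", "gE"], name="gene"),
        )

    def test_ordering_rule(self):
        q = build_query_signature(self._de(), 4)
        assert q.up_genes == ("gA", "gB")
        assert q.down_genes == ("gE", "gD")

    def test_insufficient_significant_reports_counts(self):
        with pytest.raises(ValueError, match="2 up / 3 down"):
            build_query_signature(self._de(), 8)

    def test_equal_split_of_size(self):
        de = synthetic_de_table(n_genes=800, seed=0)
        q = build_query_signature(de, 298)
        assert len(q.up_genes) == len(q.down_genes) == 149
        assert set(q.up_genes).isdisjoint(q.down_genes)


class TestKsConnectivity:
    def test_perfect_concordance_scores_high(self):
        n = 200
        genes = [f"g{i:03d}" for i in range(n)]
        eff = {g: float(n - i) for i, g in enumerate(genes)}
        q = _query(genes[:10], genes[-10:])
        res = ks_connectivity(q, _drug(eff))
        assert res.score > 0.9
        assert res.es_up > 0 and res.es_down < 0

    def test_antisymmetric_under_ranking_reversal(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(50)]
        q = _query(genes[3:8], genes[20:25])
        for _ in range(20):
            eff = dict(zip(genes, rng.standard_normal(50)))
            fwd = ks_connectivity(q, _drug(eff))
            rev = ks_connectivity(q, _drug({g: -v for g, v in eff.items()}))
            assert rev.score == pytest.approx(-fwd.score, abs=1e-14)

    def test_zero_when_enrichment_signs_agree(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(60)]
        zeroed = 0
        for _ in range(200):
            eff = dict(zip(genes, rng.standard_normal(60)))
            q = _query(genes[:3], genes[3:6])
            res = ks_connectivity(q, _drug(eff))
            if res.es_up * res.es_down > 0:
                assert res.score == 0.0
                zeroed += 1
        assert zeroed > 0  # the invariant actually fired

    def test_matches_exhaustive_enumeration_seven_genes(self):
        genes = [f"g{i}" for i in range(1, 8)]
        q = _query(["g1"], ["g7"])
        for perm in itertools.permutations(range(1, 8)):
            eff = {g: float(-perm[i]) for i, g in enumerate(genes)}
            res = ks_connectivity(q, _drug(eff))
            rank_of = {g: perm[i] for i, g in enumerate(genes)}
            expected = oracles.bruteforce_ks_score(
                [rank_of["g1"]], [rank_of["g7"]], 7
            )
            assert res.score == pytest.approx(expected, abs=1e-14)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(40)]
        eff = rng.standard_normal(40)
        q = _query(genes[:5], genes[30:35])
        a = ks_connectivity(q, _drug(dict(zip(genes, eff))))
        b = ks_connectivity(q, _drug(dict(zip(genes, np.exp(eff)))))
        assert a.score == b.score

    def test_empty_overlap_rejected(self):
        q = _query(["x1"], ["x2"])
        with pytest.raises(ValueError, match="overlap"):
            ks_connectivity(q, _drug({"y1": 1.0, "y2": -1.0}))


class TestGwcConnectivity:
    def _uniform_p(self, genes):
        return {g: 0.05 for g in genes}

    def test_monotone_agreement_is_one(self):
        genes = [f"g{i:02d}" for i in range(12)]
        svals = np.linspace(-3, 3, 12)
        q = _query(genes[:6], genes[6:], stats_vals=svals, pvals=[0.05] * 12)
        d = _drug(dict(zip(genes, np.tanh(svals))), pvals=self._uniform_p(genes))
        assert gwc_connectivity(q, d).score == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_is_minus_one(self):
        genes = [f"g{i:02d}" for i in range(12)]
        svals = np.linspace(-3, 3, 12)
        q = _query(genes[:6], genes[6:], stats_vals=svals, pvals=[0.05] * 12)
        d = _drug(dict(zip(genes, -svals)), pvals=self._uniform_p(genes))
        assert gwc_connectivity(q, d).score == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_weighted_rank_formula(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        svals = rng.standard_normal(10)
        qp = rng.uniform(0.001, 0.5, 10)
        deff = rng.standard_normal(10)
        dp = rng.uniform(0.001, 0.5, 10)
        q = _query(genes[:5], genes[5:], stats_vals=svals, pvals=qp)
        d = _drug(dict(zip(genes, deff)), pvals=dict(zip(genes, dp)))
        w = 0.5 * (-np.log10(qp) - np.log10(dp))
        expected = oracles.bruteforce_weighted_rank_corr(svals, deff, w)
        assert gwc_connectivity(q, d).score == pytest.approx(expected, abs=1e-12)

    def test_small_universe_rejected(self):
        genes = [f"g{i}" for i in range(4)]
        q = _query(genes[:2], genes[2:])
        with pytest.raises(ValueError, match="universe"):
            gwc_connectivity(q, _drug({g: 1.0 for g in genes},
                                      pvals={g: 0.5 for g in genes}))


class TestPermutationP:
    def _setup(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        eff = dict(zip(genes, np.linspace(n, 1, n)))
        q = _query(genes[:8], genes[-8:])
        return q, _drug(eff, pvals={g: 0.05 for g in genes})

    def test_extreme_concordance_hits_floor(self):
        q, d = self._setup()
        p = permutation_p(ks_connectivity, q, d, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_deterministic_given_seed(self):
        q, d = self._setup()
        assert permutation_p(ks_connectivity, q, d, n_perm=149, seed=5) == permutation_p(
            ks_connectivity, q, d, n_perm=149, seed=5
        )

    def test_null_scores_give_large_p(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:03d}" for i in range(80)]
        q = _query(genes[:5], genes[5:10])
        d = _drug(dict(zip(genes, rng.standard_normal(80))),
                  pvals={g: 0.5 for g in genes})
        p = permutation_p(ks_connectivity, q, d, n_perm=199, seed=2)
        assert p > 0.05

    def test_null_p_distribution_calibrated(self):
        """Permutation p on random drugs: approximately uniform for the
        continuous GWC score; conservative (never anti-conservative) for the
        KS score, whose sign-agreement zero rule puts an atom at p = 1."""
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(60)]
        svals = np.linspace(3, -3, 12)
        q = _query(genes[:6], genes[54:], stats_vals=svals, pvals=[0.05] * 12)
        ps_gwc, ps_ks = [], []
        for i in range(60):
            d = _drug(dict(zip(genes, rng.standard_normal(60))), drug_id=f"d{i}",
                      pvals={g: 0.5 for g in genes})
            ps_gwc.append(permutation_p(gwc_connectivity, q, d, n_perm=149, seed=i))
            ps_ks.append(permutation_p(ks_connectivity, q, d, n_perm=149, seed=i))
        assert stats.kstest(ps_gwc, "uniform").pvalue > 0.01
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(np.asarray(ps_ks) <= alpha) <= alpha + 3 * np.sqrt(
                alpha * (1 - alpha) / 60
            )

    def test_minimum_permutations_enforced(self):
        q, d = self._setup()
        with pytest.raises(ValueError):
            permutation_p(ks_connectivity, q, d, n_perm=50, seed=0)


class TestRankAndIntersect:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["drug", "method", "size", "score"])

    def test_hit_requires_all_sizes_below_cutoff(self):
        rows = []
        for size in (100, 150, 200, 298):
            rows.append(("dA", "gsea_ks", size, -0.8))
            rows.append(("dB", "gsea_ks", size, -0.8 if size != 200 else -0.4))
        out = rank_and_intersect(self._results(rows), cutoff=-0.5)
        assert out["hits"]["gsea_ks"] == ["dA"]

    def test_intersection_across_methods(self):
        rows = []
        for m, scores in (("gsea_ks", {"dA": -0.9, "dB": -0.7}),
                          ("gwc", {"dA": -0.8, "dB": -0.2})):
            for d, s in scores.items():
                rows.append((d, m, 100, s))
        out = rank_and_intersect(self._results(rows), cutoff=-0.5)
        assert out["hits"]["gsea_ks"] == ["dA", "dB"]
        assert out["hits"]["gwc"] == ["dA"]
        assert out["common"] == ["dA"]

    def test_relaxed_per_method_cutoff(self):
        rows = [("dA", "gsea_ks", 100, -0.6), ("dA", "gwc", 100, -0.47)]
        strict = rank_and_intersect(self._results(rows), cutoff=-0.5)
        assert strict["common"] == []
        relaxed = rank_and_intersect(
            self._results(rows), cutoff={"gsea_ks": -0.5, "gwc": -0.45}
        )
        assert relaxed["common"] == ["dA"]

    def test_mismatched_drug_sets_rejected(self):
        rows = [("dA", "gsea_ks", 100, -0.6), ("dB", "gwc", 100, -0.6)]
        with pytest.raises(ValueError, match="identical drugs"):
            rank_and_intersect(self._results(rows))


class TestScoreDrugSet:
    def test_agrees_with_per_drug_scoring(self):
        de = synthetic_de_table(n_genes=300, n_per_direction=60, seed=5)
        from mircoop.cmap import build_query_signature
        from mircoop.syndata import GroundTruth

        truth = GroundTruth((), (), "PTEN", 1.0, (), (), (), ())
        drug_set, truth = generate_drug_signatures(8, truth, de["t"], 2, seed=9)
        queries = {40: build_query_signature(de, 40)}
        table = score_drug_set(queries, drug_set)
        for _, row in table.iterrows():
            eff, pv = drug_set.drug(row["drug"])
            d = DrugSignature(row["drug"], eff, pv)
            fn = ks_connectivity if row["method"] == "gsea_ks" else gwc_connectivity
            assert row["score"] == pytest.approx(fn(queries[40], d).score, abs=1e-10)
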