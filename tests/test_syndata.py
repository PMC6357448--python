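import dataclasses

import numpy as np
import pandas as pd
import pytest

from mircoop.syndata import (
    GenerationError,
    GroundTruth,
    SyntheticConfig,
    generate_cohort,
    generate_drug_signatures,
    planted_coupling,
)

LEAN = dict(n_genes=40, n_pathway_genes=5, n_de_genes=10, n_cna_genes=5, n_mutation_genes=5)


def _empty_truth():
    return GroundTruth(
        aggressive_sample_ids=(),
        planted_mirna_ids=(),
        anchor_gene_id="PTEN",
        true_hr=1.0,
        pathway_signature_gene_ids=(),
        de_up_gene_ids=(),
        de_down_gene_ids=(),
        tnbc_sample_ids=(),
    )


class TestCoupling:
    def test_reduces_to_closed_form_without_shifts(self):
        for r in (0.2, 0.5, 0.8, -0.4):
            assert planted_coupling(r, 0.0, 0.0, 0.1) == pytest.approx(
                r / np.sqrt(1 - r**2), rel=1e-12
            )

    def test_population_correlation_is_exact_under_shifts(self):
        # plug the solved a back into the population moments
        r, sa, sm, p = 0.5, 3.0, 2.0, 0.05
        a = planted_coupling(r, sa, sm, p)
        pq = p * (1 - p)
        u = 1 + sa**2 * pq
        c = sa * sm * pq
        v = 1 + sm**2 * pq
        cov = a * u + c
        vary = a**2 * u + 2 * a * c + v
        assert cov / np.sqrt(u * vary) == pytest.approx(r, rel=1e-12)


class TestGenerateCohort:
    def test_deterministic_bit_identical(self):
        cfg = SyntheticConfig(n_samples=120, seed=5, **LEAN)
        b1, t1 = generate_cohort(cfg)
        b2, t2 = generate_cohort(cfg)
        assert (b1.mrna.values.to_numpy() == b2.mrna.values.to_numpy()).all()
        assert (b1.mirna.values.to_numpy() == b2.mirna.values.to_numpy()).all()
        assert b1.clinical.table.equals(b2.clinical.table)
        assert t1 == t2

    def test_planted_correlation_close_to_target(self):
        cfg = SyntheticConfig(n_samples=2000, seed=42, **LEAN)
        b, t = generate_cohort(cfg)
        anchor = b.mrna.feature(t.anchor_gene_id)
        for m in t.planted_mirna_ids:
            r = np.corrcoef(anchor, b.mirna.feature(m))[0, 1]
            assert abs(r - cfg.planted_correlation) < 0.06

    def test_mean_correlation_converges(self):
        cfg = SyntheticConfig(n_samples=5000, seed=3, **LEAN)
        b, t = generate_cohort(cfg)
        anchor = b.mrna.feature(t.anchor_gene_id)
        rs = [np.corrcoef(anchor, b.mirna.feature(m))[0, 1] for m in t.planted_mirna_ids]
        assert abs(float(np.mean(rs)) - 0.5) < 0.03

    def test_zero_correlation_zero_shift_independence(self):
        cfg = SyntheticConfig(
            n_samples=3000, seed=9, planted_correlation=0.0, anchor_shift=0.0,
            mirna_shift=0.0, **LEAN
        )
        b, t = generate_cohort(cfg)
        anchor = b.mrna.feature(t.anchor_gene_id)
        for m in t.planted_mirna_ids:
            assert abs(np.corrcoef(anchor, b.mirna.feature(m))[0, 1]) < 0.06

    def test_null_hazard_ratio(self):
        # with true_hr = 1 the aggressive group's pooled event rate matches
        # the rest's across replicates (exponential rate = events / exposure)
        ev_a = tm_a = ev_r = tm_r = 0.0
        for s in range(20):
            cfg = SyntheticConfig(n_samples=400, true_hr=1.0, seed=100 + s, **LEAN)
            b, t = generate_cohort(cfg)
            aggr = b.clinical.table.index.isin(t.aggressive_sample_ids)
            ev = b.clinical.os_event.to_numpy()
            tm = b.clinical.os_time.to_numpy()
            ev_a += ev[aggr].sum()
            tm_a += tm[aggr].sum()
            ev_r += ev[~aggr].sum()
            tm_r += tm[~aggr].sum()
        ratio = (ev_a / tm_a) / (ev_r / tm_r)
        assert abs(np.log(ratio)) < 0.25

    def test_anchor_shifted_at_least_two_log2_units(self):
        cfg = SyntheticConfig(n_samples=600, seed=1, **LEAN)
        b, t = generate_cohort(cfg)
        anchor = b.mrna.feature(t.anchor_gene_id)
        aggr = anchor.index.isin(t.aggressive_sample_ids)
        assert anchor[~aggr].mean() - anchor[aggr].mean() >= 2.0

    def test_marginal_event_rate_calibrated(self):
        # observed event fraction across replicates near 1 - censoring_rate
        rates = []
        for s in range(40):
            cfg = SyntheticConfig(n_samples=300, seed=500 + s, **LEAN)
            b, _ = generate_cohort(cfg)
            rates.append(b.clinical.os_event.mean())
        expect = 1 - 0.4
        se = np.sqrt(expect * (1 - expect) / (300 * 40))
        assert abs(float(np.mean(rates)) - expect) < 3 * se + 0.01

    def test_truth_invariants_and_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_samples=200, seed=2, **LEAN)
        _, t = generate_cohort(cfg)
        assert set(t.aggressive_sample_ids) <= set(t.tnbc_sample_ids)
        t.to_text(tmp_path / "truth.txt")
        assert GroundTruth.from_text(tmp_path / "truth.txt") == t

    def test_infeasible_config_rejected(self):
        with pytest.raises(GenerationError, match="aggressive"):
            SyntheticConfig(n_samples=50, tnbc_fraction=0.1, aggressive_fraction=0.1,
                            **LEAN).validate()

    def test_cna_and_mutations_have_group_structure(self):
        cfg = SyntheticConfig(n_samples=400, seed=8, **LEAN)
        b, t = generate_cohort(cfg)
        aggr = [s for s in b.sample_ids if s in set(t.aggressive_sample_ids)]
        assert set(np.unique(b.cna.to_numpy())) <= {-2, -1, 0, 1, 2}
        # TP53 mutated in every aggressive sample (planted probability 1)
        assert b.mutations.loc["TP53", aggr].all()


class TestDrugSignatures:
    def _profile(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.standard_normal(n) * 3
        return pd.Series(t, index=[f"G{i:03d}" for i in range(n)])

    def test_reversal_anticorrelated_and_null_not(self):
        prof = self._profile()
        sig, truth = generate_drug_signatures(20, _empty_truth(), prof, 3, seed=1)
        assert len(truth.planted_reversal_drug_ids) == 3
        for d in sig.drug_ids:
            r = np.corrcoef(prof, sig.effects[d])[0, 1]
            if d in truth.planted_reversal_drug_ids:
                assert r < -0.9
            else:
                assert abs(r) < 0.5

    def test_zero_noise_exact_sign_flip(self):
        prof = self._profile()
        sig, truth = generate_drug_signatures(5, _empty_truth(), prof, 2, seed=3, noise_sd=0.0)
        for d in truth.planted_reversal_drug_ids:
            np.testing.assert_allclose(sig.effects[d].to_numpy(), -prof.to_numpy())

    def test_no_reversals_is_null(self):
        prof = self._profile()
        sig, truth = generate_drug_signatures(30, _empty_truth(), prof, 0, seed=4)
        assert truth.planted_reversal_drug_ids == ()
        rs = [abs(np.corrcoef(prof, sig.effects[d])[0, 1]) for d in sig.drug_ids]
        assert max(rs) < 0.6

    def test_too_many_reversals_rejected(self):
        with pytest.raises(GenerationError):
            generate_drug_signatures(2, _empty_truth(), self._profile(), 3, seed=0)
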