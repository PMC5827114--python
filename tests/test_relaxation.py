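"""Relaxation forward model, τc estimation and flexibility masking."""

import math

import numpy as np
import pytest

from didomain.relaxation import (
    GAMMA_H,
    GAMMA_N,
    RelaxationRecord,
    compare_domain_tauc,
    domain_tauc,
    flexibility_mask,
    larmor_n_mhz,
    simulate_relaxation,
    tauc_from_t1t2,
)
from didomain.structures import DomainDefinition


def make_records(taucs, field=600.0, noe=0.8, chain="A", start=1):
    records = []
    for i, tc in enumerate(taucs):
        t1, t2, _ = simulate_relaxation(tc, field)
        records.append(RelaxationRecord((chain, start + i), t1, t2, noe, field))
    return records


class TestTaucEstimator:
    def test_closed_form(self):
        # 6 T1/T2 - 7 = 9 at ratio 8/3: tauc = 3 / (4 pi nuN)
        tc = tauc_from_t1t2(8.0, 3.0, 60.8)
        assert tc == pytest.approx(3.0 / (4 * math.pi * 60.8e6) * 1e9, rel=1e-12)

    def test_fast_motion_regime_flagged(self):
        with pytest.warns(UserWarning, match="slow-tumbling"):
            assert math.isnan(tauc_from_t1t2(0.4, 0.4, 60.8))

    @pytest.mark.parametrize("tauc", [11.8, 10.0])
    def test_roundtrip_at_study_conditions(self, tauc):
        t1, t2, _ = simulate_relaxation(tauc, 600.0)
        est = tauc_from_t1t2(t1, t2, larmor_n_mhz(600.0))
        assert est == pytest.approx(tauc, rel=0.02)

    def test_roundtrip_error_profile(self):
        """The T1/T2 estimator is approximate: <2% above ~4 ns at 600 MHz,
        degrading to a few percent toward the fast-tumbling validity edge."""
        for tauc in np.arange(4.0, 25.1, 1.0):
            t1, t2, _ = simulate_relaxation(tauc, 600.0)
            est = tauc_from_t1t2(t1, t2, larmor_n_mhz(600.0))
            assert abs(est - tauc) / tauc < 0.02
        for tauc in (2.0, 3.0):
            t1, t2, _ = simulate_relaxation(tauc, 600.0)
            est = tauc_from_t1t2(t1, t2, larmor_n_mhz(600.0))
            assert abs(est - tauc) / tauc < 0.05

    def test_larmor_ratio(self):
        assert larmor_n_mhz(600.0) == pytest.approx(600.0 * abs(GAMMA_N / GAMMA_H))
        assert larmor_n_mhz(600.0) == pytest.approx(60.8, rel=2e-3)


class TestForwardModel:
    def test_extreme_narrowing_limit(self):
        t1, t2, noe = simulate_relaxation(1e-4, 600.0)
        # T1 ~ T2 up to the small CSA contribution that never fully cancels
        assert t1 == pytest.approx(t2, rel=0.02)
        # 15N steady-state NOE tends to its large negative fast-motion limit
        assert noe < -3.0

    def test_t2_monotone_decreasing_in_tauc(self):
        taucs = np.arange(1.0, 30.1, 0.5)
        t2s = [simulate_relaxation(tc, 600.0)[1] for tc in taucs]
        assert all(b < a for a, b in zip(t2s, t2s[1:]))

    def test_against_independent_reimplementation(self):
        """Textbook dipolar+CSA rates recomputed from scratch agree to 1%."""
        mu0_4pi, hbar, rnh, csa = 1e-7, 1.054571817e-34, 1.02e-10, -160e-6
        for tauc_ns in (5.0, 10.0, 20.0):
            tauc = tauc_ns * 1e-9
            b0 = 600e6 * 2 * math.pi / GAMMA_H
            wh = GAMMA_H * b0
            wn = abs(GAMMA_N) * b0
            jj = lambda w: 0.4 * tauc / (1 + (w * tauc) ** 2)
            d2 = (mu0_4pi * hbar * GAMMA_H * GAMMA_N / rnh**3) ** 2
            c2 = (wn * csa) ** 2 / 3
            r1 = d2 / 4 * (jj(wh - wn) + 3 * jj(wn) + 6 * jj(wh + wn)) + c2 * jj(wn)
            r2 = d2 / 8 * (4 * jj(0) + jj(wh - wn) + 3 * jj(wn) + 6 * jj(wh) + 6 * jj(wh + wn)) + c2 / 6 * (
                4 * jj(0) + 3 * jj(wn)
            )
            noe = 1 + d2 / 4 * (GAMMA_H / GAMMA_N) * (6 * jj(wh + wn) - jj(wh - wn)) / r1
            t1, t2, noe_m = simulate_relaxation(tauc_ns, 600.0)
            assert t1 == pytest.approx(1 / r1, rel=0.01)
            assert t2 == pytest.approx(1 / r2, rel=0.01)
            assert noe_m == pytest.approx(noe, rel=0.01)

    def test_invalid_tauc(self):
        with pytest.raises(ValueError):
            simulate_relaxation(-1.0)


class TestFlexibilityMask:
    def test_threshold(self):
        records = [
            RelaxationRecord(("A", 1), 0.8, 0.06, 0.80),
            RelaxationRecord(("A", 2), 0.8, 0.06, 0.30),
        ]
        assert flexibility_mask(records) == {("A", 1)}

    def test_all_flexible_warns(self):
        records = [RelaxationRecord(("A", i), 0.5, 0.3, 0.1) for i in range(5)]
        with pytest.warns(UserWarning):
            assert flexibility_mask(records) == set()

    def test_simulated_linker_recovery(self):
        """Domain/linker membership recovered >= 95% from noisy hetNOE."""
        correct = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            records = []
            truth = {}
            for i in range(40):
                rigid = i < 30
                noe = rng.normal(0.8 if rigid else 0.3, 0.05)
                records.append(RelaxationRecord(("A", i), 0.8, 0.06, noe))
                truth[("A", i)] = rigid
            mask = flexibility_mask(records)
            for rid, rigid in truth.items():
                correct += (rid in mask) == rigid
                total += 1
        assert correct / total >= 0.95


class TestDomainTauc:
    dom = DomainDefinition("N", "A", ((1, 20),))

    def test_identical_records_zero_spread(self):
        records = make_records([10.0] * 20)
        est = domain_tauc(records, self.dom)
        single = tauc_from_t1t2(records[0].t1_s, records[0].t2_s, larmor_n_mhz(600.0))
        assert est.tauc_ns == pytest.approx(single, rel=1e-9)
        assert est.sd_ns == pytest.approx(0.0, abs=1e-12)

    def test_trimming_absorbs_exchange_outlier(self):
        records = make_records([10.0] * 20)
        outlier = RelaxationRecord(("A", 5), records[4].t1_s, records[4].t2_s / 10, 0.8, 600.0)
        records[4] = outlier
        est = domain_tauc(records, self.dom)
        clean = domain_tauc(make_records([10.0] * 20), self.dom)
        assert est.tauc_ns == pytest.approx(clean.tauc_ns, rel=0.02)

    def test_reordering_invariance(self, rng):
        taucs = rng.uniform(9, 12, 20)
        records = make_records(taucs)
        est1 = domain_tauc(records, self.dom)
        est2 = domain_tauc(records[::-1], self.dom)
        assert est1.tauc_ns == est2.tauc_ns

    def test_too_few_residues(self):
        with pytest.raises(ValueError, match="rigid residues"):
            domain_tauc(make_records([10.0] * 3), self.dom)

    def test_mask_excludes_flexible(self):
        records = make_records([10.0] * 20)
        mask = {r.residue for r in records[:10]}
        est = domain_tauc(records, self.dom, mask=mask)
        assert len(est.residues_used) == 10
        assert len(est.residues_excluded) == 10

    def test_two_domain_difference_significant(self):
        """Simulated 10.0 vs 11.8 ns domains: estimates near truth, p < 0.05."""
        rng = np.random.default_rng(42)
        dom_b = DomainDefinition("eR1", "A", ((21, 40),))
        rec_a, rec_b = [], []
        for i in range(20):
            t1, t2, _ = simulate_relaxation(10.0, 600.0)
            rec_a.append(
                RelaxationRecord(("A", 1 + i), t1 * (1 + rng.normal(0, 0.03)), t2 * (1 + rng.normal(0, 0.03)), 0.8)
            )
            t1, t2, _ = simulate_relaxation(11.8, 600.0)
            rec_b.append(
                RelaxationRecord(("A", 21 + i), t1 * (1 + rng.normal(0, 0.03)), t2 * (1 + rng.normal(0, 0.03)), 0.8)
            )
        est_a = domain_tauc(rec_a, self.dom)
        est_b = domain_tauc(rec_b, dom_b)
        assert est_a.tauc_ns == pytest.approx(10.0, abs=3 * est_a.sd_ns / math.sqrt(len(est_a.residues_used)) + 0.25)
        assert est_b.tauc_ns == pytest.approx(11.8, abs=3 * est_b.sd_ns / math.sqrt(len(est_b.residues_used)) + 0.25)
        cmp = compare_domain_tauc(est_a, est_b)
        assert cmp["p_value"] < 0.05
        assert cmp["delta_tauc_ns"] == pytest.approx(1.8, abs=0.6)
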