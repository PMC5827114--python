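"""Alignment-tensor back-calculation, SVD fitting and model comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from didomain.rdc import (
    AlignmentTensor,
    DegenerateGeometryError,
    RdcRecord,
    back_calculate,
    compare_tensor_models,
    fit_tensor_svd,
    tensor_parameters,
)
from didomain.synthetic import ScenarioSpec, make_toy_didomain, synth_rdc

from conftest import random_unit_vectors


def records_from(couplings, err=None):
    return [RdcRecord(("A", i), float(d), err) for i, d in enumerate(couplings)]


class TestBackCalculate:
    def test_z_axis_gives_twice_da(self):
        tensor = AlignmentTensor.from_parameters(-17.7, 0.22)
        d = back_calculate(np.array([[0.0, 0.0, 1.0]]), tensor)
        assert d[0] == pytest.approx(2 * -17.7, abs=1e-9)

    def test_x_axis_closed_form(self):
        # theta = 90 deg, phi = 0: D = Da * (-1 + 1.5 R)
        tensor = AlignmentTensor.from_parameters(-17.7, 0.22)
        d = back_calculate(np.array([[1.0, 0.0, 0.0]]), tensor)
        assert d[0] == pytest.approx(-17.7 * (-1 + 1.5 * 0.22), abs=1e-9)

    def test_magic_angle_ring_averages_to_zero(self):
        tensor = AlignmentTensor.from_parameters(-17.7, 0.22)
        theta = np.arccos(1.0 / np.sqrt(3.0))
        phi = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        v = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.full_like(phi, np.cos(theta))]
        )
        assert abs(back_calculate(v, tensor).mean()) < 1e-6

    def test_non_unit_vector_rejected(self):
        tensor = AlignmentTensor.from_parameters(-10.0, 0.1)
        with pytest.raises(ValueError):
            back_calculate(np.array([[0.0, 0.0, 2.0]]), tensor)

    def test_saupe_and_angle_parameterisations_agree(self, rng):
        """D(θ,φ) in the principal frame equals the Saupe contraction (1e-9 Hz)."""
        for _ in range(25):
            da = rng.uniform(-30, 30)
            r = rng.uniform(0, 2 / 3)
            rot = Rotation.random(random_state=rng).as_matrix()
            tensor = AlignmentTensor.from_parameters(da, r, rot)
            v = random_unit_vectors(rng, 10)
            # angles of each vector in the principal axis system
            v_pas = v @ rot
            cos_t = v_pas[:, 2]
            phi = np.arctan2(v_pas[:, 1], v_pas[:, 0])
            sin2 = 1 - cos_t**2
            expected = da * ((3 * cos_t**2 - 1) + 1.5 * r * sin2 * np.cos(2 * phi))
            np.testing.assert_allclose(back_calculate(v, tensor), expected, atol=1e-9)


class TestFit:
    def test_noiseless_exact_recovery(self, rng):
        tensor = AlignmentTensor.from_parameters(-18.0, 0.31, Rotation.random(random_state=rng).as_matrix())
        v = random_unit_vectors(rng, 20)
        fit = fit_tensor_svd(v, records_from(back_calculate(v, tensor)))
        np.testing.assert_allclose(fit.tensor.saupe, tensor.saupe, atol=1e-8)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.q_factor < 1e-8

    def test_parallel_vectors_degenerate(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(DegenerateGeometryError):
            fit_tensor_svd(v, records_from(np.ones(10)))

    def test_too_few_records(self, rng):
        v = random_unit_vectors(rng, 4)
        with pytest.raises(ValueError, match="at least 5"):
            fit_tensor_svd(v, records_from(np.ones(4)))

    def test_noisy_recovery_medians(self):
        """Da within 5% and R within 0.05 (medians over 100 seeded replicates)."""
        truth = AlignmentTensor.from_parameters(-18.0, 0.31)
        da_errs, r_errs = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = random_unit_vectors(rng, 40)
            obs = back_calculate(v, truth) + rng.normal(0, 1.0, 40)
            fit = fit_tensor_svd(v, records_from(obs))
            da, r, _ = tensor_parameters(fit.tensor)
            da_errs.append(abs(da - -18.0) / 18.0)
            r_errs.append(abs(r - 0.31))
        assert np.median(da_errs) < 0.05
        assert np.median(r_errs) < 0.05

    def test_weighted_fit_downweights_noisy_records(self, rng):
        truth = AlignmentTensor.from_parameters(-15.0, 0.2)
        v = random_unit_vectors(rng, 40)
        clean = back_calculate(v, truth)
        obs = clean.copy()
        obs[:5] += rng.normal(0, 10.0, 5)  # five wild records, large stated error
        recs = [
            RdcRecord(("A", i), float(d), 10.0 if i < 5 else 0.1) for i, d in enumerate(obs)
        ]
        weighted = fit_tensor_svd(v, recs)
        unweighted = fit_tensor_svd(v, records_from(obs))
        def da_err(f):
            return abs(tensor_parameters(f.tensor)[0] - -15.0)
        assert da_err(weighted) < da_err(unweighted)


class TestTensorParameters:
    def test_axially_symmetric_gives_zero_rhombicity(self):
        tensor = AlignmentTensor.from_parameters(-12.0, 0.0)
        assert tensor_parameters(tensor)[1] == pytest.approx(0.0, abs=1e-12)

    def test_construct_then_decompose_roundtrip(self):
        da, r, _ = tensor_parameters(AlignmentTensor.from_parameters(-17.7, 0.22))
        assert da == pytest.approx(-17.7, abs=1e-12)
        assert r == pytest.approx(0.22, abs=1e-12)

    def test_rotation_invariance(self, rng):
        base = AlignmentTensor.from_parameters(-17.7, 0.22)
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            rotated = AlignmentTensor(rot @ base.saupe @ rot.T)
            da, r, _ = tensor_parameters(rotated)
            assert da == pytest.approx(-17.7, rel=1e-9)
            assert r == pytest.approx(0.22, abs=1e-9)

    def test_rhombicity_in_range_for_random_tensors(self, rng):
        for _ in range(50):
            s = rng.normal(size=(3, 3))
            s = s + s.T
            s -= np.eye(3) * np.trace(s) / 3
            _, r, _ = tensor_parameters(AlignmentTensor(s))
            assert 0.0 <= r <= 2.0 / 3.0 + 1e-12


class TestModelComparison:
    def test_rigid_noiseless_models_agree(self, toy):
        model, dom_a, dom_b = toy
        import dataclasses

        spec = dataclasses.replace(ScenarioSpec.preset("rigid", 0), rdc_noise_hz=0.0)
        rdcs = synth_rdc(model, spec, dom_a, dom_b)
        cmp = compare_tensor_models(model, (dom_a, dom_b), rdcs)
        assert cmp["r_single"] == pytest.approx(1.0, abs=1e-6)
        assert cmp["r_multi"] == pytest.approx(1.0, abs=1e-6)

    def test_decoupled_scenario_separates_models(self, toy):
        model, dom_a, dom_b = toy
        spec = ScenarioSpec.preset("dynamic", 3)
        cmp = compare_tensor_models(model, (dom_a, dom_b), synth_rdc(model, spec, dom_a, dom_b))
        assert cmp["r_multi"] > 0.95
        assert cmp["r_single"] < 0.7

    def test_single_fit_independent_of_partition(self, toy):
        """The joint one-tensor fit must not depend on the domain split."""
        model, dom_a, dom_b = toy
        spec = ScenarioSpec.preset("dynamic", 5)
        rdcs = synth_rdc(model, spec, dom_a, dom_b)
        cmp1 = compare_tensor_models(model, (dom_a, dom_b), rdcs)
        cmp2 = compare_tensor_models(model, (dom_b, dom_a), rdcs)
        assert cmp1["r_single"] == pytest.approx(cmp2["r_single"], abs=1e-12)

    def test_multi_never_worse_than_single(self, toy):
        for scenario in ("rigid", "dynamic"):
            for seed in (0, 1, 2, 3, 4):
                model, dom_a, dom_b = toy
                spec = ScenarioSpec.preset(scenario, seed)
                cmp = compare_tensor_models(
                    model, (dom_a, dom_b), synth_rdc(model, spec, dom_a, dom_b)
                )
                assert cmp["r_multi"] >= cmp["r_single"] - 1e-9

    def test_insufficient_domain_records_error(self, toy):
        model, dom_a, dom_b = toy
        spec = ScenarioSpec.preset("dynamic", 0)
        rdcs = [r for r in synth_rdc(model, spec, dom_a, dom_b) if not dom_b.contains(*r.residue)]
        with pytest.raises(ValueError, match="eR1"):
            compare_tensor_models(model, (dom_a, dom_b), rdcs)
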