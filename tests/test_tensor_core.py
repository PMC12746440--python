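"""Transformation group, origin shifts, and the tensor file format."""

import json

import numpy as np
import pytest

from rayoa import (FixtureSpec, MolecularTensorSet, SpatialTransform,
                   compute_invariants, enantiomer, make_tensor_set,
                   random_rotation, read_tensor_set, shift_origin,
                   transform_tensors, write_tensor_set)
from rayoa.tensor_core import (InvalidTransformError, TensorValidationError,
                               tensor_set_from_dict, tensor_set_to_dict)

from conftest import transform_oracle


class TestSpatialTransform:
    def test_rejects_non_orthogonal_matrix(self):
        with pytest.raises(InvalidTransformError):
            SpatialTransform(np.array([[1, 0.1, 0], [0, 1, 0], [0, 0, 1.0]]))

    def test_determinant_classification(self, rng):
        assert SpatialTransform.identity().is_proper
        assert not SpatialTransform.inversion().is_proper
        assert SpatialTransform.reflection([0, 0, 1]).determinant == -1.0
        assert random_rotation(rng).determinant == 1.0

    def test_group_closure(self, rng):
        g1, g2 = random_rotation(rng), random_rotation(rng)
        composed = g1.compose(g2)
        np.testing.assert_allclose(composed.matrix, g1.matrix @ g2.matrix,
                                   atol=1e-12)

    def test_inverse_recovers_input(self, chiral_set, rng):
        g = random_rotation(rng)
        back = transform_tensors(transform_tensors(chiral_set, g), g.inverse())
        np.testing.assert_allclose(back.alpha, chiral_set.alpha, atol=1e-12)
        np.testing.assert_allclose(back.gprime, chiral_set.gprime, atol=1e-12)
        np.testing.assert_allclose(back.aquad, chiral_set.aquad, atol=1e-12)


class TestTransformTensors:
    def test_identity_is_noop(self, chiral_set):
        out = transform_tensors(chiral_set, SpatialTransform.identity())
        np.testing.assert_array_equal(out.alpha, chiral_set.alpha)
        np.testing.assert_array_equal(out.gprime, chiral_set.gprime)
        np.testing.assert_array_equal(out.aquad, chiral_set.aquad)
        assert out.omega == chiral_set.omega

    def test_inversion_realizes_parity(self, chiral_set):
        """Under inversion alpha is even, G' is even-times-det (flips), and
        the polar rank-3 A flips: the enantiomer map."""
        out = enantiomer(chiral_set)
        np.testing.assert_allclose(out.alpha, chiral_set.alpha, atol=1e-14)
        np.testing.assert_allclose(out.gprime, -chiral_set.gprime, atol=1e-14)
        np.testing.assert_allclose(out.aquad, -chiral_set.aquad, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_componentwise_loop_oracle(self, seed):
        t = make_tensor_set(FixtureSpec(seed=seed))
        rng = np.random.default_rng(100 + seed)
        g = random_rotation(rng)
        if seed % 2:  # exercise the improper branch too
            g = g.compose(SpatialTransform.inversion())
        out = transform_tensors(t, g)
        a_ref, g_ref, q_ref = transform_oracle(t.alpha, t.gprime, t.aquad,
                                               g.matrix)
        np.testing.assert_allclose(out.alpha, a_ref, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(out.gprime, g_ref, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(out.aquad, q_ref, rtol=1e-12, atol=1e-12)

    def test_group_composition_acts_consistently(self, chiral_set, rng):
        g1, g2 = random_rotation(rng), random_rotation(rng)
        via_compose = transform_tensors(chiral_set, g1.compose(g2))
        via_steps = transform_tensors(transform_tensors(chiral_set, g2), g1)
        np.testing.assert_allclose(via_compose.aquad, via_steps.aquad,
                                   rtol=1e-12, atol=1e-12)


class TestShiftOrigin:
    def test_zero_shift_is_noop(self, chiral_set):
        out = shift_origin(chiral_set, np.zeros(3))
        np.testing.assert_array_equal(out.gprime, chiral_set.gprime)
        np.testing.assert_array_equal(out.aquad, chiral_set.aquad)

    @pytest.mark.parametrize("seed", range(5))
    def test_optical_activity_invariants_origin_independent(self, seed):
        """beta(G')^2 and beta(A)^2 must not depend on the multipole origin
        when alpha is symmetric."""
        t = make_tensor_set(FixtureSpec(seed=seed))
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)  # magnitude 1 a.u.
        before = compute_invariants(t)
        after = compute_invariants(shift_origin(t, d))
        assert after.betaG2 == pytest.approx(before.betaG2, rel=1e-9)
        assert after.betaA2 == pytest.approx(before.betaA2, rel=1e-9)

    def test_shifted_set_still_satisfies_structure(self, chiral_set):
        # translation must keep A symmetric-traceless in the quadrupole pair
        out = shift_origin(chiral_set, [3.0, -1.0, 0.5])
        assert isinstance(out, MolecularTensorSet)

    def test_asymmetric_alpha_rejected(self, chiral_set):
        bad_alpha = chiral_set.alpha.copy()
        bad_alpha[0, 1] += 1.0
        bad = MolecularTensorSet(alpha=bad_alpha, gprime=chiral_set.gprime,
                                 aquad=chiral_set.aquad,
                                 wavelength_nm=chiral_set.wavelength_nm,
                                 sym_tol=1.0)
        with pytest.raises(TensorValidationError):
            shift_origin(bad, [1.0, 0.0, 0.0])


class TestValidation:
    def test_rejects_asymmetric_alpha(self, chiral_set):
        bad = chiral_set.alpha.copy()
        bad[0, 1] += 10.0
        with pytest.raises(TensorValidationError, match="asymmetric"):
            MolecularTensorSet(alpha=bad, gprime=chiral_set.gprime,
                               aquad=chiral_set.aquad, wavelength_nm=532.0)

    def test_rejects_non_traceless_aquad(self, chiral_set):
        bad = chiral_set.aquad.copy()
        bad[1, 0, 0] += 10.0
        bad[1, 1, 1] += 10.0
        bad[1, 2, 2] += 10.0
        with pytest.raises(TensorValidationError, match="traceless"):
            MolecularTensorSet(alpha=chiral_set.alpha,
                               gprime=chiral_set.gprime, aquad=bad,
                               wavelength_nm=532.0)

    def test_rejects_inconsistent_omega(self, chiral_set):
        with pytest.raises(TensorValidationError, match="omega"):
            MolecularTensorSet(alpha=chiral_set.alpha,
                               gprime=chiral_set.gprime,
                               aquad=chiral_set.aquad,
                               wavelength_nm=532.0, omega=1.0)


class TestTensorFile:
    def test_round_trip_is_bit_faithful(self, chiral_set, tmp_path):
        path = tmp_path / "t.json"
        write_tensor_set(chiral_set, path)
        back = read_tensor_set(path)
        np.testing.assert_array_equal(back.alpha, chiral_set.alpha)
        np.testing.assert_array_equal(back.gprime, chiral_set.gprime)
        np.testing.assert_array_equal(back.aquad, chiral_set.aquad)
        assert back.wavelength_nm == chiral_set.wavelength_nm
        assert back.label == chiral_set.label

    def test_gprime_sign_switch_flips_gprime_only(self, chiral_set):
        doc = tensor_set_to_dict(chiral_set)
        flipped = tensor_set_from_dict(doc, gprime_sign=-1)
        np.testing.assert_array_equal(flipped.gprime, -chiral_set.gprime)
        np.testing.assert_array_equal(flipped.alpha, chiral_set.alpha)

    def test_wrong_units_rejected(self, chiral_set):
        doc = tensor_set_to_dict(chiral_set)
        doc["units"] = "SI"
        with pytest.raises(TensorValidationError, match="units"):
            tensor_set_from_dict(doc)

    def test_loader_projects_noisy_quadrupole(self, chiral_set, caplog):
        doc = tensor_set_to_dict(chiral_set)
        noisy = np.array(doc["aquad"]).reshape(3, 3, 3)
        noisy[0, 1, 2] += 0.1 * np.abs(noisy).max()
        doc["aquad"] = noisy.ravel().tolist()
        with caplog.at_level("WARNING", logger="rayoa.tensor_core"):
            t = tensor_set_from_dict(doc)
        assert "projecting A" in caplog.text
        # the loaded tensor satisfies the structural invariants exactly
        np.testing.assert_allclose(t.aquad, t.aquad.transpose(0, 2, 1),
                                   atol=1e-12)
        np.testing.assert_allclose(np.einsum("ijj->i", t.aquad), 0, atol=1e-10)

    def test_file_is_plain_json_with_spec_keys(self, chiral_set, tmp_path):
        path = tmp_path / "t.json"
        write_tensor_set(chiral_set, path)
        doc = json.loads(path.read_text())
        assert set(doc) == {"wavelength_nm", "alpha", "gprime", "aquad",
                            "units", "label"}
        assert len(doc["alpha"]) == 9 and len(doc["aquad"]) == 27
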