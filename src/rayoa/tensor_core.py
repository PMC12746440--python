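"""Molecular property tensors and their exact spatial transformation group.

The observable computed downstream is built from three property tensors of a
chiral molecule, all stored in Hartree atomic units:

* ``alpha`` — the electric dipole–electric dipole polarizability, a symmetric
  3x3 polar tensor (symmetric because the light is far off resonance);
* ``gprime`` — the electric dipole–magnetic dipole optical activity tensor
  G', a 3x3 *axial* tensor (it picks up a det(R) factor under improper
  operations, which is what makes it chirally sensitive);
* ``aquad`` — the electric dipole–electric quadrupole tensor A, a rank-3
  polar tensor, symmetric and traceless in its quadrupole index pair.

This module owns the data model, the orthogonal-transformation rules
(including the improper branch that maps a molecule onto its enantiomer),
the origin-translation rules used as a test oracle, and the plain-JSON
tensor-file format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import omega_from_wavelength_nm

logger = logging.getLogger(__name__)

#: Default relative (Frobenius) tolerance for the symmetry invariants of
#: quantum-chemistry tensor output.
SYM_TOL = 1e-6

#: Rank-3 antisymmetric (Levi-Civita) symbol.
LEVI_CIVITA = np.zeros((3, 3, 3))
for _i, _j, _k, _s in [(0, 1, 2, 1), (1, 2, 0, 1), (2, 0, 1, 1),
                       (0, 2, 1, -1), (2, 1, 0, -1), (1, 0, 2, -1)]:
    LEVI_CIVITA[_i, _j, _k] = _s


class TensorValidationError(ValueError):
    """A tensor set violates a structural invariant beyond tolerance."""


class InvalidTransformError(ValueError):
    """A spatial transform matrix is not orthogonal (or has |det| != 1)."""


def _rel_norm(deviation: np.ndarray, reference: np.ndarray) -> float:
    ref = np.linalg.norm(reference)
    if ref == 0.0:
        return float(np.linalg.norm(deviation))
    return float(np.linalg.norm(deviation) / ref)


def project_aquad(aquad: np.ndarray) -> np.ndarray:
    """Project A onto the symmetric-traceless subspace of its last two indices.

    Quadrupole operators are conventionally symmetric and traceless; different
    electronic-structure programs print different reduced forms, so loaded
    tensors are projected rather than rejected.
    """
    sym = 0.5 * (aquad + aquad.transpose(0, 2, 1))
    trace = np.einsum("ijj->i", sym)
    return sym - trace[:, None, None] * np.eye(3)[None, :, :] / 3.0


@dataclass(frozen=True)
class MolecularTensorSet:
    """Property tensors of one molecule at one incident frequency (a.u.)."""

    alpha: np.ndarray
    gprime: np.ndarray
    aquad: np.ndarray
    wavelength_nm: float
    omega: float = 0.0  # derived from wavelength_nm when left at 0
    label: str = ""
    sym_tol: float = SYM_TOL

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "gprime", np.asarray(self.gprime, dtype=float))
        object.__setattr__(self, "aquad", np.asarray(self.aquad, dtype=float))
        if self.alpha.shape != (3, 3) or self.gprime.shape != (3, 3):
            raise TensorValidationError("alpha and gprime must be 3x3")
        if self.aquad.shape != (3, 3, 3):
            raise TensorValidationError("aquad must be 3x3x3")
        if self.omega == 0.0:
            object.__setattr__(
                self, "omega", omega_from_wavelength_nm(self.wavelength_nm))
        expected = omega_from_wavelength_nm(self.wavelength_nm)
        if not np.isclose(self.omega, expected, rtol=1e-9):
            raise TensorValidationError(
                f"omega={self.omega} inconsistent with "
                f"wavelength {self.wavelength_nm} nm (expected {expected})")
        self._check_symmetry()

    def _check_symmetry(self):
        dev_alpha = _rel_norm(self.alpha - self.alpha.T, self.alpha)
        if dev_alpha > self.sym_tol:
            raise TensorValidationError(
                f"alpha asymmetric: relative deviation {dev_alpha:.3e} "
                f"> sym_tol {self.sym_tol:.0e}")
        dev_sym = _rel_norm(self.aquad - self.aquad.transpose(0, 2, 1), self.aquad)
        if dev_sym > self.sym_tol:
            raise TensorValidationError(
                f"aquad not symmetric in quadrupole indices: {dev_sym:.3e}")
        trace = np.einsum("ijj->i", self.aquad)
        dev_tr = _rel_norm(trace, self.aquad)
        if dev_tr > self.sym_tol:
            raise TensorValidationError(
                f"aquad not traceless over quadrupole indices: {dev_tr:.3e}")

    def alpha_is_symmetric(self, tol: float | None = None) -> bool:
        return _rel_norm(self.alpha - self.alpha.T, self.alpha) <= (
            tol if tol is not None else self.sym_tol)


@dataclass(frozen=True)
class SpatialTransform:
    """A proper or improper orthogonal operation on 3-space.

    Improper operations (det = -1: reflections, inversion, rotoreflections)
    map a chiral molecule onto its enantiomer.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise InvalidTransformError("transform matrix must be 3x3")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-12):
            raise InvalidTransformError("transform matrix is not orthogonal")
        det = float(np.linalg.det(m))
        if not (abs(det - 1.0) < 1e-12 or abs(det + 1.0) < 1e-12):
            raise InvalidTransformError(f"determinant {det} not +/-1")

    @property
    def determinant(self) -> float:
        return 1.0 if np.linalg.det(self.matrix) > 0 else -1.0

    @property
    def is_proper(self) -> bool:
        return self.determinant > 0

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(np.eye(3))

    @classmethod
    def inversion(cls) -> "SpatialTransform":
        return cls(-np.eye(3))

    @classmethod
    def reflection(cls, normal) -> "SpatialTransform":
        """Mirror plane with the given (non-zero) normal vector."""
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        return cls(np.eye(3) - 2.0 * np.outer(n, n))

    def compose(self, other: "SpatialTransform") -> "SpatialTransform":
        """The operation 'self after other' (matrix product)."""
        return SpatialTransform(self.matrix @ other.matrix)

    def inverse(self) -> "SpatialTransform":
        return SpatialTransform(self.matrix.T)


def transform_tensors(t: MolecularTensorSet, g: SpatialTransform) -> MolecularTensorSet:
    """Apply an orthogonal operation R to all property tensors.

    alpha and A transform as polar tensors of rank 2 and 3; G' transforms as
    an axial rank-2 tensor and picks up the det(R) pseudoscalar factor::

        alpha'_ij = R_ia R_jb alpha_ab
        G''_ij    = det(R) R_ia R_jb G'_ab
        A'_ijk    = R_ia R_jb R_kc A_abc

    For improper g this realizes the enantiomer map: the downstream
    chirality-sensitive invariants (and Delta) flip sign exactly.
    """
    r = g.matrix
    alpha = np.einsum("ia,jb,ab->ij", r, r, t.alpha)
    gprime = g.determinant * np.einsum("ia,jb,ab->ij", r, r, t.gprime)
    aquad = np.einsum("ia,jb,kc,abc->ijk", r, r, r, t.aquad)
    return replace(t, alpha=alpha, gprime=gprime, aquad=aquad)


def enantiomer(t: MolecularTensorSet) -> MolecularTensorSet:
    """The mirror-image molecule (tensors under spatial inversion)."""
    return transform_tensors(t, SpatialTransform.inversion())


def shift_origin(t: MolecularTensorSet, displacement) -> MolecularTensorSet:
    """Translate the multipole origin by ``displacement`` (Bohr).

    The literature translation rules for a shift of origin O -> O + d are::

        alpha unchanged
        G'_ij -> G'_ij - (omega/2) eps_jkl d_k alpha_il
        A_ijk -> A_ijk - (3/2) d_j alpha_ik - (3/2) d_k alpha_ij
                       + d_l alpha_il delta_jk

    For a *symmetric* alpha the changes are annihilated by the contractions
    that build beta(G')^2 and beta(A)^2, so both invariants are origin
    independent — the property this function exists to let tests verify.

    Raises
    ------
    TensorValidationError
        If alpha is asymmetric beyond ``t.sym_tol`` (the cancellation above
        requires symmetric alpha, so the precondition is enforced strictly).
    """
    d = np.asarray(displacement, dtype=float)
    if d.shape != (3,):
        raise ValueError("displacement must be a 3-vector")
    if not t.alpha_is_symmetric(tol=SYM_TOL):  # strict: cancellation needs it
        raise TensorValidationError(
            "shift_origin requires a symmetric alpha: origin independence "
            "of the optical activity invariants holds only in that case")
    gprime = t.gprime - 0.5 * t.omega * np.einsum(
        "jkl,k,il->ij", LEVI_CIVITA, d, t.alpha)
    aquad = (t.aquad
             - 1.5 * np.einsum("j,ik->ijk", d, t.alpha)
             - 1.5 * np.einsum("k,ij->ijk", d, t.alpha)
             + np.einsum("l,il,jk->ijk", d, t.alpha, np.eye(3)))
    return replace(t, gprime=gprime, aquad=aquad)


# ---------------------------------------------------------------------------
# Tensor file format (plain JSON, row-major flattening, atomic units)
# ---------------------------------------------------------------------------

def tensor_set_to_dict(t: MolecularTensorSet) -> dict:
    return {
        "wavelength_nm": t.wavelength_nm,
        "alpha": t.alpha.ravel().tolist(),
        "gprime": t.gprime.ravel().tolist(),
        "aquad": t.aquad.ravel().tolist(),
        "units": "au",
        "label": t.label,
    }


def tensor_set_from_dict(doc: dict, gprime_sign: float = 1.0,
                         sym_tol: float = SYM_TOL) -> MolecularTensorSet:
    """Build a tensor set from the JSON document form.

    ``gprime_sign`` (+1 or -1) accommodates electronic-structure programs
    whose G' sign convention is opposite to the one used here; a wrong global
    sign would silently flip every predicted Delta.

    Tensors violating the structural invariants within reason are projected
    (alpha symmetrized; A symmetrized and detraced in the quadrupole pair)
    with a logged report of the projection magnitude.
    """
    if doc.get("units") != "au":
        raise TensorValidationError(
            f"tensor file units must be 'au', got {doc.get('units')!r}")
    if gprime_sign not in (+1, -1, +1.0, -1.0):
        raise ValueError("gprime_sign must be +1 or -1")
    alpha = np.array(doc["alpha"], dtype=float).reshape(3, 3)
    gprime = gprime_sign * np.array(doc["gprime"], dtype=float).reshape(3, 3)
    aquad = np.array(doc["aquad"], dtype=float).reshape(3, 3, 3)

    # project only above the float noise floor so that clean files
    # round-trip bit-for-bit
    dev = _rel_norm(alpha - alpha.T, alpha)
    if dev > 1e-14:
        if dev > sym_tol:
            logger.warning("symmetrizing alpha: relative asymmetry %.3e", dev)
        alpha = 0.5 * (alpha + alpha.T)
    proj = project_aquad(aquad)
    dev_a = _rel_norm(aquad - proj, aquad)
    if dev_a <= 1e-14:
        proj = aquad
    elif dev_a > sym_tol:
        logger.warning(
            "projecting A onto symmetric-traceless quadrupole form: "
            "relative projection magnitude %.3e", dev_a)
    return MolecularTensorSet(
        alpha=alpha, gprime=gprime, aquad=proj,
        wavelength_nm=float(doc["wavelength_nm"]),
        label=str(doc.get("label", "")), sym_tol=sym_tol)


def write_tensor_set(t: MolecularTensorSet, path) -> None:
    """Write the JSON tensor file (floats at full 17-significant-digit repr)."""
    with open(path, "w") as fh:
        json.dump(tensor_set_to_dict(t), fh, indent=1)
        fh.write("\n")


def read_tensor_set(path, gprime_sign: float = 1.0,
                    sym_tol: float = SYM_TOL) -> MolecularTensorSet:
    with open(path) as fh:
        return tensor_set_from_dict(json.load(fh), gprime_sign=gprime_sign,
                                    sym_tol=sym_tol)
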