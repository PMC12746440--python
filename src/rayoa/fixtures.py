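"""Synthetic molecular tensor sets for testing and demonstration.

No electronic-structure engine is needed anywhere in this package's tests:
this module draws random tensor sets with the exact structural properties of
real molecular data — a symmetric positive-definite polarizability, an
arbitrary G', a symmetric-traceless quadrupole tensor A — and with the
chirality class imposed by construction:

``chiral``
    generic tensors with G' and A scaled so the circular intensity
    differential lands in the 1e-4 to 1e-3 range typical of small chiral
    molecules (or exactly on a requested ``target_delta``);
``achiral-mirror``
    tensors constrained to commute with the reflection z -> -z, which forces
    the pseudoscalar invariants (and Delta) to vanish identically;
``isotropic``
    alpha proportional to the identity with G' = A = 0 (degenerate case:
    no depolarized scattering at all).

Everything is deterministic in the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cid import predict_from_tensors
from .tensor_core import (MolecularTensorSet, SpatialTransform, enantiomer,
                          project_aquad)

CHIRALITIES = ("chiral", "achiral-mirror", "isotropic")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic tensor set."""

    seed: int = 0
    target_delta: Optional[float] = None
    chirality: str = "chiral"
    scale: float = 100.0          #: magnitude of alpha entries (a.u.)
    wavelength_nm: float = 532.0

    def __post_init__(self):
        if self.chirality not in CHIRALITIES:
            raise ValueError(f"chirality must be one of {CHIRALITIES}")
        if self.target_delta is not None and not abs(self.target_delta) < 1:
            raise ValueError("|target_delta| must be < 1")
        if self.scale <= 0 or self.wavelength_nm <= 0:
            raise ValueError("scale and wavelength must be positive")


def random_rotation(rng: np.random.Generator) -> SpatialTransform:
    """A Haar-ish random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return SpatialTransform(q)


def _random_spd(rng: np.random.Generator, scale: float) -> np.ndarray:
    """Random symmetric positive-definite 3x3 with entries of order scale."""
    m = rng.normal(size=(3, 3))
    sym = 0.5 * (m + m.T)
    # shift spectrum well above zero so alpha is safely positive definite
    lo = np.linalg.eigvalsh(sym)[0]
    return scale * (sym + (abs(lo) + 1.0) * np.eye(3)) / 2.0


def make_tensor_set(spec: FixtureSpec) -> MolecularTensorSet:
    """Draw one tensor set of the requested chirality class."""
    rng = np.random.default_rng(spec.seed)
    label = f"fixture-{spec.chirality}-seed{spec.seed}"

    if spec.chirality == "isotropic":
        if spec.target_delta is not None:
            raise ValueError("target_delta is meaningless for an isotropic "
                             "scatterer (Delta undefined)")
        return MolecularTensorSet(
            alpha=spec.scale * np.eye(3), gprime=np.zeros((3, 3)),
            aquad=np.zeros((3, 3, 3)), wavelength_nm=spec.wavelength_nm,
            label=label)

    if spec.chirality == "achiral-mirror":
        if spec.target_delta is not None:
            raise ValueError("target_delta cannot be imposed on an achiral "
                             "tensor set (Delta is identically zero)")
        return _make_mirror_symmetric(rng, spec, label)

    # chiral: generic draw, then scale the optical activity tensors to a
    # physically representative Delta magnitude (or the exact target)
    alpha = _random_spd(rng, spec.scale)
    gprime = spec.scale * rng.normal(size=(3, 3))
    aquad = project_aquad(spec.scale * rng.normal(size=(3, 3, 3)))
    t = MolecularTensorSet(alpha=alpha, gprime=gprime, aquad=aquad,
                           wavelength_nm=spec.wavelength_nm, label=label)
    delta0 = predict_from_tensors(t).delta
    if spec.target_delta is not None:
        target = spec.target_delta
    else:
        magnitude = 10.0 ** rng.uniform(-4.0, -3.0)
        target = np.copysign(magnitude, delta0)
    factor = target / delta0  # Delta is exactly linear in (G', A) jointly
    return MolecularTensorSet(
        alpha=alpha, gprime=factor * gprime, aquad=factor * aquad,
        wavelength_nm=spec.wavelength_nm, label=label)


def _make_mirror_symmetric(rng: np.random.Generator, spec: FixtureSpec,
                           label: str) -> MolecularTensorSet:
    """Tensors invariant under the reflection sigma_z: z -> -z.

    Invariance under any improper operation makes the molecule achiral, so
    beta(G')^2 = beta(A)^2 = 0 by symmetry. Componentwise, sigma_z-invariance
    requires: alpha_xz = alpha_yz = 0; G' non-zero only where exactly one
    index is z (the axial det factor flips the parity rule); A non-zero only
    where an even number of indices are z.
    """
    alpha = _random_spd(rng, spec.scale)
    alpha[0, 2] = alpha[2, 0] = 0.0
    alpha[1, 2] = alpha[2, 1] = 0.0

    gprime = np.zeros((3, 3))
    for i, j in [(0, 2), (2, 0), (1, 2), (2, 1)]:
        gprime[i, j] = spec.scale * rng.normal()

    aquad = np.zeros((3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                if (int(i == 2) + int(j == 2) + int(k == 2)) % 2 == 0:
                    aquad[i, j, k] = spec.scale * rng.normal()
    aquad = project_aquad(aquad)  # projection preserves sigma_z-invariance
    return MolecularTensorSet(alpha=alpha, gprime=gprime, aquad=aquad,
                              wavelength_nm=spec.wavelength_nm, label=label)


def make_enantiomer_pair(spec: FixtureSpec) -> tuple[MolecularTensorSet,
                                                     MolecularTensorSet]:
    """A chiral tensor set and its mirror image (exact opposite Delta)."""
    if spec.chirality != "chiral":
        raise ValueError("enantiomer pairs exist only for chiral fixtures")
    t = make_tensor_set(spec)
    return t, enantiomer(t)
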