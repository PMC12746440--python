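"""Rotational invariants of the Rayleigh optical activity tensors.

The three anisotropy invariants used by the 90-degree depolarized circular
intensity differential are, in Hartree atomic units,

    beta^2      = (1/2) (3 alpha_ij alpha_ij - alpha_ii alpha_jj)
    beta(G')^2  = (1/2) (3 alpha_ij G'_ij   - alpha_ii G'_jj)
    beta(A)^2   = (omega/2) alpha_ij eps_ikl A_klj

with eps the rank-3 antisymmetric symbol and omega the angular frequency of
the incident light. These formulas ARE the contract of this module.

The explicit omega factor is placed inside beta(A)^2 so that beta(G')^2 and
beta(A)^2 carry identical units (alpha * G' in a.u.) and enter the circular
intensity differential on an equal footing through a single 1/c prefactor.

beta^2 is a true scalar (even under improper operations); beta(G')^2 and
beta(A)^2 are pseudoscalars — they flip sign between enantiomers and vanish
identically for any achiral tensor set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_core import LEVI_CIVITA, MolecularTensorSet


class InvalidFrequencyError(ValueError):
    """Angular frequency must be positive to evaluate beta(A)^2."""


@dataclass(frozen=True)
class InvariantSet:
    """The rotational invariants of one tensor set at one frequency (a.u.)."""

    beta2: float        #: polarizability anisotropy, >= 0
    betaG2: float       #: alpha/G' optical activity anisotropy (pseudoscalar)
    betaA2: float       #: alpha/A optical activity anisotropy (pseudoscalar)
    alpha_iso: float    #: mean polarizability (1/3) tr alpha, diagnostic only
    omega: float        #: angular frequency of evaluation
    label: str = ""


def beta2(t: MolecularTensorSet) -> float:
    """Polarizability anisotropy beta^2 = (1/2)(3 a_ij a_ij - a_ii a_jj).

    Evaluated in the algebraically identical sum-of-squares form

        (1/2) sum_{i<j} (a_ii - a_jj)^2 + 3 sum_{i<j} s_ij^2 + 3 sum_{i<j} w_ij^2

    (s, w the symmetric and antisymmetric off-diagonal parts), which is
    manifestly non-negative and immune to the catastrophic cancellation the
    raw double contraction suffers for near-isotropic alpha; it is exactly
    zero iff alpha is isotropic.
    """
    a = t.alpha
    d = np.diag(a)
    diag_term = 0.5 * ((d[0] - d[1]) ** 2 + (d[1] - d[2]) ** 2
                       + (d[2] - d[0]) ** 2)
    s = 0.5 * (a + a.T)
    w = 0.5 * (a - a.T)
    iu = np.triu_indices(3, k=1)
    return float(diag_term + 3.0 * np.sum(s[iu] ** 2) + 3.0 * np.sum(w[iu] ** 2))


def betaG2(t: MolecularTensorSet) -> float:
    """alpha/G' anisotropy beta(G')^2 = (1/2)(3 a_ij G'_ij - a_ii G'_jj)."""
    a, g = t.alpha, t.gprime
    return 0.5 * (3.0 * float(np.einsum("ij,ij->", a, g))
                  - float(np.trace(a)) * float(np.trace(g)))


def betaA2(t: MolecularTensorSet) -> float:
    """alpha/A anisotropy beta(A)^2 = (omega/2) a_ij eps_ikl A_klj."""
    if t.omega <= 0:
        raise InvalidFrequencyError(f"omega must be > 0, got {t.omega}")
    return 0.5 * t.omega * float(
        np.einsum("ij,ikl,klj->", t.alpha, LEVI_CIVITA, t.aquad))


def compute_invariants(t: MolecularTensorSet) -> InvariantSet:
    """Bundle the three anisotropy invariants plus the mean polarizability."""
    return InvariantSet(
        beta2=beta2(t),
        betaG2=betaG2(t),
        betaA2=betaA2(t),
        alpha_iso=float(np.trace(t.alpha)) / 3.0,
        omega=t.omega,
        label=t.label,
    )
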