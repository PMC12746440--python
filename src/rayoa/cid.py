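"""The scattered-circular-polarization circular intensity differential (CID).

For right-angle Rayleigh scattering in the depolarized geometry (incident
light linearly polarized in the scattering plane), the degree of circular
polarization of the scattered light from an isotropic sample of chiral
molecules far off resonance is

    Delta = (1/c) * (24 beta(G')^2 - 8 beta(A)^2) / (12 beta^2)

with c the speed of light in atomic units and the invariants from
:mod:`rayoa.invariants`. Delta is dimensionless, of order 1e-4 for typical
small chiral molecules, and has equal magnitude but opposite sign for the
two enantiomers. Far off resonance, Delta varies with wavelength simply as
Delta ~ 1/lambda, so a prediction at one wavelength can be rescaled to
another.

The minus sign in front of 8 beta(A)^2 is part of this module's contract;
some literature tabulations of the depolarized CID write the quadrupole term
with the opposite sign (convention differences in A absorb the discrepancy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .constants import C_AU, wavelength_nm_from_omega
from .invariants import InvariantSet, compute_invariants
from .tensor_core import MolecularTensorSet

logger = logging.getLogger(__name__)

#: The single scattering geometry supported: scattered circular polarization
#: at 90 degrees with depolarized (in-plane) incident linear polarization.
GEOMETRY_SCP90 = "SCP-90-depolarized"


class DegenerateMoleculeError(ValueError):
    """beta^2 = 0 (isotropic scatterer): the depolarized CID is undefined."""


class EnsembleMismatchError(ValueError):
    """Predictions to be aggregated differ in wavelength or geometry."""


@dataclass(frozen=True)
class CidPrediction:
    """A single predicted circular intensity differential."""

    delta: float
    wavelength_nm: float
    geometry: str = GEOMETRY_SCP90
    method_label: str = ""

    def __post_init__(self):
        if not abs(self.delta) <= 1.0:
            raise ValueError(
                f"|Delta| must be <= 1 (normalized intensity difference), "
                f"got {self.delta}")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.geometry != GEOMETRY_SCP90:
            raise ValueError(f"unsupported geometry {self.geometry!r}")


@dataclass(frozen=True)
class PredictionEnsemble:
    """Predictions from several electronic-structure methods, one wavelength."""

    predictions: tuple
    delta_min: float
    delta_max: float
    delta_mean: float

    @property
    def wavelength_nm(self) -> float:
        return self.predictions[0].wavelength_nm

    @property
    def signs_consistent(self) -> bool:
        """True when every member predicts the same (non-zero) sign."""
        signs = {math.copysign(1.0, p.delta) for p in self.predictions
                 if p.delta != 0.0}
        return len(signs) == 1


def delta_scp90(inv: InvariantSet) -> CidPrediction:
    """Evaluate the depolarized 90-degree SCP circular intensity differential.

    Raises
    ------
    DegenerateMoleculeError
        If beta^2 is not positive (isotropic polarizability: no depolarized
        scattering, Delta undefined).
    """
    if inv.beta2 <= 0.0:
        raise DegenerateMoleculeError(
            f"beta^2 = {inv.beta2}: depolarized CID undefined for an "
            "isotropic scatterer")
    delta = (24.0 * inv.betaG2 - 8.0 * inv.betaA2) / (12.0 * inv.beta2 * C_AU)
    return CidPrediction(delta=delta,
                         wavelength_nm=wavelength_nm_from_omega(inv.omega),
                         method_label=inv.label)


def predict_from_tensors(t: MolecularTensorSet) -> CidPrediction:
    """Convenience: tensor set -> invariants -> Delta in one call."""
    return delta_scp90(compute_invariants(t))


def rescale_wavelength(p: CidPrediction,
                       target_wavelength_nm: float) -> CidPrediction:
    """Rescale a prediction to another wavelength via the 1/lambda law.

    Valid far off resonance only; the caller is responsible for staying in
    that regime (no spectral data is available to check). Extrapolations by
    more than a factor of 2 in wavelength are logged as a caution.
    """
    if target_wavelength_nm <= 0:
        raise ValueError("target wavelength must be positive")
    ratio = p.wavelength_nm / target_wavelength_nm
    if ratio > 2.0 or ratio < 0.5:
        logger.warning(
            "rescaling Delta from %.1f to %.1f nm extrapolates the 1/lambda "
            "law by more than a factor of 2", p.wavelength_nm,
            target_wavelength_nm)
    if target_wavelength_nm == p.wavelength_nm:
        return p
    label = (p.method_label + f" [rescaled {p.wavelength_nm:g}->"
             f"{target_wavelength_nm:g} nm]")
    return replace(p, delta=p.delta * ratio,
                   wavelength_nm=target_wavelength_nm, method_label=label)


def aggregate(predictions) -> PredictionEnsemble:
    """Summarize predictions sharing one wavelength and geometry.

    Reports the min, max and arithmetic mean of Delta across members — the
    spread over electronic-structure methods is the natural robustness
    measure for a sign-based configuration assignment.
    """
    preds = tuple(predictions)
    if not preds:
        raise EnsembleMismatchError("need at least one prediction")
    wl = preds[0].wavelength_nm
    geom = preds[0].geometry
    for p in preds[1:]:
        if p.wavelength_nm != wl or p.geometry != geom:
            raise EnsembleMismatchError(
                "all predictions must share wavelength and geometry "
                f"(got {p.wavelength_nm} nm/{p.geometry} vs {wl} nm/{geom})")
    deltas = [p.delta for p in preds]
    return PredictionEnsemble(
        predictions=preds,
        delta_min=min(deltas),
        delta_max=max(deltas),
        delta_mean=sum(deltas) / len(deltas),
    )
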