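"""Photon-counting simulation of an SCP measurement and its corrections.

The instrument detects Rayleigh scattered light at right angles through a
circular analyzer and records photon counts in the right- and left-circular
channels. The observable is

    Delta_raw = (n_R - n_L) / (n_R + n_L)

whose shot-noise-limited standard error is ~ 1/sqrt(n_R + n_L): reaching a
precision of 1e-5 requires of order 1e10 detected photons, which is what
sets the hours-long exposure times of a real measurement.

Counting model: the total count is Poisson with mean (count rate x exposure);
conditioned on that draw, the two circular channels are independent Poisson
variates with means N (1 +/- Delta)/2. At the count levels of interest this
is indistinguishable from multinomial thinning and is the standard model for
independent photon detectors.

Raw values are corrected, in order, for (1) an enantiomer-independent
instrumental offset, removed by antisymmetrizing a pair of measurements on
opposite enantiomers; (2) enantiomeric excess below 1, which dilutes Delta
linearly; (3) rotation of the incident linear polarization as the beam
propagates through the optically active sample, modelled as a single
multiplicative factor supplied by the caller. Uncertainties propagate in
quadrature through these linear steps.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

FOUR_PI = 4.0 * math.pi


class UnderSampledWarning(UserWarning):
    """Expected counts too low for the Delta estimator to be reliable."""


@dataclass(frozen=True)
class InstrumentConfig:
    """Parameters of one SCP exposure.

    The detected count rate is supplied directly rather than derived from
    power, solid angle and a scattering cross-section: cross-sections and
    detector efficiencies vary by orders of magnitude between samples and
    instruments, and the statistics of Delta depend only on the total count.
    Power and solid angle are carried as metadata describing the exposure.
    """

    power_mW: float = 30.0
    wavelength_nm: float = 532.0
    solid_angle_sr: float = 2e-5
    exposure_h: float = 15.0
    count_rate_per_s: float = 2e5
    seed: int = 0

    def __post_init__(self):
        for name in ("power_mW", "wavelength_nm", "solid_angle_sr",
                     "exposure_h", "count_rate_per_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.solid_angle_sr > FOUR_PI:
            raise ValueError("solid angle cannot exceed 4*pi sr")

    @property
    def exposure_s(self) -> float:
        return self.exposure_h * 3600.0

    @property
    def expected_counts(self) -> float:
        return self.count_rate_per_s * self.exposure_s


@dataclass(frozen=True)
class ScpMeasurement:
    """Photon counts in the two circular channels and the derived Delta."""

    n_right: int
    n_left: int
    delta_raw: float
    sigma_delta: float
    config: InstrumentConfig

    def __post_init__(self):
        if self.n_right < 0 or self.n_left < 0:
            raise ValueError("photon counts must be non-negative")


@dataclass(frozen=True)
class CorrectionInputs:
    """Inputs to the three-step correction pipeline."""

    enantiomeric_excess: float = 1.0
    rotation_correction_factor: float = 1.0
    paired_measurement: Optional[ScpMeasurement] = None

    def __post_init__(self):
        if not (0.0 < self.enantiomeric_excess <= 1.0):
            raise ValueError("enantiomeric excess must lie in (0, 1]")
        if self.rotation_correction_factor < 0:
            raise ValueError("rotation correction factor must be >= 0")


@dataclass(frozen=True)
class CorrectedDelta:
    """Result of the correction pipeline: Delta with uncertainty."""

    delta: float
    sigma: float
    offset: float = 0.0            #: removed enantiomer-independent offset
    notes: str = ""


def _estimate(n_right: int, n_left: int, config: InstrumentConfig) -> ScpMeasurement:
    n = n_right + n_left
    if n == 0:
        return ScpMeasurement(0, 0, 0.0, math.inf, config)
    delta = (n_right - n_left) / n
    # binomial standard error of the normalized difference; ~1/sqrt(N)
    sigma = math.sqrt(max(1.0 - delta * delta, 1.0 / n) / n)
    return ScpMeasurement(n_right, n_left, delta, sigma, config)


def simulate_scp(true_delta: float, config: InstrumentConfig,
                 rng: np.random.Generator | None = None) -> ScpMeasurement:
    """Draw one shot-noise-limited SCP measurement of ``true_delta``.

    Reproducible: with ``rng`` omitted, a fresh generator is seeded from
    ``config.seed`` so identical configs give bit-identical measurements.
    Pass an explicit generator to draw replicate sequences.
    """
    if not abs(true_delta) < 1.0:
        raise ValueError("|true_delta| must be < 1")
    if config.expected_counts < 100:
        warnings.warn(
            f"expected total counts {config.expected_counts:.1f} < 100: "
            "Delta estimator unreliable", UnderSampledWarning, stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = rng.poisson(config.expected_counts)
    mean_right = n_total * (1.0 + true_delta) / 2.0
    mean_left = n_total * (1.0 - true_delta) / 2.0
    n_right = int(rng.poisson(mean_right))
    n_left = int(rng.poisson(mean_left))
    return _estimate(n_right, n_left, config)


def correct_measurement(m: ScpMeasurement,
                        corr: CorrectionInputs) -> CorrectedDelta:
    """Apply the offset / enantiomeric-excess / beam-rotation corrections.

    With a paired measurement of the opposite enantiomer present, the
    enantiomer-independent offset is the symmetric part (Delta_A + Delta_B)/2
    and the reported value is the antisymmetric part (Delta_A - Delta_B)/2,
    which is the physical RayOA signal of ``m``'s enantiomer. The result is
    then divided by the enantiomeric excess and multiplied by the rotation
    correction factor; the uncertainty follows the same linear chain in
    quadrature.
    """
    notes = []
    if corr.paired_measurement is not None:
        pair = corr.paired_measurement
        if pair.config.wavelength_nm != m.config.wavelength_nm:
            raise ValueError(
                "paired measurement taken at a different wavelength "
                f"({pair.config.wavelength_nm} vs {m.config.wavelength_nm} nm)")
        offset = 0.5 * (m.delta_raw + pair.delta_raw)
        delta = 0.5 * (m.delta_raw - pair.delta_raw)
        sigma = 0.5 * math.hypot(m.sigma_delta, pair.sigma_delta)
        notes.append(f"offset {offset:+.3e} removed via enantiomer pairing")
    else:
        offset = 0.0
        delta = m.delta_raw
        sigma = m.sigma_delta
        notes.append("no paired measurement: offset assumed zero")
    delta /= corr.enantiomeric_excess
    sigma /= corr.enantiomeric_excess
    if corr.enantiomeric_excess != 1.0:
        notes.append(f"scaled by 1/ee = {1.0 / corr.enantiomeric_excess:.4f}")
    delta *= corr.rotation_correction_factor
    sigma *= corr.rotation_correction_factor
    if corr.rotation_correction_factor == 1.0:
        notes.append("beam-rotation correction left at identity (default)")
    return CorrectedDelta(delta=delta, sigma=sigma, offset=offset,
                          notes="; ".join(notes))


def required_exposure(target_sigma: float, config: InstrumentConfig) -> float:
    """Exposure (hours) needed to reach a shot-noise precision target.

    Solves 1/sqrt(count_rate * exposure) = target_sigma: the required count
    is 1/target_sigma^2, so exposure scales inversely with the count rate —
    higher laser power or a larger collection solid angle (both of which
    raise the count rate) shorten the measurement proportionally.
    """
    if target_sigma <= 0:
        raise ValueError("target_sigma must be positive")
    n_required = 1.0 / (target_sigma * target_sigma)
    return n_required / config.count_rate_per_s / 3600.0
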