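"""Absolute-configuration assignment from the sign of a measured Delta.

The depolarized SCP circular intensity differential has equal magnitude and
opposite sign for the two enantiomers, and its predicted sign is robust
across electronic-structure methods. The sign of a single corrected
measurement therefore identifies the absolute configuration, provided the
measurement is significantly non-zero and the prediction ensemble agrees on
the sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cid import PredictionEnsemble


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of a sign-comparison configuration assignment.

    ``status`` is ``"assigned"`` or ``"indeterminate"`` (measurement within
    k sigma of zero). ``sign_agreement`` is the fraction of ensemble members
    whose predicted sign matches the measurement; an assignment is
    ``confident`` only with unanimous sign agreement and a measurement more
    than k sigma from zero.
    """

    status: str
    assigned_label: str | None
    sign_agreement: float
    confident: bool
    measured_delta: float
    measured_sigma: float
    k: float

    def __post_init__(self):
        if not (0.0 <= self.sign_agreement <= 1.0):
            raise ValueError("sign_agreement must lie in [0, 1]")
        if self.confident and self.sign_agreement != 1.0:
            raise ValueError("a confident assignment requires unanimous signs")


def assign_configuration(measured_delta: float, measured_sigma: float,
                         ensemble: PredictionEnsemble,
                         label_map: Mapping[int, str],
                         k: float = 3.0) -> AssignmentResult:
    """Assign an enantiomer label by comparing measured and predicted signs.

    Parameters
    ----------
    measured_delta, measured_sigma
        Corrected circular intensity differential and its standard error.
    ensemble
        Predictions across electronic-structure methods. Their consensus
        sign, together with the label of the computed structure, is what the
        caller encodes in ``label_map``; their spread quantifies how robust
        the predicted sign is against the choice of method.
    label_map
        ``{+1: label, -1: label}`` — the enantiomer assigned when the
        measured Delta is positive or negative. For instance, if the
        computed (1S,5S) structure predicts Delta > 0 at this wavelength,
        pass ``{+1: "(1S,5S)", -1: "(1R,5R)"}``.
    k
        Significance multiple: a measurement within ``k * sigma`` of zero is
        reported indeterminate rather than assigned.

    Notes
    -----
    ``sign_agreement`` is the fraction of ensemble members sharing the
    ensemble's consensus (majority) sign — each member whose sign agrees
    with the consensus implies the same assigned label for the measurement,
    so unanimity means the assignment does not depend on which
    electronic-structure method one trusts.
    """
    if not ensemble.predictions:
        raise ValueError("ensemble must be non-empty")
    if +1 not in label_map or -1 not in label_map:
        raise ValueError("label_map must provide labels for both signs")
    if k < 0:
        raise ValueError("k must be non-negative")

    if abs(measured_delta) <= k * measured_sigma:
        return AssignmentResult(
            status="indeterminate", assigned_label=None,
            sign_agreement=0.0, confident=False,
            measured_delta=measured_delta, measured_sigma=measured_sigma, k=k)

    meas_sign = int(math.copysign(1.0, measured_delta))
    signs = [int(math.copysign(1.0, p.delta)) for p in ensemble.predictions
             if p.delta != 0.0]
    n_pos = sum(1 for s in signs if s > 0)
    consensus = +1 if 2 * n_pos >= len(signs) else -1
    n_match = sum(1 for s in signs if s == consensus)
    sign_agreement = n_match / len(ensemble.predictions)
    assigned = label_map[meas_sign]
    confident = (sign_agreement == 1.0
                 and abs(measured_delta) > k * measured_sigma)
    return AssignmentResult(
        status="assigned", assigned_label=assigned,
        sign_agreement=sign_agreement, confident=confident,
        measured_delta=measured_delta, measured_sigma=measured_sigma, k=k)
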