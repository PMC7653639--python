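"""Genome-size arithmetic and replicate quality control.

Flow-cytometric 2C values (holoploid genome size, pg) are accepted when at
least three daily replicates agree to within 2 % (max/min ratio), or failing
that, when the standard error of the mean stays under 1 % of the mean.
Monoploid (1Cx) sizes are 2C divided by ploidy, rounded half-up to the 3
decimals conventional for pg values, and theoretical 2C ranges for a ploidy
level are spanned by multiplying the monoploid sizes of diploid anchor taxa —
an observed 2C below that range flags genome downsizing.
"""

from __future__ import annotations

import enum
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import FcmReplicates


class QcDecision(enum.Enum):
    ACCEPTED = "accepted"
    NEEDS_MORE = "needs_more_measurements"
    REJECTED = "rejected"


def qc_fcm_replicates(
    r: FcmReplicates,
    daily_ratio_max: float = 1.02,
    sem_max_frac: float = 0.01,
    min_reps: int = 3,
) -> QcDecision:
    """Replicate acceptance rule for repeated 2C measurements.

    Non-positive measurements reject the sample outright.  Fewer than
    ``min_reps`` replicates always need more measurements.  Otherwise the
    sample is accepted when day-to-day variation (max/min) stays within
    ``daily_ratio_max``, or when the SEM (sample sd / sqrt(n)) is below
    ``sem_max_frac`` of the mean.
    """
    values = r.values
    if any(v <= 0 for v in values):
        return QcDecision.REJECTED
    if len(values) < min_reps:
        return QcDecision.NEEDS_MORE
    if max(values) / min(values) <= daily_ratio_max + 1e-12:
        return QcDecision.ACCEPTED
    sem = float(np.std(values, ddof=1)) / math.sqrt(len(values))
    if sem / float(np.mean(values)) < sem_max_frac:
        return QcDecision.ACCEPTED
    return QcDecision.NEEDS_MORE


def monoploid_size(two_c: float, ploidy: int, decimals: int = 3) -> float:
    """1Cx value in pg: 2C / ploidy, rounded half-up to ``decimals``."""
    if two_c <= 0:
        raise ValidationError("2C value must be positive")
    if ploidy < 1:
        raise ValidationError("ploidy must be >= 1")
    quotient = Decimal(str(two_c)) / Decimal(ploidy)
    quantum = Decimal(1).scaleb(-decimals)
    return float(quotient.quantize(quantum, rounding=ROUND_HALF_UP))


def theoretical_2c_range(ploidy: int, cx_anchors: Sequence[float]) -> tuple[float, float]:
    """Expected 2C interval for a ploidy from diploid-taxon 1Cx anchors."""
    anchors = list(cx_anchors)
    if not anchors:
        raise ValidationError("need at least one 1Cx anchor")
    if ploidy < 1:
        raise ValidationError("ploidy must be >= 1")
    return (ploidy * min(anchors), ploidy * max(anchors))


def intraspecific_variation(values: Sequence[float]) -> float:
    """Percent spread of repeated/multi-sample 2C values: 100 (max-min)/min."""
    vals = list(values)
    if len(vals) < 2:
        raise ValidationError("need at least two values")
    return 100.0 * (max(vals) - min(vals)) / min(vals)


def fold_range(values: Sequence[float]) -> float:
    """max/min ratio of a set of genome sizes (the 'x-fold range')."""
    vals = list(values)
    if not vals or min(vals) <= 0:
        raise ValidationError("values must be positive and non-empty")
    return max(vals) / min(vals)
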