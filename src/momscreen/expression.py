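"""qPCR threshold-cycle preprocessing.

Relative expression is computed with the comparative-CT (ΔΔCT) method:
``2**(-ΔΔCT)`` where ``ΔΔCT = (marker_ct - normalizer_ct) - reference_delta_ct``
and the reference ΔCT comes from a calibrator sample.  Constant offsets such as
preamplification cycles cancel in the double difference (and again in MoM
normalization downstream).  Reactions whose threshold cycle reaches the
configured ``max_ct`` — or never crosses threshold at all — are flagged below
detection rather than assigned an expression value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional

from .cohort import RawMeasurement

#: Conventional qPCR detection cutoff in cycles.
DEFAULT_MAX_CT = 40.0


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles for one marker reaction.

    Any cycle value may be ``None`` when the reaction never crossed threshold.
    """

    marker_ct: Optional[float]
    normalizer_ct: Optional[float]
    reference_delta_ct: Optional[float]

    def complete(self) -> bool:
        vals = (self.marker_ct, self.normalizer_ct, self.reference_delta_ct)
        return all(v is not None and math.isfinite(v) for v in vals)


def delta_delta_ct(rec: CtRecord) -> float:
    """Fold-change expression ``2**(-ΔΔCT)``; strictly positive.

    Raises ``ValueError`` when a cycle value is absent — use
    :func:`flag_below_detection` for inputs that may be undetected.
    """
    if not rec.complete():
        raise ValueError("delta_delta_ct requires all three CT values")
    ddct = (rec.marker_ct - rec.normalizer_ct) - rec.reference_delta_ct
    return 2.0 ** (-ddct)


def flag_below_detection(
    records: Iterable[CtRecord], max_ct: float = DEFAULT_MAX_CT
) -> List[RawMeasurement]:
    """Convert CT records to measurements, flagging undetected reactions.

    A record whose marker CT is absent or at/above ``max_ct`` is returned as a
    below-detection :class:`RawMeasurement`; all others carry the ΔΔCT
    expression value.
    """
    out: List[RawMeasurement] = []
    for rec in records:
        if rec.marker_ct is None or rec.marker_ct >= max_ct or not rec.complete():
            out.append(RawMeasurement(None, below_detection=True))
        else:
            out.append(RawMeasurement(delta_delta_ct(rec)))
    return out
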