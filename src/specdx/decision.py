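"""Specimen-level diagnosis: infiltration index, spectral call, FS fusion.

The *infiltration index* summarises a specimen's five lesion-point
invasion probabilities as their sum, so it ranges over [0, 5]: 0 means
every probed lesion point reads non-invasive, 5 means every point reads
confidently invasive.  The spectral IAC call thresholds the index
(strictly: index > T).

Frozen-section (FS) results are scored 1 (definite invasive), 0
(definite non-invasive) or 0.5 (indeterminate, deferred to paraffin).
The spectral-assisted-FS fusion rule keeps definite FS calls and
resolves indeterminate ones with the spectral call.  When FS-alone
accuracy is computed, an indeterminate FS counts as incorrect (it gives
the surgeon no answer), which is why fused accuracy can only improve on
FS-alone accuracy.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BinaryLabel, FSCall, Site, Specimen

__all__ = [
    "THRESHOLD_PROFILES",
    "InfiltrationIndex",
    "DiagnosisResult",
    "infiltration_index",
    "spectral_call",
    "fs_score",
    "fused_call",
    "fs_binary_call",
    "diagnose_specimen",
    "diagnose_cohort",
]

#: Named operating thresholds on the infiltration index.
#: ``majority``: more than half of the five lesion points read invasive.
#: ``strict``: essentially all five points must read invasive; this is
#: the operating point consistent with the published worked example of
#: twelve FS-indeterminate specimens (any T in [4.5, 5.0) reproduces its
#: printed error pattern).
THRESHOLD_PROFILES: dict[str, float] = {"majority": 2.5, "strict": 4.5}


@dataclasses.dataclass(frozen=True)
class InfiltrationIndex:
    """Sum of the five lesion-point invasion probabilities, in [0, 5]."""

    value: float
    per_point_probabilities: tuple[float, ...]

    def rounded(self, ndigits: int = 1) -> float:
        """Value at reporting precision (one decimal)."""
        return round(self.value, ndigits)


def infiltration_index(per_point_probabilities: Sequence[float]) -> InfiltrationIndex:
    probs = tuple(float(p) for p in per_point_probabilities)
    if len(probs) != 5:
        raise ValueError(
            f"infiltration index needs exactly 5 lesion-point probabilities, "
            f"got {len(probs)}"
        )
    for p in probs:
        if not (0.0 <= p <= 1.0) or not np.isfinite(p):
            raise ValueError(f"probability {p} outside [0, 1]")
    return InfiltrationIndex(value=float(sum(probs)), per_point_probabilities=probs)


def spectral_call(
    index: InfiltrationIndex | float, threshold: float
) -> BinaryLabel:
    """IAC iff the infiltration index strictly exceeds the threshold."""
    value = index.value if isinstance(index, InfiltrationIndex) else float(index)
    if not (0.0 <= threshold <= 5.0):
        raise ValueError("threshold must be in [0, 5]")
    return BinaryLabel.IAC if value > threshold else BinaryLabel.NON_IAC


#: Fixed FS scoring convention.
_FS_SCORES: dict[FSCall, float] = {
    FSCall.DEFINITE_NON_IAC: 0.0,
    FSCall.INDETERMINATE: 0.5,
    FSCall.DEFINITE_IAC: 1.0,
}


def fs_score(call: FSCall) -> float:
    """Definite invasive -> 1, definite non-invasive -> 0, indeterminate -> 0.5."""
    return _FS_SCORES[FSCall(call)]


def fused_call(fs: float, spectral: BinaryLabel) -> BinaryLabel:
    """Definite FS overrides; indeterminate FS defers to the spectral call."""
    if fs == 1.0:
        return BinaryLabel.IAC
    if fs == 0.0:
        return BinaryLabel.NON_IAC
    if fs == 0.5:
        return BinaryLabel(spectral)
    raise ValueError(f"FS score must be 0, 0.5 or 1; got {fs}")


def fs_binary_call(call: FSCall) -> BinaryLabel | None:
    """Definite FS call as a binary label; None when indeterminate."""
    s = fs_score(call)
    if s == 0.5:
        return None
    return BinaryLabel.IAC if s == 1.0 else BinaryLabel.NON_IAC


@dataclasses.dataclass
class DiagnosisResult:
    specimen_id: str
    infiltration_index: InfiltrationIndex
    spectral_call: BinaryLabel
    fs_score: float | None
    fused_call: BinaryLabel | None
    threshold: float


def _lesion_probabilities(scores: pd.DataFrame, specimen_id: str) -> list[float]:
    sub = scores[
        (scores["specimen_id"] == specimen_id)
        & (scores["site"] == Site.LESION.value)
    ].sort_values("point_index")
    return list(sub["probability"])


def diagnose_specimen(
    specimen_id: str,
    lesion_probabilities: Sequence[float],
    fs: FSCall | None,
    threshold: float,
) -> DiagnosisResult:
    idx = infiltration_index(lesion_probabilities)
    s_call = spectral_call(idx, threshold)
    if fs is None:
        return DiagnosisResult(specimen_id, idx, s_call, None, None, threshold)
    score = fs_score(fs)
    return DiagnosisResult(
        specimen_id, idx, s_call, score, fused_call(score, s_call), threshold
    )


def diagnose_cohort(
    scores: pd.DataFrame,
    fs_calls: Mapping[str, FSCall] | None = None,
    threshold: float | str = "strict",
) -> list[DiagnosisResult]:
    """Specimen-level diagnoses from a group-score table.

    ``scores`` is the table produced by
    :meth:`specdx.model.InvasionClassifierResults.score_cohort`
    (columns: specimen_id, site, point_index, probability).  ``threshold``
    is a number in [0, 5] or a profile name from
    :data:`THRESHOLD_PROFILES`.
    """
    if isinstance(threshold, str):
        threshold = THRESHOLD_PROFILES[threshold]
    fs_calls = fs_calls or {}
    results = []
    for sid in scores["specimen_id"].drop_duplicates():
        probs = _lesion_probabilities(scores, sid)
        results.append(
            diagnose_specimen(sid, probs, fs_calls.get(sid), threshold)
        )
    return results


def diagnoses_to_frame(results: Iterable[DiagnosisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": r.specimen_id,
            "infiltration_index": r.infiltration_index.rounded(),
            "spectral_call": r.spectral_call.value,
            "fs_score": r.fs_score,
            "fused_call": None if r.fused_call is None else r.fused_call.value,
            "threshold": r.threshold,
        }
        for r in results
    )
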