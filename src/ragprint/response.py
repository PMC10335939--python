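"""Residual-disease log-reduction metrics and molecular-response calls.

Residual disease is a fusion-transcript level expressed as percent; the
metric is the base-10 log reduction relative to the patient's own diagnostic
baseline.  Undetected measurements are censored at the assay detection limit
(default 5.0 log reduction, the conservative end of the assay's 5.0-5.5
range).  A major molecular response (MMR) is >= 3 log reduction and a deep
molecular response (DMR) is >= 4; both boundaries are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class Measurement:
    day: int
    value: float       # percent transcript; 0 when undetected
    detected: bool = True


@dataclass
class ResponseSeries:
    patient_id: str
    baseline: float    # percent transcript at diagnosis
    measurements: list
    detection_limit_lr: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        self.measurements = sorted(self.measurements, key=lambda m: m.day)


@dataclass
class ResponseCall:
    log_reduction: float
    censored: bool
    mmr: bool
    dmr: bool


def log_reduction(
    baseline: float, value: float, detection_limit_lr: float = 5.0
) -> tuple[float, bool]:
    """log10(baseline/value); undetected (value == 0) is censored at the
    detection limit."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if value < 0:
        raise ValueError("value must be >= 0")
    if value == 0:
        return detection_limit_lr, True
    return math.log10(baseline / value), False


def classify_response(lr: float, censored: bool = False) -> ResponseCall:
    """MMR at >= 3 log reduction, DMR at >= 4 (DMR implies MMR)."""
    if not math.isfinite(lr):
        raise ValueError("log reduction must be finite")
    return ResponseCall(log_reduction=lr, censored=censored, mmr=lr >= 3.0, dmr=lr >= 4.0)


def first_post_induction_lr(
    series: ResponseSeries, window_days: int = 60
) -> Optional[tuple[float, bool]]:
    """Log reduction of the earliest measurement with 0 < day <= window_days
    (the first value after induction therapy), or None if absent."""
    for m in series.measurements:
        if 0 < m.day <= window_days:
            value = 0.0 if not m.detected else m.value
            return log_reduction(series.baseline, value, series.detection_limit_lr)
    return None


def read_response_table(path) -> list[ResponseSeries]:
    """TSV columns: patient_id, day, percent_transcript, detected.

    The day-0 (or earliest) measurement per patient is the diagnostic
    baseline.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for pid, grp in df.groupby("patient_id"):
        grp = grp.sort_values("day")
        baseline = float(grp.iloc[0]["percent_transcript"])
        ms = [
            Measurement(day=int(r.day), value=float(r.percent_transcript),
                        detected=bool(r.detected))
            for r in grp.itertuples()
        ]
        out.append(ResponseSeries(patient_id=str(pid), baseline=baseline, measurements=ms))
    return out
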