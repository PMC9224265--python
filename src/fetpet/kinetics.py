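"""Time-activity-curve extraction, time-to-peak and the ternary shape score.

A lesion's dynamic behaviour is summarised by two biomarkers:

* **TTP** (time-to-peak, minutes): time from the start of the dynamic
  acquisition to the curve maximum; curves without an identifiable peak
  (maximum at the final frame, or constant) are assigned the acquisition end
  (40 min by default).
* **TAC shape score** in {-1, 0, 1}: -1 for an early peak (before the
  22.5-min cutoff) followed by a descent of at least 5% of the peak; 0 for an
  early peak followed by a plateau or a descent of less than 5%; 1 for curves
  that keep rising (no identifiable peak) or peak only at/after the cutoff.

"Identifiable peak" is operationalised as: the first index attaining the
global maximum is not the final frame; the descent is measured from the peak
value to the final-frame value, as a fraction of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import DynamicSeries, VoiMask

__all__ = [
    "TimeActivityCurve",
    "KineticBiomarkers",
    "extract_tac",
    "smooth_tac",
    "compute_ttp",
    "tac_score",
]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean SUV in a VOI per frame, against frame mid-times in minutes."""

    time_min: np.ndarray
    suv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        s = np.asarray(self.suv, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("time_min and suv must be equal-length non-empty 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_min must be strictly increasing")
        if np.any(t <= 0):
            raise ValueError("time_min must be positive (frame mid-times)")
        if np.any(s < 0):
            raise ValueError("suv must be >= 0")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "suv", s)

    def __len__(self) -> int:
        return self.time_min.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min, "suv": self.suv})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["suv"].to_numpy())


@dataclass(frozen=True)
class KineticBiomarkers:
    """TTP and shape score of one lesion TAC."""

    ttp_min: float
    tac_score: int  # -1 descending, 0 plateau, 1 ascending/late peak
    peak_suv: float
    terminal_descent: float  # (peak - final) / peak, 0 for score-1 curves


def extract_tac(series: DynamicSeries, kinetic_voi: VoiMask) -> TimeActivityCurve:
    """Per-frame arithmetic mean SUV over the VOI, at frame mid-times (min)."""
    if kinetic_voi.empty:
        raise ValueError("kinetic VOI is empty")
    if kinetic_voi.voxels.shape != series.grid_shape:
        raise ValueError("VOI grid does not match the series grid")
    suv = series.voxels[:, kinetic_voi.voxels].mean(axis=1)
    return TimeActivityCurve(series.schedule.mid_times_min, suv)


def smooth_tac(tac: TimeActivityCurve, window: int = 3) -> TimeActivityCurve:
    """Centred moving average with symmetrically shrinking windows at the ends.

    ``window`` must be odd; ``window = 1`` is the identity.  At index ``i``
    the half-width shrinks to ``min(window//2, i, n-1-i)`` so the average
    stays centred (the first and last samples are left unchanged).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return tac
    n = len(tac)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = tac.suv[i - r : i + r + 1].mean()
    return TimeActivityCurve(tac.time_min, out)


def _first_peak_index(suv: np.ndarray) -> int:
    return int(np.argmax(suv))  # argmax returns the first maximal index


def compute_ttp(tac: TimeActivityCurve, acquisition_end: float = 40.0) -> float:
    """Time-to-peak in minutes.

    The peak is the first index attaining the global maximum; if that is the
    final frame, or the curve is constant (no identifiable peak), TTP is the
    acquisition end.
    """
    p = _first_peak_index(tac.suv)
    if p == len(tac) - 1 or tac.suv.max() == tac.suv.min():
        return float(acquisition_end)
    return float(tac.time_min[p])


def tac_score(
    tac: TimeActivityCurve,
    early_cutoff: float = 22.5,
    plateau_tolerance: float = 0.05,
    acquisition_end: float = 40.0,
) -> KineticBiomarkers:
    """Classify a TAC into the ternary shape score and report TTP.

    Score 1: no identifiable peak before ``early_cutoff`` minutes (maximum at
    the final frame, constant or all-zero curve, or peak at/after the
    cutoff).  Otherwise the terminal descent ``(peak - final) / peak``
    decides: score -1 if it is at least ``plateau_tolerance``, score 0 for a
    plateau or smaller descent.
    """
    suv = tac.suv
    p = _first_peak_index(suv)
    peak = float(suv[p])
    ttp = compute_ttp(tac, acquisition_end)
    no_peak = p == len(tac) - 1 or suv.max() == suv.min() or peak == 0.0
    if no_peak or tac.time_min[p] >= early_cutoff:
        return KineticBiomarkers(ttp_min=ttp, tac_score=1, peak_suv=peak, terminal_descent=0.0)
    descent = (peak - float(suv[-1])) / peak
    score = -1 if descent >= plateau_tolerance else 0
    return KineticBiomarkers(ttp_min=ttp, tac_score=score, peak_suv=peak, terminal_descent=descent)
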