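"""FUCCI cell-cycle reporter trace classification and entry counting.

Two-channel single-cell traces (mCherry-hCdt1 "RFP" and mVenus-hGeminin
"YFP" mean nuclear intensities) are classified frame-by-frame into quadrants:
RFP-high/YFP-low = G1, RFP-high/YFP-high = S, RFP-low/YFP-high = G2,
RFP-low/YFP-low = M/early G1.  A cell-cycle entry is a transition from S to G2
between consecutive frames.  "High" means strictly above the channel
threshold; thresholds come from an unstimulated reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = ["FucciTrace", "classify_phases", "count_entries",
           "snapshot_fractions", "reference_thresholds", "PHASES"]

PHASES = ("G1", "S", "G2", "M")


@dataclass
class FucciTrace:
    """One tracked cell: equally long channel vectors, intensities >= 0."""

    times: np.ndarray
    rfp: np.ndarray
    yfp: np.ndarray
    thresholds: tuple[float, float] | None = None  # (rfp_thr, yfp_thr)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        if not (len(self.times) == len(self.rfp) == len(self.yfp)):
            raise ValueError("times, rfp and yfp must have equal length")


def _fill_forward(x: np.ndarray) -> np.ndarray:
    """Carry the last observation forward over missing frames."""
    x = x.copy()
    ok = np.isfinite(x)
    if not ok.any():
        raise ValueError("trace has no finite intensities")
    idx = np.where(ok, np.arange(len(x)), 0)
    np.maximum.accumulate(idx, out=idx)
    x = x[idx]
    x[: np.argmax(ok)] = x[np.argmax(ok)]
    return x


def classify_phases(trace: FucciTrace,
                    thresholds: tuple[float, float] | None = None) -> np.ndarray:
    """Quadrant phase call per frame (array of 'G1'/'S'/'G2'/'M')."""
    thr = thresholds or trace.thresholds
    if thr is None:
        raise ValueError("no thresholds set; derive them from an unstimulated "
                         "reference with reference_thresholds()")
    rfp_thr, yfp_thr = thr
    rfp = _fill_forward(trace.rfp)
    yfp = _fill_forward(trace.yfp)
    r_high = rfp > rfp_thr
    y_high = yfp > yfp_thr
    out = np.empty(len(rfp), dtype=object)
    out[r_high & ~y_high] = "G1"
    out[r_high & y_high] = "S"
    out[~r_high & y_high] = "G2"
    out[~r_high & ~y_high] = "M"
    return out


def count_entries(phases: np.ndarray) -> int:
    """Number of S -> G2 transitions between consecutive frames."""
    phases = np.asarray(phases)
    return int(np.sum((phases[:-1] == "S") & (phases[1:] == "G2")))


def snapshot_fractions(rfp: np.ndarray, yfp: np.ndarray,
                       thresholds: tuple[float, float]) -> dict[str, float]:
    """Quadrant fractions of a population snapshot (sum to 1)."""
    rfp = np.asarray(rfp, dtype=float)
    yfp = np.asarray(yfp, dtype=float)
    if rfp.size == 0:
        raise ValueError("empty population window")
    rfp_thr, yfp_thr = thresholds
    r_high = rfp > rfp_thr
    y_high = yfp > yfp_thr
    n = float(rfp.size)
    return {
        "G1": float(np.sum(r_high & ~y_high)) / n,
        "S": float(np.sum(r_high & y_high)) / n,
        "G2": float(np.sum(~r_high & y_high)) / n,
        "M": float(np.sum(~r_high & ~y_high)) / n,
    }


def reference_thresholds(rfp: np.ndarray, yfp: np.ndarray) -> tuple[float, float]:
    """Per-channel bimodal (Otsu) split of an unstimulated reference snapshot."""
    return (float(threshold_otsu(np.asarray(rfp, dtype=float))),
            float(threshold_otsu(np.asarray(yfp, dtype=float))))


def entry_table(traces: list[FucciTrace],
                thresholds: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-cell entry counts (cell, n_entries), e.g. for entry histograms."""
    rows = [{"cell": i, "n_entries": count_entries(classify_phases(t, thresholds))}
            for i, t in enumerate(traces)]
    return pd.DataFrame(rows)
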