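"""Batch-release advisor backed by the published prediction table.

The packaged calibration resource maps a measured RCP (percent) and the
read time after development (0.5, 2, 3.5, 5 or 6.5 h) to the expected
equilibrium RCP with a 95% prediction interval.  A release decision
against a purity threshold follows directly from the interval:

* ``release``  -- the interval lower bound meets the threshold,
* ``reject``   -- the interval upper bound is below the threshold,
* ``hold``     -- the threshold falls inside the interval (re-measure
  later or wait for equilibrium).

From the table one recovers the published release frontiers: with a 95%
purity threshold, release is guaranteed by a measurement of >= 98% at
0.5 h or >= 94% at 2 h.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationTable",
    "ReleaseDecision",
    "load_calibration",
    "lookup",
    "advise",
    "release_frontier",
    "CALIBRATION_TIMES_H",
    "EQUILIBRIUM_CUTOFF_H",
]

logger = logging.getLogger("actlc.release")

CALIBRATION_TIMES_H = (0.5, 2.0, 3.5, 5.0, 6.5)
MEASURED_GRID = tuple(range(0, 100, 10)) + tuple(range(91, 101))
#: at or beyond this read time the chain is back at secular equilibrium and
#: the measurement needs no correction
EQUILIBRIUM_CUTOFF_H = 20.0


@dataclass(frozen=True)
class CalibrationRecord:
    measured_pct: int
    time_h: float
    expected_pct: int
    lower_pct: int
    upper_pct: int


@dataclass(frozen=True)
class CalibrationTable:
    records: Tuple[CalibrationRecord, ...]

    def at(self, time_h: float) -> List[CalibrationRecord]:
        recs = [r for r in self.records if math.isclose(r.time_h, time_h)]
        return sorted(recs, key=lambda r: r.measured_pct)


@dataclass(frozen=True)
class ReleaseDecision:
    verdict: str  # release | hold | reject
    measured_pct: float
    read_time_h: float
    expected_pct: float
    lower_pct: float
    upper_pct: float
    threshold_pct: float
    rationale: str
    equilibrium_read: bool = False


def load_calibration() -> CalibrationTable:
    """Load and validate the packaged calibration table.

    Fails loudly if the resource does not contain the full grid (20
    measured levels x 5 read times), if any interval fails to bracket its
    expected value, or if an expected column is not nondecreasing in the
    measured value.
    """
    ref = resources.files("actlc.data").joinpath("calibration_table.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    expected_cols = ["measured_pct", "time_h", "expected_pct", "lower_pct", "upper_pct"]
    if list(df.columns) != expected_cols:
        raise ValueError(f"calibration resource has columns {list(df.columns)}")
    if len(df) != len(MEASURED_GRID) * len(CALIBRATION_TIMES_H):
        raise ValueError(f"calibration resource has {len(df)} records")
    records = tuple(
        CalibrationRecord(
            int(r.measured_pct),
            float(r.time_h),
            int(r.expected_pct),
            int(r.lower_pct),
            int(r.upper_pct),
        )
        for r in df.itertuples()
    )
    table = CalibrationTable(records)
    for t in CALIBRATION_TIMES_H:
        recs = table.at(t)
        if [r.measured_pct for r in recs] != list(MEASURED_GRID):
            raise ValueError(f"measured grid incomplete at {t} h")
        for r in recs:
            if not (0 <= r.lower_pct <= r.expected_pct <= r.upper_pct <= 100):
                raise ValueError(f"interval violation at {r}")
        exp = [r.expected_pct for r in recs]
        if any(a > b for a, b in zip(exp, exp[1:])):
            raise ValueError(f"expected values not monotone at {t} h")
    return table


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def lookup(
    table: CalibrationTable, measured_pct: float, read_time_h: float
) -> CalibrationRecord:
    """Calibration entry for a measured value at a supported read time.

    Read times must match the table exactly (no interpolation across
    times: the columns come from distinct model strata); off-grid
    measured values are interpolated linearly between the bracketing grid
    rows and rounded half-up to integer percent.
    """
    if not 0.0 <= measured_pct <= 100.0:
        raise ValueError("measured_pct outside [0, 100]")
    if not any(math.isclose(read_time_h, t) for t in CALIBRATION_TIMES_H):
        raise ValueError(
            f"read time {read_time_h} h is not a calibrated stratum "
            f"{CALIBRATION_TIMES_H}; use the model-based predictor for "
            "other times"
        )
    recs = table.at(read_time_h)
    grid = np.array([r.measured_pct for r in recs], dtype=float)
    if measured_pct in grid:
        return recs[int(np.flatnonzero(grid == measured_pct)[0])]
    j = int(np.searchsorted(grid, measured_pct))
    lo_rec, hi_rec = recs[j - 1], recs[j]
    f = (measured_pct - lo_rec.measured_pct) / (hi_rec.measured_pct - lo_rec.measured_pct)

    def interp(a: int, b: int) -> int:
        return _round_half_up(a + f * (b - a))

    return CalibrationRecord(
        measured_pct=_round_half_up(measured_pct),
        time_h=lo_rec.time_h,
        expected_pct=interp(lo_rec.expected_pct, hi_rec.expected_pct),
        lower_pct=interp(lo_rec.lower_pct, hi_rec.lower_pct),
        upper_pct=interp(lo_rec.upper_pct, hi_rec.upper_pct),
    )


def advise(
    measured_pct: float,
    read_time_h: float,
    threshold_pct: float = 95.0,
    table: Optional[CalibrationTable] = None,
) -> ReleaseDecision:
    """Batch-release decision for a measured RCP at a given read time.

    Reads at or after 20 h are equilibrium reads: the measurement itself
    is the RCP (degenerate interval).  Otherwise the calibration interval
    decides: release iff its lower bound meets the threshold, reject iff
    its upper bound misses it, hold in between.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold_pct outside (0, 100]")
    if read_time_h >= EQUILIBRIUM_CUTOFF_H:
        expected = lower = upper = float(measured_pct)
        equilibrium = True
    else:
        table = table if table is not None else load_calibration()
        rec = lookup(table, measured_pct, read_time_h)
        expected, lower, upper = (
            float(rec.expected_pct),
            float(rec.lower_pct),
            float(rec.upper_pct),
        )
        equilibrium = False
    if lower >= threshold_pct:
        verdict = "release"
        rationale = (
            f"interval lower bound {lower:.0f}% meets the {threshold_pct:.0f}% threshold"
        )
    elif upper < threshold_pct:
        verdict = "reject"
        rationale = (
            f"interval upper bound {upper:.0f}% is below the {threshold_pct:.0f}% threshold"
        )
    else:
        verdict = "hold"
        rationale = (
            f"threshold {threshold_pct:.0f}% falls inside the prediction interval "
            f"({lower:.0f}, {upper:.0f})%"
        )
    if equilibrium:
        rationale += " [equilibrium read; measurement taken at face value]"
    decision = ReleaseDecision(
        verdict=verdict,
        measured_pct=float(measured_pct),
        read_time_h=float(read_time_h),
        expected_pct=expected,
        lower_pct=lower,
        upper_pct=upper,
        threshold_pct=float(threshold_pct),
        rationale=rationale,
        equilibrium_read=equilibrium,
    )
    logger.info(
        "advise measured=%.1f%% t=%.1fh threshold=%.0f%% -> %s (expected %.0f%%, PI %.0f-%.0f%%)",
        decision.measured_pct,
        decision.read_time_h,
        decision.threshold_pct,
        decision.verdict,
        decision.expected_pct,
        decision.lower_pct,
        decision.upper_pct,
    )
    return decision


def release_frontier(
    table: CalibrationTable, read_time_h: float, threshold_pct: float = 95.0
) -> Optional[int]:
    """Smallest integer measured RCP on the 90-100 grid whose interval
    lower bound meets the threshold at the given read time."""
    for rec in table.at(read_time_h):
        if rec.measured_pct >= 90 and rec.lower_pct >= threshold_pct:
            return rec.measured_pct
    return None
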