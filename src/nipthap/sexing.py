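"""Fetal sex determination from chrY-target coverage in maternal plasma.

A male fetus contributes chromosome-Y fragments to maternal plasma, so the
captured Y-specific target shows substantial mean depth and breadth of
coverage; in female pregnancies only non-specific mapping noise remains.
The call uses both the mean depth and the fraction of target bases covered
by at least 4 reads (4x coverage), which separates the two classes by a
wide empirical margin (male pregnancies >=97% 4x coverage, female <=25%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class YRegionStats:
    """Coverage summary over the Y-specific target region."""

    mean_depth: float
    cov4x: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cov4x <= 1.0:
            raise ValueError(f"cov4x={self.cov4x} outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError(f"negative mean depth {self.mean_depth}")


@dataclass(frozen=True)
class SexThresholds:
    """Decision cuts chosen inside the empirical male/female gap, with an
    indeterminate buffer between them."""

    male_min_cov4x: float = 0.50
    male_min_depth: float = 20.0
    female_max_cov4x: float = 0.30


def compute_y_stats(depths) -> YRegionStats:
    """Summarise per-base depths over the Y target region."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("empty depth vector for Y region")
    if np.any(d < 0):
        raise ValueError("negative depths in Y region")
    return YRegionStats(mean_depth=float(d.mean()), cov4x=float((d >= 4).mean()))


def call_fetal_sex(stats: YRegionStats, thresholds: SexThresholds = SexThresholds()) -> str:
    """Call ``male``/``female``/``indeterminate`` from Y-region coverage.

    Male requires both high 4x coverage and adequate mean depth; female
    requires low 4x coverage; anything in the buffer zone is reported as
    indeterminate rather than silently forced into a class.
    """
    if stats.cov4x >= thresholds.male_min_cov4x and stats.mean_depth >= thresholds.male_min_depth:
        return "male"
    if stats.cov4x <= thresholds.female_max_cov4x:
        return "female"
    return "indeterminate"
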