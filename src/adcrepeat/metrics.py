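"""Per-pair repeatability statistics and group summaries.

Repeatability of a test/retest pair is the symmetric percentage change

    R12 = 2 (D1 - D2) / (D1 + D2) * 100,

applied to mean ADC (dADC%) and, with voxel counts, to volume (dVOL%).
Cohort reproducibility is summarised by the width of the 95% confidence
bound, taken as 1.96 x SD of the per-pair values; the standard deviation
uses the population form (ddof=0) by default, which is the convention
that reproduces this study's printed group statistics, with ``ddof``
exposed for the sample form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import InsufficientDataError, RepeatabilityRecord, TestRetestPair


@dataclass(frozen=True)
class GroupSummary:
    """Cohort-level summary of a collection of percentage values."""

    n: int
    mean: float
    sd: float
    ci_width_95: float
    cov_pct: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def to_dict(self) -> dict:
        d = {"n": self.n, "mean": self.mean, "sd": self.sd,
             "ci_width_95": self.ci_width_95}
        if self.cov_pct is not None:
            d["cov_pct"] = self.cov_pct
        return d


def percent_change(d1: float, d2: float) -> float:
    """Symmetric percentage change 200 (d1 - d2) / (d1 + d2).

    Bounded in (-200, 200) for positive inputs and antisymmetric in its
    arguments.
    """
    denom = d1 + d2
    if not denom > 0:
        raise ValueError("d1 + d2 must be > 0")
    return 200.0 * (d1 - d2) / denom


def group_summary(values: Iterable[float], *, ddof: int = 0) -> GroupSummary:
    """Mean, SD and 95% confidence-bound width (1.96 x SD) of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need >= 2 values for a group summary")
    sd = float(arr.std(ddof=ddof))
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=sd,
                        ci_width_95=1.96 * sd)


def make_record(pair: TestRetestPair) -> RepeatabilityRecord:
    """Build a repeatability record (dADC% and dVOL%) from a pair."""
    return RepeatabilityRecord(
        pair=pair,
        r12=percent_change(pair.roi_1.mean_adc, pair.roi_2.mean_adc),
        delta_vol_pct=percent_change(float(pair.roi_1.n_voxels),
                                     float(pair.roi_2.n_voxels)),
    )


def make_records(pairs: Iterable[TestRetestPair]) -> list[RepeatabilityRecord]:
    return [make_record(p) for p in pairs]


def within_subject_cov(pairs: Sequence[TestRetestPair], *,
                       ddof: int = 0) -> float:
    """Within-subject coefficient of variation, percent.

    Standard test-retest form: 100 x SD(within-pair ADC differences) /
    (sqrt(2) x grand mean of all session means).
    """
    if len(pairs) < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d1 = np.array([p.roi_1.mean_adc for p in pairs], dtype=float)
    d2 = np.array([p.roi_2.mean_adc for p in pairs], dtype=float)
    grand = float(np.concatenate([d1, d2]).mean())
    if not grand > 0:
        raise ValueError("grand mean must be > 0")
    return 100.0 * float((d1 - d2).std(ddof=ddof)) / (np.sqrt(2.0) * grand)


def within_subject_cov_from_summary(avg_adc: Sequence[float],
                                    r12_pct: Sequence[float], *,
                                    ddof: int = 0) -> float:
    """CoV recovered from per-pair session averages and R12 values.

    Given the pair average Dbar = (D1 + D2)/2 and R12 = 200 (D1 - D2) /
    (D1 + D2), the within-pair difference is D1 - D2 = R12 * Dbar / 100,
    so the CoV is computable from summary tables that publish only
    averages and percentage changes.
    """
    avg = np.asarray(avg_adc, dtype=float)
    r12 = np.asarray(r12_pct, dtype=float)
    if avg.size < 2 or avg.size != r12.size:
        raise InsufficientDataError("need matched avg_adc/r12 with n >= 2")
    diffs = r12 * avg / 100.0
    grand = float(avg.mean())
    if not grand > 0:
        raise ValueError("grand mean must be > 0")
    return 100.0 * float(diffs.std(ddof=ddof)) / (np.sqrt(2.0) * grand)
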