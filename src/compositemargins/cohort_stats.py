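"""Cohort-level statistics for margin studies.

Two questions are asked of a finished cohort: do the two image-matching
protocols produce systematically different overlap distributions (paired,
two-sided Wilcoxon signed-rank per margin increment), and are the
per-patient m95 margins normal enough for the x_bar + 1.28 s aggregation
to be meaningful (Shapiro-Wilk screen)?

No multiple-testing correction is applied across margin increments; each
increment's p-value is reported as-is, which overstates family-wise
significance when many increments are read together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError
from .margin_engine import PatientMarginRecord

EXACT_TEST_MAX_N = 25
ALPHA = 0.05

__all__ = [
    "PairedOverlapSample",
    "WilcoxonResult",
    "NormalityResult",
    "compare_protocols",
    "normality_check",
    "summarize_cohort",
]


@dataclass(frozen=True)
class PairedOverlapSample:
    """Per-patient % overlaps under both protocols at one margin increment."""

    margin_mm: float
    patient_ids: tuple[str, ...]
    bone: tuple[float, ...]
    soft_tissue: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.patient_ids) == len(self.bone) == len(self.soft_tissue)):
            raise ValueError("patient ids and both overlap arms must align")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_informative: int
    degenerate: bool  # all paired differences were zero


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool  # p >= 0.05: no evidence against normality


def compare_protocols(sample: PairedOverlapSample) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test between the two matching protocols.

    Zero differences are dropped before ranking; ties are mid-ranked. The
    exact null distribution is used for up to 25 informative tie-free pairs,
    the normal approximation with continuity correction otherwise. An
    all-zero difference vector is degenerate: p = 1 by convention, flagged.
    """
    bone = np.asarray(sample.bone, dtype=float)
    st = np.asarray(sample.soft_tissue, dtype=float)
    diffs = bone - st
    informative = diffs[diffs != 0]
    if informative.size == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_informative=0, degenerate=True
        )
    ties = np.unique(np.abs(informative)).size < informative.size
    method = "exact" if (informative.size <= EXACT_TEST_MAX_N and not ties) else "approx"
    res = stats.wilcoxon(
        bone,
        st,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_informative=int(informative.size),
        degenerate=False,
    )


def normality_check(
    records: Sequence[PatientMarginRecord] | Sequence[float],
) -> NormalityResult:
    """Shapiro-Wilk screen of per-patient margins.

    Gates whether the normal-theory population margin is reported with or
    without a non-normality warning; it never blocks aggregation.
    """
    values = np.array(
        [r.m95 if isinstance(r, PatientMarginRecord) else float(r) for r in records],
        dtype=float,
    )
    if values.size < 3:
        raise DegenerateSampleError(
            f"Shapiro-Wilk needs at least 3 observations, got {values.size}"
        )
    if values.size > 5000:
        raise DegenerateSampleError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(values) == 0:
        raise DegenerateSampleError(
            "all margins identical; Shapiro-Wilk statistic undefined"
        )
    stat, p = stats.shapiro(values)
    return NormalityResult(
        statistic=float(stat), p_value=float(p), normal=bool(p >= ALPHA)
    )


def summarize_cohort(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Per structure x protocol summary of the cohort.

    ``per_patient`` is the tidy per-patient table produced by a study run,
    with columns ``patient_id, structure, protocol, pct_volume_cm3,
    composite_ratio, overlap_at_5mm_pct, m95_mm``. Returns mean and SD of
    each quantity per (structure, protocol) cell — planning volume, the
    composite/planning volume ratio, % overlap at a 5 mm margin, and the
    individual 95%-overlap margins. SDs of single-patient cells are NaN
    (explicitly absent), never silently zero.
    """
    required = {
        "patient_id",
        "structure",
        "protocol",
        "pct_volume_cm3",
        "composite_ratio",
        "overlap_at_5mm_pct",
        "m95_mm",
    }
    missing = required - set(per_patient.columns)
    if missing:
        raise ValueError(f"per-patient table missing columns: {sorted(missing)}")
    grouped = per_patient.groupby(["structure", "protocol"], sort=True)
    rows = []
    for (structure, protocol), g in grouped:
        row: dict[str, object] = {
            "structure": structure,
            "protocol": protocol,
            "n_patients": int(g["patient_id"].nunique()),
        }
        for col, out in [
            ("pct_volume_cm3", "pct_volume_cm3"),
            ("composite_ratio", "composite_ratio"),
            ("overlap_at_5mm_pct", "overlap_at_5mm_pct"),
            ("m95_mm", "m95_mm"),
        ]:
            vals = g[col].astype(float)
            row[f"{out}_mean"] = float(vals.mean())
            row[f"{out}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
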