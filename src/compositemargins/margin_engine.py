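"""Margin sweeps, 95%-overlap interpolation, and population margins.

The per-patient quantity is m95: the smallest uniform expansion of the
planning CTV whose PTV covers 95% of the composite structure. The cohort
margin follows the normal-theory coverage rule

    margin = x_bar + 1.28 * s

(the margin achieving the per-patient criterion in 90% of a normally
distributed population), with the classical recipe

    margin = 2.5 * Sigma + 0.7 * sigma

available as a comparator for rigid, single-target geometries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np

from .errors import AggregationError, NonConvergenceError
from .mask_geometry import CompositeStructure, StructureMask, distance_map, overlap_fraction

DEFAULT_MARGINS_MM: tuple[float, ...] = tuple(float(m) for m in range(0, 13))
SWEEP_CAP_MM = 50.0
COVERAGE_FACTOR = 1.28  # 90% population coverage under normality

__all__ = [
    "DEFAULT_MARGINS_MM",
    "SWEEP_CAP_MM",
    "MarginSweepResult",
    "PatientMarginRecord",
    "PopulationMarginSummary",
    "ErrorComponents",
    "margin_sweep",
    "margin_at_threshold",
    "derive_patient_margin",
    "population_margin",
    "population_margin_from_moments",
    "vanherk_margin",
    "composite_ratio",
    "round_margin_mm",
]


@dataclass(frozen=True)
class MarginSweepResult:
    """(margin, % overlap) pairs for one structure under one protocol."""

    structure_label: str
    protocol: str
    increments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        margins = [m for m, _ in self.increments]
        if any(m2 <= m1 for m1, m2 in zip(margins, margins[1:])):
            raise ValueError("sweep margins must be strictly increasing")
        if any(not 0.0 <= o <= 100.0 for _, o in self.increments):
            raise ValueError("overlaps must lie in [0, 100]")

    def overlap_at(self, margin: float) -> float:
        for m, o in self.increments:
            if m == margin:
                return o
        raise KeyError(f"margin {margin} mm not in sweep")


@dataclass(frozen=True)
class PatientMarginRecord:
    """Interpolated margin (mm) achieving the overlap threshold for one patient."""

    patient_id: str
    structure_label: str
    protocol: str
    m95: float

    def __post_init__(self) -> None:
        if self.m95 < 0:
            raise ValueError("m95 must be >= 0")


@dataclass(frozen=True)
class PopulationMarginSummary:
    """Cohort mean, SD and coverage margin for one structure/protocol."""

    structure_label: str
    protocol: str
    n_patients: int
    mean_mm: float
    sd_mm: float
    margin_mm: float  # round_margin_mm(mean + 1.28 * sd)


@dataclass(frozen=True)
class ErrorComponents:
    """Systematic (Sigma, between-patient) and random (sigma, between-fraction)
    displacement SDs in mm — the inputs of the classical margin recipe."""

    sigma_sys: float
    sigma_rand: float

    def __post_init__(self) -> None:
        if self.sigma_sys < 0 or self.sigma_rand < 0:
            raise ValueError("error components must be >= 0")


def round_margin_mm(value: float) -> float:
    """Round a margin to 0.1 mm, half away from zero."""
    # pre-round to cut float noise like 58.4999999 from x*10
    q = Decimal(f"{value:.6f}").quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def margin_sweep(
    ctv: StructureMask,
    composite: CompositeStructure,
    margins: Sequence[float] | None = None,
) -> MarginSweepResult:
    """Measure % overlap of the expanded CTV with the composite at each margin.

    Equivalent to ``overlap_fraction(expand_isotropic(ctv, m), composite)``
    per increment; implemented with a single distance transform of the CTV so
    the whole sweep costs one EDT plus one threshold count per increment.
    """
    if margins is None:
        margins = DEFAULT_MARGINS_MM
    margins = [float(m) for m in margins]
    if any(m < 0 for m in margins):
        raise ValueError("sweep margins must be >= 0")
    dist = distance_map(ctv)
    pairs = tuple(
        (m, _overlap_at_distance(dist, composite, m)) for m in margins
    )
    return MarginSweepResult(
        structure_label=ctv.label or composite.mask.label,
        protocol=composite.protocol,
        increments=pairs,
    )


def _overlap_at_distance(
    dist: np.ndarray, composite: CompositeStructure, margin: float
) -> float:
    ptv = StructureMask(
        grid=composite.mask.grid, occupancy=dist <= margin, label=""
    )
    return overlap_fraction(ptv, composite)


def margin_at_threshold(
    sweep: MarginSweepResult,
    threshold: float = 95.0,
    extend_fn: Callable[[float], float] | None = None,
    step: float = 1.0,
    cap: float = SWEEP_CAP_MM,
) -> tuple[float, MarginSweepResult]:
    """Linearly interpolate the margin achieving ``threshold`` % overlap.

    Uses the first pair of consecutive increments (m1, o1), (m2, o2) with
    o1 < threshold <= o2. If the smallest margin already meets the
    threshold, that margin is returned (0 for a sweep starting at 0) rather
    than extrapolating below it. If the threshold is unmet at the last
    increment and ``extend_fn`` (margin -> overlap %) is given, the sweep is
    extended in ``step`` mm increments up to ``cap``; exhausting the cap
    raises :class:`~compositemargins.errors.NonConvergenceError`.

    Returns the interpolated margin and the (possibly extended) sweep.
    """
    if not sweep.increments:
        raise ValueError("sweep is empty")
    pairs = list(sweep.increments)
    if pairs[0][1] >= threshold:
        return pairs[0][0], sweep
    while True:
        for (m1, o1), (m2, o2) in zip(pairs, pairs[1:]):
            if o1 < threshold <= o2:
                m = m1 + (threshold - o1) * (m2 - m1) / (o2 - o1)
                return m, _with_increments(sweep, pairs)
        last_m = pairs[-1][0]
        if extend_fn is None or last_m + step > cap + 1e-9:
            raise NonConvergenceError(
                f"{threshold}% overlap not reached for structure "
                f"{sweep.structure_label!r} ({sweep.protocol}) within "
                f"{last_m:g} mm (cap {cap:g} mm)"
            )
        nxt = last_m + step
        pairs.append((nxt, float(extend_fn(nxt))))


def _with_increments(
    sweep: MarginSweepResult, pairs: list[tuple[float, float]]
) -> MarginSweepResult:
    if len(pairs) == len(sweep.increments):
        return sweep
    return MarginSweepResult(
        structure_label=sweep.structure_label,
        protocol=sweep.protocol,
        increments=tuple(pairs),
    )


def derive_patient_margin(
    patient_id: str,
    ctv: StructureMask,
    composite: CompositeStructure,
    threshold: float = 95.0,
    margins: Sequence[float] | None = None,
    step: float = 1.0,
    cap: float = SWEEP_CAP_MM,
) -> tuple[PatientMarginRecord, MarginSweepResult]:
    """Sweep, auto-extend and interpolate in one call for one patient.

    The sweep's distance transform is reused for any extension increments,
    so pathological patients that need margins past the default 12 mm cost
    one threshold count per extra millimetre, not one expansion.
    """
    if margins is None:
        margins = DEFAULT_MARGINS_MM
    dist = distance_map(ctv)
    pairs = tuple(
        (float(m), _overlap_at_distance(dist, composite, float(m))) for m in margins
    )
    sweep = MarginSweepResult(
        structure_label=ctv.label or composite.mask.label,
        protocol=composite.protocol,
        increments=pairs,
    )
    m95, sweep = margin_at_threshold(
        sweep,
        threshold=threshold,
        extend_fn=lambda m: _overlap_at_distance(dist, composite, m),
        step=step,
        cap=cap,
    )
    record = PatientMarginRecord(
        patient_id=patient_id,
        structure_label=sweep.structure_label,
        protocol=sweep.protocol,
        m95=m95,
    )
    return record, sweep


def population_margin(
    records: Sequence[PatientMarginRecord],
) -> PopulationMarginSummary:
    """Aggregate per-patient m95 values into the cohort coverage margin.

    Sample (n-1) standard deviation; margin = mean + 1.28 * SD reported to
    0.1 mm, half away from zero.
    """
    if len(records) < 2:
        raise AggregationError("population margin needs >= 2 patient records")
    labels = {r.structure_label for r in records}
    protocols = {r.protocol for r in records}
    if len(labels) > 1 or len(protocols) > 1:
        raise AggregationError(
            f"records mix structures {sorted(labels)} / protocols {sorted(protocols)}"
        )
    values = np.array([r.m95 for r in records], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return PopulationMarginSummary(
        structure_label=labels.pop(),
        protocol=protocols.pop(),
        n_patients=len(records),
        mean_mm=mean,
        sd_mm=sd,
        margin_mm=round_margin_mm(mean + COVERAGE_FACTOR * sd),
    )


def population_margin_from_moments(mean_mm: float, sd_mm: float) -> float:
    """Coverage margin (mm, rounded to 0.1) from a cohort mean and SD of m95."""
    if sd_mm < 0:
        raise ValueError("sd must be >= 0")
    return round_margin_mm(mean_mm + COVERAGE_FACTOR * sd_mm)


def vanherk_margin(err: ErrorComponents) -> float:
    """Classical population margin recipe 2.5*Sigma + 0.7*sigma (mm).

    Assumes a rigid spherical target, translational errors only, and an
    effectively infinite number of fractions; used here purely as a
    comparator for the composite-volume margins.
    """
    return 2.5 * err.sigma_sys + 0.7 * err.sigma_rand


def composite_ratio(
    composite: CompositeStructure, pct_ctv: StructureMask
) -> float:
    """Composite volume divided by planning CTV volume (dimensionless).

    >= 1 whenever the composite fully covers the planning structure (e.g.
    when the planning contours are one of the union's generators).
    """
    v_plan = pct_ctv.voxel_count
    if v_plan == 0:
        raise ZeroDivisionError("planning CTV has zero volume; ratio undefined")
    return composite.mask.voxel_count / v_plan
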