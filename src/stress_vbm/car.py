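"""Cortisol awakening response (CAR): sample QC, AUC measures, group tests.

The waking protocol collects three saliva samples at 0, 30 and 60 minutes
after awakening. A subject's response is summarised by Pruessner's two
area-under-the-curve measures over that hour:

    AUCg = 15 * (c0 + 2*c30 + c60)        (trapezoid, area w.r.t. ground)
    AUCi = AUCg - 60 * c0                 (area w.r.t. the waking baseline)

in nmol*min/l, together with the 30-minute rise Delta30 = c30 - c0. A series
is excluded from analysis when a sample is missing, has very low saliva
volume, was collected too far from its nominal time point, or when Delta30
is negative (a marker of delayed first-sample collection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ContractViolationError,
    DegenerateVarianceError,
    MalformedInputError,
)

NOMINAL_TIMES = (0, 30, 60)

#: default QC parameters
VOLUME_FLOOR_UL = 200.0
TIMING_TOLERANCE_MIN = 15.0

#: QC reason codes
MISSING_SAMPLE = "missing_sample"
LOW_VOLUME = "low_volume"
TIMING_DEVIATION = "timing_deviation"
NEGATIVE_DELTA30 = "negative_delta30"


@dataclass(frozen=True)
class CortisolSample:
    """One timed saliva sample.

    ``actual_time_min`` may be ``None`` when the subject did not report a
    collection time; by default such samples are treated as on time.
    """

    subject_id: str
    nominal_time_min: int
    concentration_nmol_l: float
    volume_ul: float
    actual_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.nominal_time_min not in NOMINAL_TIMES:
            raise MalformedInputError(
                f"nominal time {self.nominal_time_min} not in {NOMINAL_TIMES}"
            )
        if self.concentration_nmol_l < 0:
            raise MalformedInputError("cortisol concentration must be >= 0")
        if self.volume_ul < 0:
            raise MalformedInputError("saliva volume must be >= 0")


@dataclass
class SubjectCortisolSeries:
    """The (up to) three samples of one subject, keyed by nominal time."""

    subject_id: str
    samples: dict[int, CortisolSample] = field(default_factory=dict)

    @classmethod
    def from_samples(
        cls, subject_id: str, samples: Iterable[CortisolSample]
    ) -> "SubjectCortisolSeries":
        out: dict[int, CortisolSample] = {}
        for s in samples:
            if s.nominal_time_min in out:
                raise MalformedInputError(
                    f"subject {subject_id}: duplicate nominal time "
                    f"{s.nominal_time_min}"
                )
            out[s.nominal_time_min] = s
        return cls(subject_id=subject_id, samples=out)

    def concentration(self, nominal_time_min: int) -> float | None:
        s = self.samples.get(nominal_time_min)
        return None if s is None else s.concentration_nmol_l


@dataclass
class CarResult:
    """QC verdict and, for passing series, the CAR summary measures."""

    subject_id: str
    qc_pass: bool
    qc_reasons: list[str]
    auc_g: float | None = None
    auc_i: float | None = None
    delta30: float | None = None


@dataclass
class GroupTestResult:
    t_statistic: float
    df: int
    p_two_sided: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def qc_filter(
    series: SubjectCortisolSeries,
    volume_floor_ul: float = VOLUME_FLOOR_UL,
    timing_tolerance_min: float = TIMING_TOLERANCE_MIN,
    strict_timing: bool = False,
) -> CarResult:
    """Apply the exclusion rules and return the QC verdict.

    Rules (each contributes an independent reason code):

    * ``missing_sample`` — any of the three nominal time points absent;
    * ``low_volume`` — any sample with volume < ``volume_floor_ul`` (µl);
    * ``timing_deviation`` — any sample collected more than
      ``timing_tolerance_min`` minutes before or after its nominal time
      (the boundary itself passes); a missing self-reported time is treated
      as on time unless ``strict_timing``;
    * ``negative_delta30`` — c30 < c0 (delayed first sample).

    Excluded subjects carry no AUC values.
    """
    reasons: list[str] = []
    missing = [t for t in NOMINAL_TIMES if t not in series.samples]
    if missing:
        reasons.append(MISSING_SAMPLE)
    for t in NOMINAL_TIMES:
        s = series.samples.get(t)
        if s is None:
            continue
        if s.volume_ul < volume_floor_ul:
            if LOW_VOLUME not in reasons:
                reasons.append(LOW_VOLUME)
        if s.actual_time_min is None:
            if strict_timing and TIMING_DEVIATION not in reasons:
                reasons.append(TIMING_DEVIATION)
        elif abs(s.actual_time_min - t) > timing_tolerance_min:
            if TIMING_DEVIATION not in reasons:
                reasons.append(TIMING_DEVIATION)
    c0 = series.concentration(0)
    c30 = series.concentration(30)
    if c0 is not None and c30 is not None and c30 - c0 < 0:
        reasons.append(NEGATIVE_DELTA30)

    if reasons:
        return CarResult(series.subject_id, qc_pass=False, qc_reasons=reasons)
    return compute_car(series, _checked=True)


def compute_car(
    series: SubjectCortisolSeries, _checked: bool = False
) -> CarResult:
    """Compute AUCg, AUCi and Delta30 for a series that passes QC.

    AUCg is the trapezoidal area of concentration against nominal time over
    [0, 60] minutes, AUCi the same area above the waking baseline:
    ``auc_i == auc_g - 60 * c0`` identically.
    """
    if not _checked:
        verdict = qc_filter(series)
        if not verdict.qc_pass:
            raise ContractViolationError(
                f"subject {series.subject_id} failed QC "
                f"({', '.join(verdict.qc_reasons)}); CAR is undefined"
            )
        return verdict
    c0 = series.concentration(0)
    c30 = series.concentration(30)
    c60 = series.concentration(60)
    assert c0 is not None and c30 is not None and c60 is not None
    auc_g = 15.0 * (c0 + 2.0 * c30 + c60)
    auc_i = auc_g - 60.0 * c0
    return CarResult(
        series.subject_id,
        qc_pass=True,
        qc_reasons=[],
        auc_g=auc_g,
        auc_i=auc_i,
        delta30=c30 - c0,
    )


def car_table(
    series_list: Sequence[SubjectCortisolSeries],
    volume_floor_ul: float = VOLUME_FLOOR_UL,
    timing_tolerance_min: float = TIMING_TOLERANCE_MIN,
    strict_timing: bool = False,
) -> pd.DataFrame:
    """QC and CAR measures for a cohort, one row per subject."""
    rows = []
    for series in series_list:
        r = qc_filter(
            series,
            volume_floor_ul=volume_floor_ul,
            timing_tolerance_min=timing_tolerance_min,
            strict_timing=strict_timing,
        )
        rows.append(
            {
                "subject_id": r.subject_id,
                "qc_pass": r.qc_pass,
                "qc_reasons": ";".join(r.qc_reasons),
                "auc_g": r.auc_g,
                "auc_i": r.auc_i,
                "delta30": r.delta30,
            }
        )
    return pd.DataFrame(rows)


def series_from_table(samples: pd.DataFrame) -> list[SubjectCortisolSeries]:
    """Group a long-format cortisol sample table into per-subject series.

    Expected columns: subject_id, nominal_time_min, actual_time_min,
    volume_ul, cortisol_nmol_l. NaN concentration/volume rows denote a
    missing sample and are dropped (the QC stage flags the gap).
    """
    required = {
        "subject_id",
        "nominal_time_min",
        "actual_time_min",
        "volume_ul",
        "cortisol_nmol_l",
    }
    missing_cols = required - set(samples.columns)
    if missing_cols:
        raise MalformedInputError(
            f"cortisol table missing columns: {sorted(missing_cols)}"
        )
    out = []
    for sid, grp in samples.groupby("subject_id", sort=True):
        samps = []
        for row in grp.itertuples(index=False):
            if pd.isna(row.cortisol_nmol_l) or pd.isna(row.volume_ul):
                continue
            actual = None if pd.isna(row.actual_time_min) else float(row.actual_time_min)
            samps.append(
                CortisolSample(
                    subject_id=str(sid),
                    nominal_time_min=int(row.nominal_time_min),
                    concentration_nmol_l=float(row.cortisol_nmol_l),
                    volume_ul=float(row.volume_ul),
                    actual_time_min=actual,
                )
            )
        out.append(SubjectCortisolSeries.from_samples(str(sid), samps))
    return out


def pooled_t_test(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    welch: bool = False,
) -> GroupTestResult:
    """Two-sample two-tailed t-test from summary statistics.

    The default is the pooled-variance Student t with df = n_a + n_b - 2;
    ``welch=True`` uses the Welch–Satterthwaite unequal-variance form.
    """
    if n_a < 2 or n_b < 2:
        raise ContractViolationError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ContractViolationError("standard deviations must be >= 0")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            df = n_a + n_b - 2
            return GroupTestResult(0.0, df, 1.0, mean_a, mean_b, sd_a, sd_b, n_a, n_b)
        raise DegenerateVarianceError(
            "both groups have zero variance and different means"
        )
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        t = (mean_a - mean_b) / math.sqrt(va + vb)
        df_w = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        p = 2.0 * stats.t.sf(abs(t), df_w)
        return GroupTestResult(t, df_w, p, mean_a, mean_b, sd_a, sd_b, n_a, n_b)
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupTestResult(t, df, p, mean_a, mean_b, sd_a, sd_b, n_a, n_b)


def pooled_t_test_values(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> GroupTestResult:
    """Same test computed from raw value vectors (sample SD, ddof=1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    return pooled_t_test(
        float(a.mean()),
        float(a.std(ddof=1)),
        a.size,
        float(b.mean()),
        float(b.std(ddof=1)),
        b.size,
        welch=welch,
    )


def detect_outliers(
    values: Sequence[float], z_threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Standard scores against the full sample, flagging ``|z| > threshold``.

    The candidate itself is included in the mean/SD (sample SD, ddof=1),
    matching the convention of screening a full sample for extreme values.

    Returns ``(flags, z_scores)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ContractViolationError("outlier detection needs >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("values have no spread; z undefined")
    z = (x - x.mean()) / sd
    return np.abs(z) > z_threshold, z
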