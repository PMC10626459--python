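"""Clinical validation statistics for formula-predicted IOL powers.

The clinically required IOL power for emmetropia is reconstructed
retrospectively as the implanted power plus the postoperative best
spectacle spherical correction (plain signed addition at the spectacle
plane; no vertex-distance or IOL-plane magnification correction).  The
formula's prediction error per eye is theoretical minus clinical-required
power; the group level summaries are

* mean +/- SD (sample, n-1 denominator) of both power columns,
* mean absolute error (MAE) +/- SD,
* counts in the half-open absolute-error bands
  [0, 0.5), [0.5, 1.0), [1.0, 1.5), [1.5, 2.0), [2.0, inf),
* a paired t-test between theoretical and clinical powers, and
* the two-way mixed-effects, consistency, single-measures intraclass
  correlation ICC(3,1) with its classical F-based confidence interval.

ICC(3,1) comes from the two-way ANOVA of the n x 2 (eyes x methods) grid:
with MSR the between-subjects and MSE the residual mean square,
ICC = (MSR - MSE) / (MSR + (k-1) MSE), k = 2.  Consistency ICC ignores a
constant additive offset between the methods, which is the right notion
when comparing a formula against a clinical reconstruction that may carry
a systematic bias.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats

from .datasets import BiometryRecord
from .errors import InputValidationError

__all__ = [
    "OutcomeRecord",
    "PredictionErrorTable",
    "IccResult",
    "VaSummary",
    "ValidationReport",
    "required_clinical_power",
    "prediction_errors",
    "mae",
    "error_band_counts",
    "icc_consistency_single",
    "icc_confidence_interval",
    "paired_t_test",
    "shapiro_normality",
    "summarize_group",
    "va_summary",
    "ERROR_BAND_EDGES",
]

#: Half-open absolute-error band edges in diopters.
ERROR_BAND_EDGES = (0.0, 0.5, 1.0, 1.5, 2.0, math.inf)


@dataclass(frozen=True)
class OutcomeRecord:
    """Formula prediction and clinical outcome for one eye."""

    patient_id: str
    theoretical_power_d: float
    implanted_power_d: float
    postop_sphere_d: float
    mean_k_d: float
    va_preop_uncorrected: float | None = None
    va_preop_corrected: float | None = None
    va_postop_corrected: float | None = None

    def __post_init__(self) -> None:
        for name in ("theoretical_power_d", "implanted_power_d"):
            v = getattr(self, name)
            if not (0.0 < v < 40.0):
                raise InputValidationError(f"{self.patient_id}: {name}={v} outside (0, 40)")
        if not (-15.0 < self.postop_sphere_d < 15.0):
            raise InputValidationError(
                f"{self.patient_id}: postop_sphere_d={self.postop_sphere_d} outside (-15, 15)"
            )

    @classmethod
    def from_biometry(cls, record: BiometryRecord) -> "OutcomeRecord":
        if record.theoretical_power_d is None:
            raise InputValidationError(
                f"{record.patient_id}: no theoretical power recorded"
            )
        return cls(
            patient_id=record.patient_id,
            theoretical_power_d=record.theoretical_power_d,
            implanted_power_d=record.implanted_power_d,
            postop_sphere_d=record.postop_sphere_d,
            mean_k_d=record.mean_k_d,
            va_preop_uncorrected=record.va_preop_uc,
            va_preop_corrected=record.va_preop_cc,
            va_postop_corrected=record.va_postop_cc,
        )


@dataclass(frozen=True)
class PredictionErrorTable:
    """Per-eye theoretical vs clinical-required powers and derived errors."""

    patient_ids: tuple[str, ...]
    theoretical_d: tuple[float, ...]
    clinical_required_d: tuple[float, ...]
    signed_error_d: tuple[float, ...]
    abs_error_d: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.patient_ids)


def required_clinical_power(implanted_power_d: float, postop_sphere_d: float) -> float:
    """Clinical IOL power required for emmetropia: implanted + sphere.

    Plain signed addition of the spectacle spherical correction to the
    implanted power; deliberately no vertex or IOL-plane conversion.
    """
    if not (math.isfinite(implanted_power_d) and math.isfinite(postop_sphere_d)):
        raise InputValidationError("powers must be finite")
    return implanted_power_d + postop_sphere_d


def prediction_errors(records: list[OutcomeRecord]) -> PredictionErrorTable:
    """Assemble the per-eye prediction-error table (signed = theoretical - clinical)."""
    if not records:
        raise InputValidationError("no records")
    clinical = [
        required_clinical_power(r.implanted_power_d, r.postop_sphere_d) for r in records
    ]
    signed = [r.theoretical_power_d - c for r, c in zip(records, clinical)]
    return PredictionErrorTable(
        patient_ids=tuple(r.patient_id for r in records),
        theoretical_d=tuple(r.theoretical_power_d for r in records),
        clinical_required_d=tuple(clinical),
        signed_error_d=tuple(signed),
        abs_error_d=tuple(abs(s) for s in signed),
    )


def mae(table: PredictionErrorTable) -> tuple[float, float]:
    """Mean absolute error and its sample SD, diopters."""
    if len(table) < 2:
        raise InputValidationError("SD undefined for fewer than 2 records")
    ae = np.asarray(table.abs_error_d)
    return float(ae.mean()), float(ae.std(ddof=1))


def error_band_counts(table: PredictionErrorTable) -> tuple[int, int, int, int, int]:
    """Counts of absolute errors in the five half-open diopter bands."""
    if len(table) < 1:
        raise InputValidationError("empty table")
    counts, _ = np.histogram(table.abs_error_d, bins=ERROR_BAND_EDGES)
    return tuple(int(c) for c in counts)  # type: ignore[return-value]


def _two_way_mean_squares(x, y):
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    grand = data.mean()
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return n, k, msr, mse


@dataclass(frozen=True)
class IccResult:
    icc: float
    msr: float
    mse: float
    n: int
    k: int
    degenerate: bool = False


def icc_consistency_single(x, y) -> IccResult:
    """ICC(3,1): two-way mixed, consistency, single measures, for k = 2 raters.

    ``(MSR - MSE) / (MSR + (k-1) MSE)`` from the eyes-by-methods ANOVA.
    Zero between-subject variance is flagged as degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputValidationError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise InputValidationError("ICC needs at least 3 subjects")
    n, k, msr, mse = _two_way_mean_squares(x, y)
    if msr <= 0:
        warnings.warn("zero between-subject variance: ICC degenerate", stacklevel=2)
        return IccResult(icc=float("nan"), msr=msr, mse=mse, n=n, k=k, degenerate=True)
    icc = (msr - mse) / (msr + (k - 1) * mse)
    return IccResult(icc=float(icc), msr=float(msr), mse=float(mse), n=n, k=k)


def icc_confidence_interval(result: IccResult, alpha: float = 0.05) -> tuple[float, float]:
    """Classical F-based (1-alpha) confidence bounds for ICC(3,1).

    F0 = MSR/MSE with (n-1) and (n-1)(k-1) df;
    FL = F0 / F_{1-alpha/2}(n-1, (n-1)(k-1)),
    FU = F0 * F_{1-alpha/2}((n-1)(k-1), n-1);
    each bound maps through (F - 1) / (F + k - 1).
    """
    if not (0.0 < alpha < 1.0):
        raise InputValidationError(f"alpha={alpha} outside (0, 1)")
    df1 = result.n - 1
    df2 = (result.n - 1) * (result.k - 1)
    if df1 < 1 or df2 < 1:
        raise InputValidationError("insufficient degrees of freedom for the ICC CI")
    if result.degenerate or result.mse == 0:
        raise InputValidationError("degenerate ANOVA: CI undefined")
    f0 = result.msr / result.mse
    fl = f0 / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    fu = f0 * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    k = result.k
    return float((fl - 1.0) / (fl + k - 1.0)), float((fu - 1.0) / (fu + k - 1.0))


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired two-sided t-test; returns (t, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise InputValidationError("paired t needs equal-length series, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: p undefined", stacklevel=2)
        return 0.0 if np.allclose(d, 0) else math.copysign(math.inf, d.mean()), float("nan")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def shapiro_normality(values) -> tuple[float, float]:
    """Advisory Shapiro-Wilk normality check; returns (W, p)."""
    res = stats.shapiro(np.asarray(values, float))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class VaSummary:
    """logMAR visual-acuity means/SDs at three stages, with stage-to-stage t-tests."""

    preop_uncorrected: tuple[float, float]
    preop_corrected: tuple[float, float]
    postop_corrected: tuple[float, float]
    t_uc_vs_cc: tuple[float, float]
    t_cc_vs_postop: tuple[float, float]
    n: int


@dataclass(frozen=True)
class ValidationReport:
    """Group-level summary of a validation run; serializes to JSON/TSV."""

    n: int
    mean_theoretical: float
    sd_theoretical: float
    mean_clinical: float
    sd_clinical: float
    mae: float
    sd_abs_error: float
    band_counts: tuple[int, int, int, int, int]
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    t_statistic: float
    p_two_sided: float
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    def to_tsv(self) -> str:
        d = asdict(self)
        d["band_counts"] = ",".join(str(c) for c in self.band_counts)
        d["notes"] = "; ".join(self.notes)
        keys = list(d)
        return "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"


def summarize_group(
    records: list[OutcomeRecord], notes: tuple[str, ...] = ()
) -> ValidationReport:
    """Compose the full group-level validation report."""
    if len(records) < 3:
        raise InputValidationError("need at least 3 records to summarize")
    table = prediction_errors(records)
    theo = np.asarray(table.theoretical_d)
    clin = np.asarray(table.clinical_required_d)
    mean_ae, sd_ae = mae(table)
    icc_res = icc_consistency_single(theo, clin)
    if icc_res.degenerate:
        ci = (float("nan"), float("nan"))
        notes = notes + ("ICC degenerate: zero between-subject variance",)
    else:
        ci = icc_confidence_interval(icc_res)
    t, p = paired_t_test(theo, clin)
    return ValidationReport(
        n=len(records),
        mean_theoretical=float(theo.mean()),
        sd_theoretical=float(theo.std(ddof=1)),
        mean_clinical=float(clin.mean()),
        sd_clinical=float(clin.std(ddof=1)),
        mae=mean_ae,
        sd_abs_error=sd_ae,
        band_counts=error_band_counts(table),
        icc=icc_res.icc,
        icc_ci_low=ci[0],
        icc_ci_high=ci[1],
        t_statistic=t,
        p_two_sided=p,
        notes=notes,
    )


def va_summary(records: list[OutcomeRecord]) -> VaSummary:
    """Visual-acuity summaries across the three recorded stages.

    Missing values are excluded pairwise (with a warning); the paired
    t-tests use only eyes with both stages present.
    """
    cols = {
        "uc": [r.va_preop_uncorrected for r in records],
        "cc": [r.va_preop_corrected for r in records],
        "post": [r.va_postop_corrected for r in records],
    }
    if all(v is None for v in cols["uc"] + cols["cc"] + cols["post"]):
        raise InputValidationError("no visual-acuity columns present")

    def mean_sd(vals):
        arr = np.asarray([v for v in vals if v is not None], float)
        if arr.size < 2:
            raise InputValidationError("fewer than 2 VA values in a column")
        return float(arr.mean()), float(arr.std(ddof=1))

    def paired(a, b):
        pairs = [(x, y) for x, y in zip(a, b) if x is not None and y is not None]
        if len(pairs) < len(a):
            warnings.warn(
                f"{len(a) - len(pairs)} eyes excluded pairwise for missing VA",
                stacklevel=2,
            )
        xs, ys = zip(*pairs)
        return paired_t_test(xs, ys)

    return VaSummary(
        preop_uncorrected=mean_sd(cols["uc"]),
        preop_corrected=mean_sd(cols["cc"]),
        postop_corrected=mean_sd(cols["post"]),
        t_uc_vs_cc=paired(cols["uc"], cols["cc"]),
        t_cc_vs_postop=paired(cols["cc"], cols["post"]),
        n=len(records),
    )
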