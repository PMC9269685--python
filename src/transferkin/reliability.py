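"""Intraclass correlation and Bland-Altman agreement statistics.

Both ICC forms are single-measure ICCs from the two-way ANOVA mean squares
of a complete targets x raters matrix (targets = subjects or trials, raters
= repeated trials or sensors):

* ``ICC_2_1`` — two-way random effects, absolute agreement (McGraw-Wong
  ICC(A,1)); used for inter-sensor reliability.  Systematic offsets between
  raters lower it.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

* ``ICC_3_1`` — two-way mixed effects, consistency (McGraw-Wong ICC(C,1));
  used for intra-sensor (repeated-trial) reliability.  It is insensitive to
  a fixed rater offset, so on offset data ICC(3,1) >= ICC(2,1).

    ICC = (MSR - MSE) / (MSR + (k-1) MSE)

95% confidence intervals use the exact F-distribution method.  ICC values
are banded as excellent (> 0.8), good [0.6, 0.8], moderate [0.4, 0.6),
fair [0.2, 0.4) or poor (< 0.2); only the excellent bound is strict.

Bland-Altman limits of agreement are m -/+ 1.96 s over the paired
differences (m = mean, s = sample SD); two instruments are deemed
interchangeable when at least 95% of differences fall within the limits.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ReliabilityError, UndefinedICCError

__all__ = [
    "MeasurementMatrix",
    "ICCResult",
    "BlandAltmanResult",
    "icc",
    "categorize_icc",
    "bland_altman",
    "bland_altman_plot",
    "reliability_report",
    "ReliabilityReport",
    "REPORT_COLUMNS",
]

ICC_MODELS = ("ICC_2_1", "ICC_3_1")

REPORT_COLUMNS = [
    "feature",
    "model",
    "icc",
    "ci_lower",
    "ci_upper",
    "category",
    "mean_a",
    "std_a",
    "mean_b",
    "std_b",
    "ba_m",
    "ba_s",
    "ba_inf",
    "ba_sup",
    "ba_within",
    "interchangeable",
]


@dataclass(frozen=True)
class MeasurementMatrix:
    """Complete targets x raters grid of one feature."""

    values: np.ndarray
    feature: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ReliabilityError("measurement matrix must be 2-D (targets x raters)")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ReliabilityError("need at least 2 targets and 2 raters")
        if not np.isfinite(values).all():
            raise ReliabilityError(
                "missing cells are not allowed; apply complete-case filtering upstream"
            )

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    model: str
    category: str
    n_targets: int
    n_raters: int
    msr: float
    msc: float
    mse: float


@dataclass(frozen=True)
class BlandAltmanResult:
    m: float  # mean of paired differences (a - b)
    s: float  # sample SD of differences (n - 1)
    infimum: float  # m - 1.96 s
    supremum: float  # m + 1.96 s
    within_fraction: float
    interchangeable: bool
    n: int
    means: np.ndarray = field(repr=False, default=None)  # (a + b)/2, plot x
    differences: np.ndarray = field(repr=False, default=None)  # a - b, plot y


def categorize_icc(value: float) -> str:
    """Reliability band of an ICC value (monotone step function)."""
    if not np.isfinite(value):
        raise ReliabilityError("cannot categorize a non-finite ICC")
    if value > 0.8:
        return "excellent"
    if value >= 0.6:
        return "good"
    if value >= 0.4:
        return "moderate"
    if value >= 0.2:
        return "fair"
    return "poor"


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (targets), columns (raters), residual."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    values: MeasurementMatrix | np.ndarray,
    model: str = "ICC_2_1",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measure ICC with an exact F-based confidence interval.

    Raises :class:`UndefinedICCError` when the matrix has zero total
    variance and :class:`ReliabilityError` for incomplete designs.
    """
    if not isinstance(values, MeasurementMatrix):
        values = MeasurementMatrix(np.asarray(values, dtype=float))
    if model not in ICC_MODELS:
        raise ReliabilityError(f"model must be one of {ICC_MODELS}, got {model!r}")
    x = values.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    if msr <= 0 and msc <= 0 and mse <= 0:
        raise UndefinedICCError("zero total variance: ICC undefined")

    if model == "ICC_3_1":
        denom = msr + (k - 1) * mse
        if denom <= 0:
            raise UndefinedICCError("zero variance in the consistency denominator")
        est = (msr - mse) / denom
        if mse == 0.0:
            lo = hi = est
        else:
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fobs = msr / mse
            fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:  # ICC_2_1, absolute agreement
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom <= 0:
            raise UndefinedICCError("zero variance in the agreement denominator")
        est = (msr - mse) / denom
        if mse == 0.0 and msc == 0.0:
            lo = hi = est
        else:
            r = est
            a = (k * r) / (n * (1 - r)) if r < 1 else np.inf
            b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else np.inf
            if not np.isfinite(a):
                lo = hi = est
            else:
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
                f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (
                    n * (msr - f_lo * mse)
                    / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                hi = (
                    n * (f_hi * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
                )

    est = float(min(est, 1.0))
    lo = float(min(lo, est))
    hi = float(min(max(hi, est), 1.0))
    return ICCResult(
        icc=est,
        ci_lower=lo,
        ci_upper=hi,
        model=model,
        category=categorize_icc(est),
        n_targets=n,
        n_raters=k,
        msr=msr,
        msc=msc,
        mse=mse,
    )


def bland_altman(a, b, z: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman limits of agreement for paired measurements ``a`` and ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ReliabilityError("paired lists must be 1-D and of equal length")
    if len(a) < 3:
        raise ReliabilityError("need at least 3 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ReliabilityError("non-finite values in paired lists")
    d = a - b
    m = float(d.mean())
    s = float(d.std(ddof=1))
    inf_, sup = m - z * s, m + z * s
    within = float(np.mean((d >= inf_) & (d <= sup)))
    return BlandAltmanResult(
        m=m,
        s=s,
        infimum=inf_,
        supremum=sup,
        within_fraction=within,
        interchangeable=within >= 0.95,
        n=len(d),
        means=(a + b) / 2.0,
        differences=d,
    )


def bland_altman_plot(result: BlandAltmanResult, ax=None, title: str = ""):
    """Render the classic mean-vs-difference plot with the limits of agreement."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=12, alpha=0.7)
    ax.axhline(result.m, color="k", lw=1, label=f"mean {result.m:.2f}")
    for y, lab in ((result.infimum, "infimum"), (result.supremum, "supremum")):
        ax.axhline(y, color="r", ls="--", lw=1, label=f"{lab} {y:.2f}")
    ax.set_xlabel("mean of sensors")
    ax.set_ylabel("difference (a - b)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


@dataclass
class ReliabilityReport:
    """Tables 3-6 style report: intra-sensor and inter-sensor sections."""

    intra: pd.DataFrame
    inter: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "intra": self.intra.to_dict(orient="records"),
            "inter": self.inter.to_dict(orient="records"),
            "warnings": list(self.warnings),
        }


def _pivot_intra(df: pd.DataFrame, feature: str) -> np.ndarray | None:
    """Subjects x trial-repetitions matrix, truncated to the common minimum."""
    rows = []
    counts = []
    for _, grp in df.groupby("subject_id", sort=False):
        vals = grp[feature].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        counts.append(len(vals))
        rows.append(vals)
    kmin = min(counts) if counts else 0
    if kmin < 2 or len(rows) < 2:
        return None
    return np.vstack([r[:kmin] for r in rows])


def reliability_report(
    features_by_sensor: dict[str, pd.DataFrame],
    feature_names: tuple[str, ...] = ("dswp", "lpoe", "le", "tf"),
) -> ReliabilityReport:
    """Full reliability battery over per-trial feature tables.

    ``features_by_sensor`` maps sensor label -> DataFrame with at least
    ``subject_id``, ``trial_id`` and the feature columns.  Per feature it
    computes the intra-sensor ICC(3,1) per sensor (targets = subjects,
    raters = trial repetitions truncated to the common minimum), the
    inter-sensor ICC(2,1) (targets = pooled trials, raters = sensors,
    complete-case), per-sensor mean/STD, and Bland-Altman limits for the
    first sensor pair.
    """
    if len(features_by_sensor) < 2:
        raise ReliabilityError("need at least 2 sensors for a reliability report")
    sensors = list(features_by_sensor)
    notes: list[str] = []

    intra_rows = []
    for sensor in sensors:
        df = features_by_sensor[sensor]
        for feature in feature_names:
            mat = _pivot_intra(df, feature)
            if mat is None:
                msg = (
                    f"intra-sensor ICC omitted for {sensor}/{feature}: fewer than "
                    "2 repeated trials per subject"
                )
                notes.append(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            res = icc(mat, model="ICC_3_1")
            intra_rows.append(
                {
                    "feature": feature,
                    "sensor": sensor,
                    "model": "ICC_3_1",
                    "icc": res.icc,
                    "ci_lower": res.ci_lower,
                    "ci_upper": res.ci_upper,
                    "category": res.category,
                    "n_targets": res.n_targets,
                    "n_raters": res.n_raters,
                }
            )
    intra = pd.DataFrame(intra_rows)
    if len(intra) and len(sensors) == 2:
        # Tables 3/5 "Diff." column: absolute ICC difference between sensors
        diff = (
            intra.pivot(index="feature", columns="sensor", values="icc")
            .diff(axis=1)
            .iloc[:, -1]
            .abs()
        )
        intra["diff_vs_other"] = intra["feature"].map(diff)

    inter_rows = []
    sa, sb = sensors[0], sensors[1]
    fa = features_by_sensor[sa].set_index(["subject_id", "trial_id"])
    fb = features_by_sensor[sb].set_index(["subject_id", "trial_id"])
    common = fa.index.intersection(fb.index)
    for feature in feature_names:
        va = fa.loc[common, feature].to_numpy(dtype=float)
        vb = fb.loc[common, feature].to_numpy(dtype=float)
        ok = np.isfinite(va) & np.isfinite(vb)  # complete-case pairing
        va, vb = va[ok], vb[ok]
        if len(va) < 3:
            notes.append(f"inter-sensor analysis omitted for {feature}: <3 pairs")
            continue
        res = icc(np.column_stack([va, vb]), model="ICC_2_1")
        ba = bland_altman(va, vb)
        inter_rows.append(
            {
                "feature": feature,
                "model": "ICC_2_1",
                "icc": res.icc,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "category": res.category,
                "mean_a": float(va.mean()),
                "std_a": float(va.std(ddof=1)),
                "mean_b": float(vb.mean()),
                "std_b": float(vb.std(ddof=1)),
                "ba_m": ba.m,
                "ba_s": ba.s,
                "ba_inf": ba.infimum,
                "ba_sup": ba.supremum,
                "ba_within": ba.within_fraction,
                "interchangeable": ba.interchangeable,
            }
        )
    inter = pd.DataFrame(inter_rows, columns=REPORT_COLUMNS)
    return ReliabilityReport(intra=intra, inter=inter, warnings=notes)
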