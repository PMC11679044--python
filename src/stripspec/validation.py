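"""Analytical-validation statistics for the strip-reader platform.

Three study designs are covered:

* **reproducibility** — intraday/interday replicate precision summarized as
  mean, SD and CV% with the assay-community classes
  (excellent CV < 10%, good 10–20%, poor otherwise);
* **interference** — paired t-tests of measured concentration with vs
  without a candidate interfering substance, significance at α = 0.05;
* **method agreement** — comparison against a reference method (e.g.
  LC-MS) via the intraclass correlation coefficient ICC(A,1), Pearson
  correlation and Bland–Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import (
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)

ALPHA = 0.05
LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass
class ReproducibilityResult:
    condition_label: str
    n: int
    mean_ppb: float
    sd_ppb: float
    cv_percent: float
    cv_class: str


@dataclass
class InterferenceResult:
    substance: str
    n_pairs: int
    mean_with: float
    mean_without: float
    t_statistic: float
    p_value: float
    significant: bool


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: list[float]
    differences: list[float]


@dataclass
class AgreementResult:
    n: int
    icc: float
    icc_class: str
    pearson_r: float
    bias: float
    loa_lower: float
    loa_upper: float


@dataclass
class ValidationReport:
    """Aggregate of the three validation sections; absent sections are
    listed in ``missing_sections`` rather than silently dropped."""

    reproducibility: list[ReproducibilityResult] = field(default_factory=list)
    interference: list[InterferenceResult] = field(default_factory=list)
    agreement: AgreementResult | None = None
    missing_sections: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reproducibility": [asdict(r) for r in self.reproducibility],
            "interference": [asdict(r) for r in self.interference],
            "agreement": None if self.agreement is None else asdict(self.agreement),
            "missing_sections": list(self.missing_sections),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ValidationReport":
        return cls(
            reproducibility=[
                ReproducibilityResult(**r) for r in doc.get("reproducibility", [])
            ],
            interference=[
                InterferenceResult(**r) for r in doc.get("interference", [])
            ],
            agreement=(
                AgreementResult(**doc["agreement"])
                if doc.get("agreement") is not None
                else None
            ),
            missing_sections=list(doc.get("missing_sections", [])),
        )


def classify_cv(cv_percent: float) -> str:
    """Assay-precision class: excellent < 10%, good 10–20%, else poor.

    The boundary value 10% falls in "good" (the excellent class is strict).
    """
    if cv_percent < 10.0:
        return "excellent"
    if cv_percent < 20.0:
        return "good"
    return "poor"


def classify_icc(icc: float) -> str:
    """Reliability class at the 0.5 / 0.75 / 0.9 cutoffs."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def reproducibility(
    values_ppb: list[float], label: str = ""
) -> ReproducibilityResult:
    """Replicate precision: mean, sample SD and CV% for one condition."""
    values = np.asarray(values_ppb, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 replicates for precision, got {values.size}"
        )
    mean = float(values.mean())
    if mean <= 0:
        raise UndefinedStatisticError(
            f"CV undefined for non-positive mean ({mean})"
        )
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean
    return ReproducibilityResult(
        condition_label=label,
        n=int(values.size),
        mean_ppb=mean,
        sd_ppb=sd,
        cv_percent=cv,
        cv_class=classify_cv(cv),
    )


def paired_t_test(
    with_substance: list[float],
    without_substance: list[float],
    substance: str = "",
) -> InterferenceResult:
    """Classical two-sided paired t-test of with- vs without-substance runs.

    Identical pairs (zero-variance, zero-mean differences) return t = 0,
    p = 1 by convention so the downstream all-p-above-α decision rule has
    a defined value.
    """
    a = np.asarray(with_substance, dtype=float)
    b = np.asarray(without_substance, dtype=float)
    if a.size != b.size:
        raise ParameterError(
            f"paired samples differ in length: {a.size} vs {b.size}"
        )
    if a.size < 2:
        raise InsufficientDataError("need >= 2 pairs for a paired t-test")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            t_stat, p = 0.0, 1.0
        else:  # constant nonzero shift: infinitely strong evidence
            t_stat, p = float(np.sign(d[0]) * np.inf), 0.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return InterferenceResult(
        substance=substance,
        n_pairs=int(a.size),
        mean_with=float(a.mean()),
        mean_without=float(b.mean()),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < ALPHA),
    )


def icc_agreement(
    method_a: list[float], method_b: list[float], icc_type: str = "ICC(A,1)"
) -> float:
    """Intraclass correlation between two methods on the same samples.

    Default form is ICC(A,1): two-way random effects, absolute agreement,
    single measures — the form that complements Bland–Altman, since it
    penalizes a constant bias between methods. Other pingouin forms
    ("ICC(1,1)", "ICC(C,1)", ...) can be selected via *icc_type*.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.size != b.size:
        raise ParameterError(
            f"methods differ in length: {a.size} vs {b.size}"
        )
    if a.size < 3:
        raise InsufficientDataError("need >= 3 paired samples for ICC")
    values = np.concatenate([a, b])
    if np.all(values == values[0]):
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(a.size), 2),
            "rater": ["A"] * a.size + ["B"] * a.size,
            "rating": values,
        }
    )
    table = pg.intraclass_corr(
        data=df, targets="target", raters="rater", ratings="rating"
    )
    row = table.loc[table["Type"] == icc_type]
    if row.empty:
        raise ParameterError(f"unknown ICC form {icc_type!r}")
    return float(row["ICC"].iloc[0])


def bland_altman(
    method_a: list[float], method_b: list[float]
) -> BlandAltmanResult:
    """Bland–Altman agreement: bias and 95% limits of differences a − b.

    Differences are platform − reference; limits are bias ± 1.96·SD with
    the n−1 SD. Per-point (mean, difference) pairs are kept for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.size != b.size:
        raise ParameterError(
            f"methods differ in length: {a.size} vs {b.size}"
        )
    if a.size < 2:
        raise InsufficientDataError("need >= 2 pairs for Bland–Altman")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        n=int(a.size),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        means=((a + b) / 2.0).tolist(),
        differences=d.tolist(),
    )


def pearson_r(x: list[float], y: list[float]) -> float:
    """Product-moment correlation between two equal-length samples."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ParameterError(f"lengths differ: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise InsufficientDataError("need >= 3 points for a correlation")
    if xa.std() == 0 or ya.std() == 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in an input"
        )
    return float(stats.pearsonr(xa, ya).statistic)


def method_agreement(
    platform: list[float], reference: list[float], icc_type: str = "ICC(A,1)"
) -> AgreementResult:
    """ICC + Pearson + Bland–Altman between platform and reference method."""
    icc = icc_agreement(platform, reference, icc_type=icc_type)
    ba = bland_altman(platform, reference)
    return AgreementResult(
        n=ba.n,
        icc=icc,
        icc_class=classify_icc(icc),
        pearson_r=pearson_r(platform, reference),
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
    )


def validation_report(
    reproducibility_results: list[ReproducibilityResult] | None = None,
    interference_results: list[InterferenceResult] | None = None,
    agreement: AgreementResult | None = None,
) -> ValidationReport:
    """Assemble sections into one report, flagging whichever are absent."""
    missing = []
    if not reproducibility_results:
        missing.append("reproducibility")
    if not interference_results:
        missing.append("interference")
    if agreement is None:
        missing.append("agreement")
    return ValidationReport(
        reproducibility=reproducibility_results or [],
        interference=interference_results or [],
        agreement=agreement,
        missing_sections=missing,
    )
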