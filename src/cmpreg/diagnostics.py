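"""Dispersion / zero-inflation test battery and model-comparison statistics.

Nested likelihood-ratio tests (Poisson vs CMP for dispersion, ZIP vs ZICMP
for dispersion under zero inflation, CMP vs ZICMP and Poisson vs ZIP for
zero inflation) are referred to a chi-squared distribution with one degree
of freedom.  No boundary-null mixture correction is applied to the
zero-inflation tests: the plain chi-squared reference is the convention in
the applied literature this package follows, and it is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats.contingency import association

from .design import DesignSet
from .frequency import CountFrequencyTable
from .models import FittedModel, predict_mean
from .distribution import DEFAULT_CONTROL, SeriesControl

#: (restricted, full) model pairs that form valid one-parameter nestings.
NESTED_PAIRS = {
    ("poisson", "cmp"): "dispersion",
    ("zip", "zicmp"): "dispersion (zero-inflated)",
    ("cmp", "zicmp"): "zero inflation",
    ("poisson", "zip"): "zero inflation",
}


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its chi-squared reference."""

    method: str
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ComparisonRow:
    """One column of a model-comparison table."""

    kind: str
    loglik: float
    aic: float
    pearson: float
    n_params: int


def _chi2_result(method: str, statistic: float, df: int) -> TestResult:
    statistic = max(float(statistic), 0.0)  # floor numerical noise
    return TestResult(method, statistic, df, float(chi2.sf(statistic, df)))


def lrt_nested(restricted: FittedModel, full: FittedModel, df: int = 1) -> TestResult:
    """Likelihood-ratio test of a restricted model against a nesting full model.

    The statistic is ``2 * (loglik_full - loglik_restricted)``, floored at
    zero, on ``df`` degrees of freedom (1 for every pairing used here).
    """
    pair = (restricted.kind, full.kind)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"{restricted.kind!r} is not nested in {full.kind!r}")
    stat = 2.0 * (full.loglik - restricted.loglik)
    return _chi2_result(f"LRT {restricted.kind} vs {full.kind} ({NESTED_PAIRS[pair]})", stat, df)


def score_test_zero_inflation(freq: CountFrequencyTable) -> TestResult:
    """Score test of zero inflation against a Poisson null.

    With ``n`` observations, ``n0`` zeros, sample mean ``ybar`` and
    ``p0 = exp(-ybar)``, the statistic is

        S = (n0 - n p0)**2 / (n p0 (1 - p0) - n ybar p0**2)

    computed from the null fit alone, referred to chi-squared(1).
    """
    n = freq.n
    ybar = freq.mean
    if ybar <= 0.0:
        raise ValueError("score test requires a positive sample mean")
    n0 = freq.n_zero
    p0 = np.exp(-ybar)
    denom = n * p0 * (1.0 - p0) - n * ybar * p0**2
    if denom <= 0.0:
        raise ValueError(
            "degenerate score-test denominator: the Poisson null leaves no "
            "room for excess-zero variation at this mean"
        )
    stat = (n0 - n * p0) ** 2 / denom
    return _chi2_result("score test for zero inflation", stat, 1)


def pearson_gof(
    fit: FittedModel,
    design: DesignSet,
    variant: str = "pearson",
    control: SeriesControl = DEFAULT_CONTROL,
) -> float:
    """Goodness-of-fit summary for a fitted count model.

    ``variant="pearson"`` is the generalized Pearson chi-squared
    ``sum w_i (y_i - E[Y_i])**2 / E[Y_i]`` with the exact model mean.
    ``variant="ssq_approx_mean"`` (CMP/ZICMP only) is the *unnormalized*
    squared-deviation sum about the asymptotic-approximation CMP mean; it
    exists solely because some published CMP comparisons report that
    quantity under the Pearson label, and it is labelled accordingly in
    reports.
    """
    if variant == "pearson":
        mu = predict_mean(fit, design, control=control)
        if np.any(mu <= 0.0):
            raise ValueError("nonpositive fitted mean in Pearson statistic")
        return float(np.dot(design.w, (design.y - mu) ** 2 / mu))
    if variant == "ssq_approx_mean":
        if fit.kind not in ("cmp", "zicmp"):
            raise ValueError("ssq_approx_mean applies to CMP-family fits only")
        lam = np.exp(design.X @ fit.beta)
        nu = np.exp(design.S @ fit.delta)
        if np.any(nu <= 0.0):
            raise ValueError("approximate mean requires nu > 0")
        mu = lam ** (1.0 / nu) - (nu - 1.0) / (2.0 * nu)
        if fit.kind == "zicmp":
            from scipy.special import expit

            mu = (1.0 - expit(design.W @ fit.gamma)) * mu
        return float(np.dot(design.w, (design.y - mu) ** 2))
    raise ValueError(f"unknown variant {variant!r}")


def information_criteria(fit: FittedModel) -> ComparisonRow:
    """AIC = -2 loglik + 2 k with k the number of estimated coefficients."""
    return ComparisonRow(
        kind=fit.kind,
        loglik=fit.loglik,
        aic=-2.0 * fit.loglik + 2.0 * fit.n_params,
        pearson=fit.pearson,
        n_params=fit.n_params,
    )


def cramers_v(a, b) -> float:
    """Cramer's V association between two categorical vectors, in [0, 1]."""
    a = pd.Series(a)
    b = pd.Series(b)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    table = pd.crosstab(a, b).to_numpy()
    if min(table.shape) < 2:
        raise ValueError("both variables need at least two observed levels")
    return float(association(table, method="cramer", correction=False))


@dataclass
class ComparisonReport:
    """Model-comparison rows plus the applicable nested and score tests."""

    rows: list[ComparisonRow]
    tests: list[TestResult]
    boundary_notes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                r.kind: {
                    "loglik": r.loglik,
                    "aic": r.aic,
                    "pearson": r.pearson,
                    "n_params": r.n_params,
                }
                for r in self.rows
            }
        )

    def to_text(self) -> str:
        lines = ["Model comparison", "=" * 16, ""]
        frame = self.to_frame()
        header = f"{'':24s}" + "".join(f"{k:>14s}" for k in frame.columns)
        lines.append(header)
        for label, fmt in (
            ("Log-likelihood", "loglik"),
            ("AIC", "aic"),
            ("Pearson chi-squared", "pearson"),
            ("No. of parameters", "n_params"),
        ):
            vals = frame.loc[fmt]
            if fmt == "n_params":
                row = "".join(f"{int(v):>14d}" for v in vals)
            else:
                row = "".join(f"{v:>14.2f}" for v in vals)
            lines.append(f"{label:24s}" + row)
        if self.tests:
            lines += ["", "Tests", "-" * 5]
            for t in self.tests:
                lines.append(
                    f"{t.method}: statistic = {t.statistic:.2f}, df = {t.df}, "
                    f"p = {t.p_value:.4g}"
                )
        for note in self.boundary_notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def comparison_table(
    fits: list[FittedModel],
    freq: CountFrequencyTable | None = None,
) -> ComparisonReport:
    """Assemble comparison rows and run every test the fitted pairs admit."""
    if not fits:
        raise ValueError("at least one fitted model is required")
    rows = [information_criteria(f) for f in fits]
    by_kind = {f.kind: f for f in fits}
    tests: list[TestResult] = []
    if "poisson" in by_kind and "cmp" in by_kind:
        tests.append(lrt_nested(by_kind["poisson"], by_kind["cmp"]))
    if "zip" in by_kind and "zicmp" in by_kind:
        tests.append(lrt_nested(by_kind["zip"], by_kind["zicmp"]))
    if "cmp" in by_kind and "zicmp" in by_kind:
        tests.append(lrt_nested(by_kind["cmp"], by_kind["zicmp"]))
    if freq is not None:
        tests.append(score_test_zero_inflation(freq))
    notes = []
    for f in fits:
        flags = f.boundary_flags.get("gamma")
        if flags is not None and np.any(flags):
            names = [n for n, bad in zip(f.w_names, flags) if bad]
            notes.append(
                f"{f.kind}: zero-part coefficient(s) {names} at the logit-scale "
                "boundary; their standard errors are unreliable"
            )
    return ComparisonReport(rows=rows, tests=tests, boundary_notes=notes)
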