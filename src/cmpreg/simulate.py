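"""Synthetic accident data with the statistical structure of the 2015 Thai
road-accident records.

The generator draws the six categorical covariates independently with the
marginal frequencies observed in the study year (covariate association in
the real records is weak, Cramer's V at most 0.59, and is deliberately not
emulated) and death counts from a zero-inflated CMP regression at
user-specified coefficients.  It exists so that every stage of the fitting
pipeline — design construction, maximum likelihood, the test battery — can
be exercised and validated by parameter recovery without the record-level
source file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import CategoricalCoding, THAILAND_CODING, build_design
from .distribution import DEFAULT_CONTROL, SeriesControl, _series_terms
from .frequency import CountFrequencyTable
from .models import FITTERS

#: Observed covariate frequencies (number of accidents) in the study year,
#: n = 20,229.
THAILAND_COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "roadway_class": {
        "National highway": 8737,
        "Rural highway": 2738,
        "Urban road": 2977,
        "Local street": 5777,
    },
    "road_surface": {"Dry": 18752, "Wet": 1477},
    "road_section": {"Straight": 13750, "Curve": 2478, "Crossing and others": 4001},
    "weather": {"Clear": 18797, "Fog": 792, "Rain": 640},
    "light": {"Day": 12360, "Night with light": 4615, "Night without light": 3254},
    "month": {
        "January": 2668, "February": 1412, "March": 1575, "April": 3700,
        "May": 1443, "June": 1242, "July": 1348, "August": 1305,
        "September": 1127, "October": 1170, "November": 1206, "December": 2033,
    },
}

#: Observed deaths-per-accident frequency distribution in the study year.
THAILAND_FATALITY_COUNTS: dict[int, int] = {
    0: 14641, 1: 5218, 2: 285, 3: 45, 4: 23, 5: 8, 6: 9,
}


@dataclass(frozen=True)
class CovariateMarginals:
    """Per-variable ordered level labels with sampling probabilities."""

    levels: dict[str, tuple[str, ...]]
    probs: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for var, levs in self.levels.items():
            p = np.asarray(self.probs[var], dtype=float)
            if len(p) != len(levs):
                raise ValueError(f"{var!r}: probabilities do not match levels")
            if np.any(p < 0.0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{var!r}: probabilities must be nonnegative and sum to 1")


def thailand_covariate_marginals() -> CovariateMarginals:
    """The packaged default marginals: study-year proportions."""
    levels = {}
    probs = {}
    for var, table in THAILAND_COVARIATE_COUNTS.items():
        levs = tuple(table.keys())
        counts = np.array(list(table.values()), dtype=float)
        levels[var] = levs
        probs[var] = tuple(counts / counts.sum())
    return CovariateMarginals(levels=levels, probs=probs)


def thailand_fatality_table() -> CountFrequencyTable:
    """The study-year deaths-per-accident frequency table (n = 20,229)."""
    return CountFrequencyTable(THAILAND_FATALITY_COUNTS)


@dataclass(frozen=True)
class TrueCoefficients:
    """Generating coefficients for the count, dispersion and zero parts.

    ``gamma=None`` forces the structural-zero probability to 0.  Term lists
    name categorical variables that enter each part (treatment coded,
    baselines first); the coefficient vectors must match the implied design
    including the intercept.
    """

    beta: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray | None = None
    count_terms: tuple[str, ...] = ()
    dispersion_terms: tuple[str, ...] = ()
    zero_terms: tuple[str, ...] = ()
    coding: CategoricalCoding = field(default=THAILAND_CODING)


def generate_covariates(
    n: int,
    marginals: CovariateMarginals | None = None,
    seed=0,
) -> pd.DataFrame:
    """Independent categorical draws per variable; reproducible given seed."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    marginals = marginals or thailand_covariate_marginals()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = {}
    for var, levs in marginals.levels.items():
        idx = rng.choice(len(levs), size=n, p=np.asarray(marginals.probs[var]))
        data[var] = pd.Categorical.from_codes(idx, categories=list(levs)).astype(object)
    return pd.DataFrame(data)


def _row_params(records: pd.DataFrame, coefs: TrueCoefficients):
    tmp = records.copy()
    tmp["fatalities"] = 0  # placeholder outcome; only the matrices are used
    design = build_design(
        tmp,
        count_terms=coefs.count_terms,
        dispersion_terms=coefs.dispersion_terms,
        zero_terms=coefs.zero_terms,
        coding=coefs.coding,
    )
    if design.X.shape[1] != len(coefs.beta):
        raise ValueError("beta does not match the count design")
    if design.S.shape[1] != len(coefs.delta):
        raise ValueError("delta does not match the dispersion design")
    loglam = design.X @ np.asarray(coefs.beta, dtype=float)
    nu = np.exp(design.S @ np.asarray(coefs.delta, dtype=float))
    if coefs.gamma is None:
        pi = np.zeros(len(records))
    else:
        if design.W.shape[1] != len(coefs.gamma):
            raise ValueError("gamma does not match the zero design")
        pi = expit(design.W @ np.asarray(coefs.gamma, dtype=float))
    return loglam, nu, pi


def generate_deaths(
    records: pd.DataFrame,
    coefs: TrueCoefficients,
    seed=0,
    control: SeriesControl = DEFAULT_CONTROL,
) -> np.ndarray:
    """Per-row ZICMP draw with row-specific (lam, nu, pi).

    Two-stage sampling: a Bernoulli(pi) structural zero, otherwise a CMP
    draw by inversion of the row's cumulative pmf.  Rows sharing a
    parameter combination share one tabulated pmf.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    loglam, nu, pi = _row_params(records, coefs)
    key = np.column_stack([loglam, nu])
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    _, log_terms = _series_terms(uniq[:, 0], uniq[:, 1], control)
    from scipy.special import logsumexp

    log_z = logsumexp(log_terms, axis=1)
    cdf = np.cumsum(np.exp(log_terms - log_z[:, None]), axis=1)
    structural = rng.random(len(records)) < pi
    u = rng.random(len(records))
    draws = (u[:, None] > cdf[inverse]).sum(axis=1)
    draws[structural] = 0
    return draws.astype(np.int64)


@dataclass
class RecoverySummary:
    """Per-coefficient recovery diagnostics from a simulation experiment."""

    table: pd.DataFrame  # columns: part, name, truth, mean_est, bias, empirical_se, coverage
    reps: int
    n: int
    seed: int
    n_failed: int

    def coverage(self) -> pd.Series:
        return self.table.set_index(["part", "name"])["coverage"]


def recovery_experiment(
    coefs: TrueCoefficients,
    marginals: CovariateMarginals | None = None,
    n: int = 5000,
    reps: int = 50,
    seed: int = 0,
    kind: str = "zicmp",
    control: SeriesControl = DEFAULT_CONTROL,
) -> RecoverySummary:
    """Generate-fit-summarize loop: bias and 95% Wald CI coverage per coefficient.

    One master seed spawns independent per-replicate child streams.  Fit
    failures are counted and excluded, never fatal.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if kind not in FITTERS:
        raise ValueError(f"unknown model kind {kind!r}")
    marginals = marginals or thailand_covariate_marginals()
    truth_parts: list[tuple[str, str, float]] = []

    children = np.random.SeedSequence(seed).spawn(reps)
    estimates: list[np.ndarray] = []
    ses: list[np.ndarray] = []
    n_failed = 0
    names_ref = None
    truth_vec = None
    for child in children:
        rng = np.random.default_rng(child)
        records = generate_covariates(n, marginals, seed=rng)
        y = generate_deaths(records, coefs, seed=rng, control=control)
        records = records.assign(fatalities=y)
        intercept_only = not (coefs.count_terms or coefs.dispersion_terms or coefs.zero_terms)
        if intercept_only:
            # Weighted frequency-table fit is exactly equivalent and much faster.
            from .design import DesignSet

            design = DesignSet.from_frequency(CountFrequencyTable.from_records(y))
        else:
            design = build_design(
                records,
                count_terms=coefs.count_terms,
                dispersion_terms=coefs.dispersion_terms,
                zero_terms=coefs.zero_terms,
                coding=coefs.coding,
            )
        try:
            fit = FITTERS[kind](design, control=control)
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        est = [fit.beta]
        se = [fit.se_beta]
        names = [("count", nm) for nm in fit.x_names]
        truths = [("count", nm, v) for nm, v in zip(design.x_names, coefs.beta)]
        if fit.delta is not None:
            est.append(fit.delta)
            se.append(fit.se_delta)
            names += [("dispersion", nm) for nm in fit.s_names]
            truths += [("dispersion", nm, v) for nm, v in zip(design.s_names, coefs.delta)]
        if fit.gamma is not None:
            gamma_truth = coefs.gamma if coefs.gamma is not None else np.full(len(fit.gamma), -np.inf)
            est.append(fit.gamma)
            se.append(fit.se_gamma)
            names += [("zero", nm) for nm in fit.w_names]
            truths += [("zero", nm, v) for nm, v in zip(design.w_names, gamma_truth)]
        estimates.append(np.concatenate(est))
        ses.append(np.concatenate(se))
        if names_ref is None:
            names_ref = names
            truth_parts = truths
            truth_vec = np.array([t for _, _, t in truths])
    if not estimates:
        raise RuntimeError("every replicate failed to fit")
    est_mat = np.vstack(estimates)
    se_mat = np.vstack(ses)
    mean_est = est_mat.mean(axis=0)
    emp_se = est_mat.std(axis=0, ddof=1)
    covered = (np.abs(est_mat - truth_vec) <= 1.959963984540054 * se_mat).mean(axis=0)
    table = pd.DataFrame(
        {
            "part": [p for p, _, _ in truth_parts],
            "name": [nm for _, nm, _ in truth_parts],
            "truth": truth_vec,
            "mean_est": mean_est,
            "bias": mean_est - truth_vec,
            "empirical_se": emp_se,
            "coverage": covered,
        }
    )
    return RecoverySummary(table=table, reps=reps, n=n, seed=seed, n_failed=n_failed)
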