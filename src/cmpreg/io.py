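"""Reading accident records and frequency tables, and the end-to-end pipeline.

File conventions: comma-separated UTF-8 text with a header row, decimal
point only.  Record-level files carry one row per accident with a
nonnegative-integer fatality count plus categorical covariates, which may
be stored either as level labels or as integer codes translated through a
configurable code map (defaulting to 1-based codes in coding order).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CategoricalCoding, THAILAND_CODING, build_design, DesignSet
from .diagnostics import ComparisonReport, comparison_table, pearson_gof
from .distribution import SeriesControl, DEFAULT_CONTROL
from .frequency import CountFrequencyTable
from .models import FITTERS, FitOptions, FittedModel
from .simulate import thailand_fatality_table

logger = logging.getLogger("cmpreg")


def default_code_maps(coding: CategoricalCoding = THAILAND_CODING) -> dict[str, dict[int, str]]:
    """Integer codes 1..k per variable, in coding order (the usual convention
    of the study's source database)."""
    return {
        var: {i + 1: level for i, level in enumerate(levels)}
        for var, levels in coding.levels.items()
    }


def read_frequency_table(path) -> CountFrequencyTable:
    """Read a two-column (value, count) delimited file into a frequency table."""
    frame = pd.read_csv(path)
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (value, count)")
    values = frame.iloc[:, 0]
    counts = frame.iloc[:, 1]
    if (values < 0).any() or (values != values.astype(int)).any():
        raise ValueError(f"{path}: outcome values must be distinct nonnegative integers")
    if (counts < 0).any():
        raise ValueError(f"{path}: counts must be nonnegative")
    if values.duplicated().any():
        dup = values[values.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate outcome value {dup}")
    return CountFrequencyTable(dict(zip(values.astype(int), counts.astype(int))))


def write_frequency_table(table: CountFrequencyTable, path) -> None:
    pd.DataFrame({"value": table.values, "count": table.counts}).to_csv(path, index=False)


def read_accidents(
    path,
    coding: CategoricalCoding = THAILAND_CODING,
    outcome: str = "fatalities",
    column_map: dict[str, str] | None = None,
    code_maps: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Read record-level accident data, translating integer codes to labels.

    ``column_map`` renames file columns to the canonical variable names;
    ``code_maps`` maps stored codes to level labels per variable (labels
    already matching the coding pass through unchanged).
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    if outcome not in frame.columns:
        raise ValueError(f"{path}: missing outcome column {outcome!r}")
    y_num = pd.to_numeric(frame[outcome], errors="coerce")
    bad = y_num.isna() | (y_num != np.floor(y_num)) | (y_num < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: fatality count must be a nonnegative integer; "
            f"offending value {frame[outcome].iloc[row]!r} at row {row}"
        )
    frame[outcome] = y_num.astype(np.int64)
    maps = code_maps if code_maps is not None else default_code_maps(coding)
    for var, levels in coding.levels.items():
        if var not in frame.columns:
            raise ValueError(f"{path}: missing covariate column {var!r}")
        col = frame[var]
        translated = col.map(maps.get(var, {})) if var in maps else pd.Series(pd.NA, index=col.index)
        resolved = translated.where(translated.notna(), col.astype(object))
        unknown = ~resolved.isin(list(levels))
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValueError(
                f"{path}: unmappable value {col.iloc[row]!r} for {var!r} at row {row}"
            )
        frame[var] = resolved.astype(object)
    logger.info("read %d records from %s", len(frame), path)
    return frame


def write_accidents(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything needed to drive one end-to-end fit-and-compare run."""

    data: str | None = None           # record-level CSV
    freq: str | None = None           # two-column frequency CSV
    models: tuple[str, ...] = ("poisson", "cmp", "zip", "zicmp")
    count_terms: tuple[str, ...] = ()
    dispersion_terms: tuple[str, ...] = ()
    zero_terms: tuple[str, ...] = ()
    outcome: str = "fatalities"
    rel_tol: float = 1e-12
    max_terms: int = 10_000
    gtol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "count_terms", "dispersion_terms", "zero_terms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def control(self) -> SeriesControl:
        return SeriesControl(rel_tol=self.rel_tol, max_terms=self.max_terms)

    def options(self) -> FitOptions:
        return FitOptions(gtol=self.gtol, max_iter=self.max_iter)


def _round_for_report(fit: FittedModel) -> dict:
    def part(names, coef, se, flags):
        return [
            {
                "name": nm,
                "estimate": round(float(c), 4),
                "se": round(float(s), 4),
                "boundary": bool(fl),
            }
            for nm, c, s, fl in zip(names, coef, se, flags)
        ]

    out = {
        "kind": fit.kind,
        "count": part(
            fit.x_names, fit.beta, fit.se_beta, fit.boundary_flags["beta"]
        ),
        "loglik": round(fit.loglik, 2),
        "aic": round(fit.aic, 2),
        "pearson": round(fit.pearson, 2),
        "n_params": fit.n_params,
        "converged": fit.converged,
    }
    if fit.delta is not None:
        out["dispersion"] = part(
            fit.s_names, fit.delta, fit.se_delta, fit.boundary_flags["delta"]
        )
    if fit.gamma is not None:
        out["zero"] = part(
            fit.w_names, fit.gamma, fit.se_gamma, fit.boundary_flags["gamma"]
        )
    return out


def _machine_results(fits: dict[str, FittedModel], report: ComparisonReport) -> dict:
    out = {"models": {}, "tests": []}
    for kind, fit in fits.items():
        entry = {
            "beta": fit.beta.tolist(),
            "se_beta": fit.se_beta.tolist(),
            "x_names": fit.x_names,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "pearson": fit.pearson,
            "n_params": fit.n_params,
            "converged": fit.converged,
        }
        if fit.delta is not None:
            entry["delta"] = fit.delta.tolist()
            entry["se_delta"] = fit.se_delta.tolist()
            entry["s_names"] = fit.s_names
        if fit.gamma is not None:
            entry["gamma"] = fit.gamma.tolist()
            entry["se_gamma"] = fit.se_gamma.tolist()
            entry["w_names"] = fit.w_names
            entry["gamma_boundary"] = fit.boundary_flags["gamma"].tolist()
        out["models"][kind] = entry
    for t in report.tests:
        out["tests"].append(
            {"method": t.method, "statistic": t.statistic, "df": t.df, "p_value": t.p_value}
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Fit every requested model, run the applicable tests, write reports.

    Returns a dict with the fitted models, the comparison report and the
    output paths.  Per-model fit failures are logged and reported; the
    pipeline continues with the remaining models.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    control = config.control()
    options = config.options()

    freq = None
    if config.data is not None:
        records = read_accidents(config.data, outcome=config.outcome)
        design = build_design(
            records,
            count_terms=config.count_terms,
            dispersion_terms=config.dispersion_terms,
            zero_terms=config.zero_terms,
            outcome=config.outcome,
        )
        freq = CountFrequencyTable.from_records(design.y)
    elif config.freq is not None:
        freq = read_frequency_table(config.freq)
        design = DesignSet.from_frequency(freq)
    else:
        freq = thailand_fatality_table()
        design = DesignSet.from_frequency(freq)
        logger.info("no input given; using the packaged study frequency table")
    logger.info("design built: %d rows, %.0f effective observations", len(design.y), design.n_obs)

    fits: dict[str, FittedModel] = {}
    failures: dict[str, str] = {}
    for kind in config.models:
        if kind not in FITTERS:
            raise ValueError(f"unknown model kind {kind!r}")
        t_fit = time.time()
        try:
            fits[kind] = FITTERS[kind](design, control=control, options=options)
            logger.info(
                "fitted %s in %.2fs (loglik %.2f, converged=%s)",
                kind, time.time() - t_fit, fits[kind].loglik, fits[kind].converged,
            )
        except Exception as exc:  # keep going with the remaining models
            failures[kind] = str(exc)
            logger.error("fit of %s failed: %s", kind, exc)
    if not fits:
        raise RuntimeError(f"every requested model failed: {failures}")

    # Score test applies when intercept-only models are in play.
    score_input = freq if not config.count_terms else None
    report = comparison_table(list(fits.values()), freq=score_input)

    (outdir / "report.txt").write_text(report.to_text() + "\n")
    report.to_frame().to_csv(outdir / "comparison.csv")
    machine = _machine_results(fits, report)
    machine["failures"] = failures
    machine["coefficients_rounded"] = [_round_for_report(f) for f in fits.values()]
    with open(outdir / "results.json", "w") as fh:
        json.dump(machine, fh, indent=2)
    logger.info("pipeline finished in %.2fs; reports in %s", time.time() - t0, outdir)
    return {"fits": fits, "report": report, "design": design, "freq": freq,
            "failures": failures, "outdir": outdir}


def plot_observed_vs_fitted(
    freq: CountFrequencyTable,
    fits: dict[str, FittedModel],
    path,
    control: SeriesControl = DEFAULT_CONTROL,
) -> None:
    """Bar chart of observed frequencies with fitted pmfs overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .distribution import CMPParams, ZICMPParams, cmp_pmf, zicmp_pmf
    from scipy.special import expit
    from scipy.stats import poisson

    values = freq.values
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(values, freq.counts / freq.n, color="0.8", label="observed")
    for kind, fit in fits.items():
        lam = float(np.exp(fit.beta[0]))
        if kind == "poisson":
            pmf = poisson.pmf(values, lam)
        elif kind == "cmp":
            pmf = cmp_pmf(values, CMPParams(lam, float(np.exp(fit.delta[0]))), control)
        elif kind == "zip":
            pi = float(expit(fit.gamma[0]))
            pmf = zicmp_pmf(values, ZICMPParams(CMPParams(lam, 1.0), pi), control)
        else:
            pi = float(expit(fit.gamma[0]))
            pmf = zicmp_pmf(
                values, ZICMPParams(CMPParams(lam, float(np.exp(fit.delta[0]))), pi), control
            )
        ax.plot(values, pmf, marker="o", label=kind)
    ax.set_xlabel("deaths per accident")
    ax.set_ylabel("probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
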