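"""End-to-end orchestration: model study, synthetic cohort study, reanalysis.

Each run validates its configuration up front, writes the resolved
configuration next to its outputs, and lays results out as::

    out/
      config/resolved.yaml
      traces/    per-trial or per-condition time series
      tables/    tidy period statistics
      report/    marginal means, contrasts, ordinal fit, diagnostics

The same analysis code path serves the synthetic study and the reanalysis
of externally supplied recordings, so a synthetic cohort written to disk and
re-analyzed from disk produces byte-identical reports.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .errors import MappingError, SchemaError
from .field import build_field_map
from .model import ModelParams, default_params, duration_response_table, run_paradigm
from .spv import extract_spv, detect_events, period_summaries
from .stats import duration_regression, fit_condition_model, fit_ordinal_intensity, pairwise_contrasts
from .synth import generate_cohort

log = logging.getLogger("mvslab")

_SCHEMA = {
    "mode": (str, ("model", "synthetic", "reanalysis")),
    "seed": (int, None),
    "b0": ((int, float), None),
    "entry_s": ((int, float), None),
    "dwell_s": ((int, float), None),
    "exit_s": ((int, float), None),
    "pre_s": ((int, float), None),
    "post_s": ((int, float), None),
    "dt": ((int, float), None),
    "durations": (list, None),
    "field_strengths": (list, None),
    "n_subjects": (int, None),
    "conditions": (list, None),
    "fs": ((int, float), None),
    "data_dir": (str, None),
    "column_map": (dict, None),
    "long_dwell_s": ((int, float), None),
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str = "model"
    seed: int = 0
    b0: float = 7.0
    dt: float = 0.05
    pre_s: float = 120.0
    post_s: float = 240.0
    dwell_s: float = 300.0
    entry_s: float = 20.0
    exit_s: float = 20.0
    durations: list = field(default_factory=lambda: [0, 20, 60, 120, 180, 300])
    field_strengths: list = field(default_factory=lambda: [1.5, 3.0, 7.0, 9.4, 11.7])
    long_dwell_s: float = 1800.0
    n_subjects: int = 8
    conditions: list = field(default_factory=lambda: [20.0, 120.0, 300.0])
    fs: float = 100.0
    data_dir: Optional[str] = None
    column_map: Optional[dict] = None

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        unknown = set(obj) - set(_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
        for key, val in obj.items():
            typ, allowed = _SCHEMA[key]
            if val is not None and not isinstance(val, typ):
                raise SchemaError(f"key {key!r} must be of type {typ}")
            if allowed is not None and val not in allowed:
                raise SchemaError(f"key {key!r} must be one of {allowed}")
        cfg = cls(**obj)
        if cfg.dt <= 0 or cfg.b0 <= 0 or cfg.fs <= 0:
            raise SchemaError("dt, b0 and fs must be positive")
        if cfg.mode == "reanalysis" and not cfg.data_dir:
            raise SchemaError("reanalysis mode requires data_dir")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(mio.load_yaml(path))


def _prepare_out(out_dir, cfg: RunConfig) -> Path:
    out = Path(out_dir)
    for sub in ("config", "traces", "tables", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    resolved = {k: v for k, v in asdict(cfg).items() if v is not None}
    mio.dump_yaml(out / "config" / "resolved.yaml", resolved)
    return out


def run_simulate(cfg: RunConfig, out_dir) -> dict:
    """Model study: duration sweeps, field sweep, long-dwell run, regression."""
    out = _prepare_out(out_dir, cfg)
    params = default_params()
    t0 = _time.time()

    sweeps = {}
    for vary in ("entry", "exit", "both"):
        tbl = duration_response_table(
            params, cfg.durations, b0=cfg.b0, dwell_s=cfg.dwell_s, vary=vary, dt=cfg.dt
        )
        mio.write_table(out / "tables" / f"duration_response_{vary}.csv", tbl)
        sweeps[vary] = tbl

    field_rows = []
    for b in cfg.field_strengths:
        res = run_paradigm(params, entry_s=cfg.entry_s, dwell_s=cfg.dwell_s,
                           exit_s=cfg.exit_s, b0=float(b), dt=cfg.dt)
        res.to_frame().to_csv(out / "traces" / f"field_{b:g}T.csv",
                              index=False, float_format="%.6f")
        tbl = duration_response_table(params, [cfg.entry_s], b0=float(b),
                                      dwell_s=cfg.dwell_s, dt=cfg.dt)
        field_rows.append({"b0": float(b), "per_peak": tbl["per_peak"].iloc[0],
                           "post_peak": tbl["post_peak"].iloc[0]})
    field_tbl = pd.DataFrame(field_rows)
    mio.write_table(out / "tables" / "field_response.csv", field_tbl)

    long_tbl = duration_response_table(
        params, cfg.durations, b0=cfg.b0, dwell_s=cfg.long_dwell_s, vary="both", dt=cfg.dt
    )
    mio.write_table(out / "tables" / "duration_response_long_dwell.csv", long_tbl)

    if len(cfg.durations) >= 3:
        reg_per = duration_regression(sweeps["entry"]["duration_s"],
                                      sweeps["entry"]["per_peak"])
        reg_post = duration_regression(sweeps["exit"]["duration_s"],
                                       sweeps["exit"]["post_peak"])
        regression = pd.DataFrame([
            {"response": "per_peak", "varied": "entry", **reg_per._asdict()},
            {"response": "post_peak", "varied": "exit", **reg_post._asdict()},
        ])
    else:
        regression = pd.DataFrame(
            columns=["response", "varied", "slope", "intercept", "r2", "adj_r2"]
        )
    mio.write_table(out / "report" / "duration_regression.csv", regression)
    log.info("simulate finished in %.1f s", _time.time() - t0)
    return {"sweeps": sweeps, "field": field_tbl, "long_dwell": long_tbl,
            "regression": regression}


def _analyze_recordings(files, out: Path, b0: float,
                        ratings: Optional[pd.DataFrame] = None,
                        column_map: Optional[dict] = None) -> dict:
    """Shared analysis path: SPV extraction, period table, statistics."""
    rows = []
    for path in files:
        rec = mio.read_recording(path, column_map=column_map)
        subject = rec.meta.get("subject")
        condition = rec.meta.get("condition")
        if subject is None or condition is None:
            raise MappingError(
                f"recording {Path(path).name} lacks subject/condition metadata"
            )
        t = rec.time
        trace = extract_spv(t, rec.cyclopean_horizontal())
        events = detect_events(t, rec.data["b_tesla"].to_numpy(), b0)
        summ = period_summaries(trace, events)
        rows.append({
            "file": Path(path).name, "subject": subject,
            "condition": float(condition),
            "baseline": summ.baseline_mean, "per_peak": summ.per_peak,
            "per_steady": summ.per_steady_mean, "post_peak": summ.post_peak,
        })
        log.info("analyzed %s (%d samples)", Path(path).name, t.size)
    period_tbl = pd.DataFrame(rows).sort_values(["subject", "condition"]).reset_index(drop=True)
    mio.write_table(out / "tables" / "period_statistics.csv", period_tbl)

    emm_rows = []
    contrast_rows = []
    for period in ("baseline", "per_peak", "per_steady", "post_peak"):
        fit = fit_condition_model(period_tbl[period], period_tbl["condition"],
                                  period_tbl["subject"])
        em = fit.emmeans.copy()
        em.insert(0, "period", period)
        em["p_condition"] = fit.p_value
        emm_rows.append(em)
        ct = pairwise_contrasts(fit)
        ct.insert(0, "period", period)
        contrast_rows.append(ct)
    emmeans = pd.concat(emm_rows, ignore_index=True)
    contrasts = pd.concat(contrast_rows, ignore_index=True)
    mio.write_table(out / "report" / "condition_means.csv", emmeans)
    mio.write_table(out / "report" / "pairwise_contrasts.csv", contrasts)

    ordinal_df = None
    if ratings is not None and len(ratings):
        fit = fit_ordinal_intensity(ratings["rating"], ratings["condition"],
                                    ratings["phase"], ratings["subject"])
        ordinal_df = pd.DataFrame([
            {"term": name, "estimate": fit.coef[name], "se": fit.se.get(name),
             "p_value": fit.p_values.get(name)}
            for name in fit.coef
        ])
        ordinal_df.loc[len(ordinal_df)] = {
            "term": "sigma_subject", "estimate": fit.sigma_u,
            "se": np.nan, "p_value": np.nan,
        }
        mio.write_table(out / "report" / "ordinal_intensity.csv", ordinal_df)

    return {"periods": period_tbl, "emmeans": emmeans, "contrasts": contrasts,
            "ordinal": ordinal_df}


def run_synthesize(cfg: RunConfig, out_dir) -> dict:
    """Generate a synthetic cohort, write it, and analyze it from disk."""
    out = _prepare_out(out_dir, cfg)
    traces = out / "traces"
    recordings, truth = generate_cohort(
        n_subjects=cfg.n_subjects, conditions=cfg.conditions, seed=cfg.seed,
        fs=cfg.fs, dwell_s=cfg.dwell_s, pre_s=cfg.pre_s, post_s=cfg.post_s,
        fieldmap=build_field_map(b0=cfg.b0), out_dir=traces,
    )
    mio.write_table(traces / "truth.csv",
                    truth.trials.drop(columns=["n_quick_phases"]))
    mio.write_table(traces / "ratings.csv",
                    truth.ratings.drop(columns=["latent"]))
    mio.dump_yaml(traces / "manifest.yaml", truth.manifest)

    files = [traces / f for f, _ in recordings]
    ratings = pd.read_csv(traces / "ratings.csv")
    report = _analyze_recordings(files, out, b0=cfg.b0, ratings=ratings)

    # truth-vs-estimate diagnostics, incl. CI coverage of the true condition means
    est = report["periods"].set_index(["subject", "condition"])
    tru = truth.trials.set_index(["subject", "condition"])
    diag_rows = []
    for period, tcol in (("per_peak", "true_per_peak"),
                         ("post_peak", "true_post_peak"),
                         ("per_steady", "true_per_steady"),
                         ("baseline", "true_baseline")):
        err = est[period] - tru[tcol]
        emm = report["emmeans"]
        emm_p = emm[emm["period"] == period]
        true_means = tru.groupby("condition")[tcol].mean()
        covered = sum(
            float(emm_p[emm_p["condition"] == c]["ci_low"].iloc[0])
            <= true_means[c]
            <= float(emm_p[emm_p["condition"] == c]["ci_high"].iloc[0])
            for c in true_means.index
        )
        diag_rows.append({
            "period": period,
            "rmse_vs_truth": float(np.sqrt(np.mean(err**2))),
            "max_abs_error": float(np.max(np.abs(err))),
            "ci_covered": int(covered),
            "n_conditions": int(len(true_means)),
        })
    diagnostics = pd.DataFrame(diag_rows)
    mio.write_table(out / "report" / "recovery_diagnostics.csv", diagnostics)
    report["diagnostics"] = diagnostics
    report["truth"] = truth
    return report


def run_reanalyze(cfg: RunConfig, out_dir) -> dict:
    """Analyze user-supplied recordings with the synthetic-study pipeline."""
    out = _prepare_out(out_dir, cfg)
    data_dir = Path(cfg.data_dir)
    if not data_dir.is_dir():
        raise MappingError(f"data directory {data_dir} does not exist")
    reserved = {"truth.csv", "ratings.csv"}
    files = sorted(p for p in data_dir.glob("*.csv") if p.name not in reserved)
    if not files:
        raise MappingError(f"no recording files (*.csv) found in {data_dir}")
    ratings = None
    ratings_path = data_dir / "ratings.csv"
    if ratings_path.exists():
        ratings = pd.read_csv(ratings_path)
    return _analyze_recordings(files, out, b0=cfg.b0, ratings=ratings,
                               column_map=cfg.column_map)
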