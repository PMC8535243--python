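"""End-to-end study orchestration: ingest/simulate -> assemble -> OLS ->
per-quantile fits with bootstrap bands -> penalized selection.

Every run is driven by a :class:`RunConfig`, fully serialized into the
output directory alongside a structured ``run.log``; with the same config
and seed, two runs produce byte-identical artifacts.  Each CSV artifact
carries a provenance header line ``# qbill config_hash=... seed=...``.

In simulate mode the generator first writes claims-shaped raw CSVs and
the run then *ingests its own raw files*, so the simulated and ingested
paths exercise the identical assembly code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims_io, ols_baseline, penalized_selection, quantile_core, synthetic_data
from .synthetic_data import COVARIATE_NAMES

__all__ = ["RunConfig", "run_pipeline", "comparison_report"]

logger = logging.getLogger(__name__)

_TRUTH_FACTORIES = {
    "default": synthetic_data.default_truth,
    "recovery": synthetic_data.recovery_truth,
    "selection": synthetic_data.selection_truth,
    "null": synthetic_data.null_truth,
    "heavy_tail": synthetic_data.heavy_tail_truth,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    outdir: str
    mode: str = "simulate"  # "simulate" | "ingest"
    seed: int = 0
    # simulate mode
    n: int = 500
    truth: str = "default"
    # ingest mode
    claims_path: str | None = None
    state_path: str | None = None
    locality_path: str | None = None
    # analysis settings
    procedure_code: str = "77055"
    denominator: str = "allowed"
    quantiles: list[float] = field(default_factory=lambda: list(quantile_core.DEFAULT_QUANTILES))
    bootstrap_B: int = 200
    bootstrap_level: float = 0.95
    lambda_min: float = 0.01
    lambda_max: float = 1.0
    lambda_points: int = 100
    cn: str = "loglog_n"
    threshold: float = 0.001
    refit: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest":
            missing = [k for k in ("claims_path", "state_path", "locality_path")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(f"ingest mode requires {missing}")
        self.quantiles = sorted(float(t) for t in self.quantiles)
        if any(not 0 < t < 1 for t in self.quantiles):
            raise ValueError("quantile levels must be in (0, 1)")
        if self.truth not in _TRUTH_FACTORIES:
            raise ValueError(f"unknown truth config {self.truth!r}; "
                             f"choose from {sorted(_TRUTH_FACTORIES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (the output location is
        provenance, not a parameter, and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# qbill config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def comparison_report(
    ols: ols_baseline.OlsFit, qfits: list[quantile_core.QuantileFit]
) -> pd.DataFrame:
    """Long-format OLS-vs-quantile comparison (the coefficient-band plot data).

    One row per (variable, estimator): estimate with its interval, plus a
    flag on quantile rows whose point estimate falls outside the OLS 95%
    interval — the covariate/quantile cells where mean regression and the
    localized quantile effect visibly disagree.
    """
    names = ["(Intercept)"] + list(ols.feature_names)
    for f in qfits:
        if ["(Intercept)"] + list(f.feature_names) != names:
            raise ValueError("OLS and quantile fits have mismatched variable sets")
    rows = []
    for j, name in enumerate(names):
        rows.append({
            "variable": name, "tau": "OLS", "estimate": ols.beta[j],
            "lower": ols.ci_lower[j], "upper": ols.ci_upper[j],
            "outside_ols_ci": False,
        })
        for f in sorted(qfits, key=lambda f: f.tau):
            lo = f.ci_lower[j] if f.ci_lower is not None else np.nan
            hi = f.ci_upper[j] if f.ci_upper is not None else np.nan
            est = f.beta[j]
            rows.append({
                "variable": name, "tau": f"{f.tau:g}", "estimate": est,
                "lower": lo, "upper": hi,
                "outside_ols_ci": bool(est < ols.ci_lower[j] or est > ols.ci_upper[j]),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full study; returns the artifact paths.

    Artifacts: ``analysis_table.csv``, ``ols.csv``, ``diagnostics.json``,
    ``qq.csv``, ``quantile_coefficients.csv``, ``selection.csv``,
    ``selection_paths.json``, ``comparison.csv``, ``join_report.json``,
    ``config.yaml``, ``run.log`` (plus ``raw/`` in simulate mode).

    Any stage failure is logged with the stage name and re-raised; partial
    outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("qbill")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": outdir / "run.log"}
    stage = "configure"
    try:
        config.to_yaml(outdir / "config.yaml")
        paths["config"] = outdir / "config.yaml"

        stage = "simulate"
        if config.mode == "simulate":
            t0 = time.perf_counter()
            sim = synthetic_data.simulate_study(
                config.n, config.seed, truth_factory=_TRUTH_FACTORIES[config.truth]
            )
            raw = synthetic_data.emit_raw_files(
                sim.X, sim.meta, sim.y, outdir / "raw",
                truth=sim.truth, procedure_code=config.procedure_code,
            )
            paths.update({f"raw_{k}": v for k, v in raw.items()})
            claims_path = raw["claims"]
            state_path = raw["state_covariates"]
            locality_path = raw["locality"]
            logger.info("simulate: n=%d truth=%s (%.2fs)", config.n, config.truth,
                        time.perf_counter() - t0)
        else:
            claims_path, state_path, locality_path = (
                config.claims_path, config.state_path, config.locality_path)

        stage = "assemble"
        t0 = time.perf_counter()
        claims, load_report = claims_io.load_claims(claims_path)
        study = claims_io.filter_study_population(claims, config.procedure_code)
        table, join_report = claims_io.assemble_design(
            study,
            claims_io.read_state_covariates(state_path),
            claims_io.read_locality(locality_path),
            denominator=config.denominator,
        )
        _write_csv(table, outdir / "analysis_table.csv", config, index=False)
        (outdir / "join_report.json").write_text(
            json.dumps({"load": load_report, "join": join_report}, indent=2, sort_keys=True))
        paths["analysis_table"] = outdir / "analysis_table.csv"
        paths["join_report"] = outdir / "join_report.json"
        logger.info("assemble: %d providers (%.2fs)", len(table), time.perf_counter() - t0)

        X = table[COVARIATE_NAMES].to_numpy(dtype=float)
        y = table["aggressiveness"].to_numpy(dtype=float)

        stage = "ols"
        t0 = time.perf_counter()
        ols = ols_baseline.fit_ols(X, y, feature_names=COVARIATE_NAMES,
                                   ci_level=config.bootstrap_level)
        _write_csv(ols.table(), outdir / "ols.csv", config, index=True)
        stat, pval = ols_baseline.lilliefors_test(
            ols.residuals, seed=np.random.SeedSequence((config.seed, 2)))
        _write_csv(ols_baseline.qq_data(ols.residuals), outdir / "qq.csv", config, index=False)
        (outdir / "diagnostics.json").write_text(json.dumps(
            {"lilliefors_statistic": stat, "lilliefors_p": pval,
             "r_squared": ols.r_squared, "sigma2": ols.sigma2},
            indent=2, sort_keys=True))
        paths.update(ols=outdir / "ols.csv", qq=outdir / "qq.csv",
                     diagnostics=outdir / "diagnostics.json")
        logger.info("ols: R^2=%.3f lilliefors p=%.4g (%.2fs)",
                    ols.r_squared, pval, time.perf_counter() - t0)

        stage = "quantreg"
        t0 = time.perf_counter()
        qfits = []
        for i, tau in enumerate(config.quantiles):
            fit = quantile_core.fit_quantreg(X, y, tau, feature_names=COVARIATE_NAMES)
            boot = quantile_core.bootstrap_ci(
                X, y, tau, B=config.bootstrap_B, level=config.bootstrap_level,
                seed=np.random.SeedSequence((config.seed, 3, i)))
            fit.ci_lower, fit.ci_upper = boot.ci_lower, boot.ci_upper
            fit.p_values = boot.p_values
            qfits.append(fit)
        _write_csv(quantile_core.quantile_table(qfits),
                   outdir / "quantile_coefficients.csv", config, index=True)
        paths["quantile_coefficients"] = outdir / "quantile_coefficients.csv"
        logger.info("quantreg: %d quantiles, B=%d (%.2fs)",
                    len(qfits), config.bootstrap_B, time.perf_counter() - t0)

        stage = "select"
        t0 = time.perf_counter()
        grid = penalized_selection.default_lambda_grid(
            config.lambda_min, config.lambda_max, config.lambda_points)
        selections = [
            penalized_selection.select_lambda(
                X, y, tau, grid=grid, cn_spec=config.cn, cut=config.threshold,
                feature_names=COVARIATE_NAMES, refit=config.refit)
            for tau in config.quantiles
        ]
        _write_csv(penalized_selection.selection_table(selections),
                   outdir / "selection.csv", config, index=True)
        (outdir / "selection_paths.json").write_text(json.dumps(
            {f"{s.tau:g}": {
                "lambda_hat": s.lambda_hat,
                "cn_value": s.cn_value,
                "support": [COVARIATE_NAMES[j] for j in s.support],
                "lambda_grid": [pt.lam for pt in s.path],
                "bic_path": [pt.bic for pt in s.path],
                "support_size_path": [pt.support_size for pt in s.path],
            } for s in selections},
            indent=2, sort_keys=True))
        paths["selection"] = outdir / "selection.csv"
        paths["selection_paths"] = outdir / "selection_paths.json"
        logger.info("select: grid %d points (%.2fs)", len(grid), time.perf_counter() - t0)

        stage = "report"
        _write_csv(comparison_report(ols, qfits), outdir / "comparison.csv",
                   config, index=False)
        paths["comparison"] = outdir / "comparison.csv"
        logger.info("pipeline complete: %s", outdir)
        return paths
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
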