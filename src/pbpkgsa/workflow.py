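"""End-to-end GSA-to-calibration workflow.

The recommended procedure for calibrating a PBPK model efficiently:

1. establish priors for all parameters and check that prior predictions
   cover the calibration data;
2. (optional, for expensive models) Morris screening to discard clearly
   non-influential parameters, normalised per output, convergence checked;
3. variance-based sensitivity analysis with eFAST, doubling the sample size
   until the convergence index drops below threshold (or a budget is hit);
4. classify parameters as influential / non-influential with a cut-off on
   the maximum index per parameter;
5. calibrate only the influential parameters by MCMC, fixing the
   non-influential ones at nominal values.

`run_workflow` executes these stages on a PK dataset and archives every
intermediate table together with a content-hash manifest so a rerun can be
checked for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ClassificationResult, classify as classify_parameters, normalize_morris
from .bayes import FitReport, McmcConfig, McmcTrace, fit_report, gelman_rubin, make_pbpk_predictor, run_mcmc
from .convergence import ConvergenceReport, convergence_index
from .gsa import DesignConfig, GSA_TIMES, efast_indices, indices_to_table, make_pbpk_adapter, run_gsa
from .pbpk import DoseSpec, ModelConfig, build_default_parameters, prior_predictive_check
from .priors import PriorTable, load_prior_table

__all__ = ["WorkflowConfig", "WorkflowResult", "run_workflow", "compare_calibrations"]

log = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    """Settings for one workflow run."""

    subset_mode: str = "original-21"        # original-21 | full-58 | custom
    custom_names: tuple[str, ...] = ()
    gsa_n: int = 512                        # starting eFAST base sample size
    gsa_n_max: int = 8192                   # auto-doubling budget
    efast_M: int = 4
    efast_Nr: int = 5
    cutoff: float = 0.05
    convergence_threshold: float = 0.1
    morris_screen: bool = False             # off by default; eFAST is primary
    morris_n: int = 64
    prior_draws: int = 200
    gsa_dose_mg: float = 1000.0
    times: tuple[float, ...] = GSA_TIMES
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    seed: int = 0
    proceed_if_unconverged: bool = True

    def parameter_names(self, table: PriorTable) -> list[str]:
        if self.subset_mode == "original-21":
            return table.subset("original").names
        if self.subset_mode == "full-58":
            return table.names
        if self.subset_mode == "custom":
            if not self.custom_names:
                raise ValueError("custom subset mode needs custom_names")
            missing = [n for n in self.custom_names if n not in table]
            if missing:
                raise ValueError(f"unknown parameters: {missing}")
            return list(self.custom_names)
        raise ValueError(f"unknown subset_mode {self.subset_mode!r}")


@dataclass
class WorkflowResult:
    prior_coverage: pd.DataFrame
    morris_table: pd.DataFrame | None
    index_table: pd.DataFrame
    convergence: ConvergenceReport
    gsa_n_final: int
    n_evaluations: int
    classification: ClassificationResult
    trace: McmcTrace
    psrf: np.ndarray
    report: FitReport
    manifest: dict | None = None

    @property
    def influential(self) -> list[str]:
        return self.classification.influential


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_workflow(
    config: WorkflowConfig,
    dataset: pd.DataFrame,
    table: PriorTable | None = None,
    outdir: str | Path | None = None,
    model_config: ModelConfig | None = None,
) -> WorkflowResult:
    """Run the five-stage workflow on a PK dataset; see the module docstring.

    Artifacts (long-format index tables, classification, trace, fit summary)
    are written under ``outdir`` with a JSON manifest of SHA-256 content
    hashes when ``outdir`` is given.
    """
    table = table or load_prior_table()
    names = config.parameter_names(table)
    timings = {}

    t0 = time.perf_counter()
    coverage = prior_predictive_check(
        table, dataset, config.prior_draws, seed=config.seed, config=model_config
    )
    timings["prior_predictive_s"] = time.perf_counter() - t0
    log.info("prior predictive coverage:\n%s", coverage)

    dose = DoseSpec(config.gsa_dose_mg)
    morris_table = None
    if config.morris_screen:
        t0 = time.perf_counter()
        adapter = make_pbpk_adapter(
            table, names, dose, config.times, model_config=model_config
        )
        morris_df = run_gsa(
            adapter, table,
            DesignConfig(method="morris", n=config.morris_n, seed=config.seed),
            names,
        )
        morris_table = normalize_morris(morris_df)
        screen = classify_parameters(morris_table, 0.1, metrics="morris")
        names = screen.influential
        timings["morris_s"] = time.perf_counter() - t0
        log.info("Morris screen kept %d of %d parameters", len(names), len(screen.frame))

    # eFAST with auto-doubling until the convergence index passes
    t0 = time.perf_counter()
    n = config.gsa_n
    n_evaluations = 0
    while True:
        adapter = make_pbpk_adapter(
            table, names, dose, config.times, model_config=model_config
        )
        sobol = efast_indices(
            adapter, len(names), n, M=config.efast_M, Nr=config.efast_Nr,
            seed=config.seed,
        )
        n_evaluations += adapter.n_evaluations
        conv = convergence_index(
            sobol, method="efast", threshold=config.convergence_threshold
        )
        log.info("eFAST n=%d convergence index %.4f", n, conv.index)
        if conv.converged or n * 2 > config.gsa_n_max:
            break
        n *= 2
    if not conv.converged:
        msg = (
            f"eFAST convergence index {conv.index:.3f} above threshold "
            f"{config.convergence_threshold} at budget n={n}"
        )
        if not config.proceed_if_unconverged:
            raise RuntimeError(msg)
        log.warning("%s; proceeding per configuration", msg)
    index_table = indices_to_table(sobol, names, adapter.output_index, "efast", n)
    timings["gsa_s"] = time.perf_counter() - t0

    classification = classify_parameters(index_table, config.cutoff, metrics="sobol")
    influential = classification.influential
    log.info(
        "cut-off %.2g: %d influential of %d", config.cutoff, len(influential), len(names)
    )

    t0 = time.perf_counter()
    base = build_default_parameters(table)
    predictor = make_pbpk_predictor(dataset, base, model_config)
    trace = run_mcmc(predictor, table, influential, dataset, config.mcmc)
    psrf = gelman_rubin(trace)
    report = fit_report(trace, dataset, predictor, seed=config.seed, label=config.subset_mode)
    timings["mcmc_s"] = time.perf_counter() - t0

    manifest = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts = {
            "prior_coverage.csv": coverage,
            "index_table.csv": index_table,
            "classification.csv": classification.frame,
            "trace.csv": trace.to_frame(),
            "fit_summary.csv": report.summary().to_frame("value"),
        }
        if morris_table is not None:
            artifacts["morris_table.csv"] = morris_table
        manifest = {"artifacts": {}, "timings_s": timings, "config": {
            "subset_mode": config.subset_mode, "cutoff": config.cutoff,
            "gsa_n_final": n, "seed": config.seed,
            "influential": influential,
        }}
        for fname, df in artifacts.items():
            path = outdir / fname
            df.to_csv(path, index=False)
            manifest["artifacts"][fname] = _sha256(path)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return WorkflowResult(
        prior_coverage=coverage,
        morris_table=morris_table,
        index_table=index_table,
        convergence=conv,
        gsa_n_final=n,
        n_evaluations=n_evaluations,
        classification=classification,
        trace=trace,
        psrf=psrf,
        report=report,
        manifest=manifest,
    )


def compare_calibrations(
    reports: Mapping[str, FitReport],
    traces: Mapping[str, McmcTrace] | None = None,
) -> pd.DataFrame:
    """Tabulate accuracy/precision across calibrations of the same dataset.

    One row per calibration: residual median and IQR, per-study R2 range,
    LnData summary.  When traces are given, posterior-median shifts of every
    parameter shared between calibrations are attached in
    ``.attrs['median_shifts']``.
    """
    if len(reports) < 1:
        raise ValueError("need at least one fit report")
    sizes = {name: len(r.residuals) for name, r in reports.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"reports cover different datasets: {sizes}")
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "calibration": name,
                "residual_median": r.residual_median,
                "residual_iqr": r.residual_iqr,
                "r2_min": float(r.r2_by_study.min()),
                "r2_median": float(r.r2_by_study.median()),
                "lnl_median": r.lnl_summary["median"],
                "lnl_q25": r.lnl_summary["q25"],
                "lnl_q75": r.lnl_summary["q75"],
            }
        )
    out = pd.DataFrame(rows)
    if traces:
        medians = {
            name: {
                p: float(np.median(t.params.reshape(-1, t.params.shape[2])[:, j]))
                for j, p in enumerate(t.names)
            }
            for name, t in traces.items()
        }
        shifts = {}
        names = list(medians)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared = sorted(set(medians[a]) & set(medians[b]))
                shifts[f"{a}->{b}"] = {
                    p: medians[b][p] / medians[a][p] for p in shared
                }
        out.attrs["median_shifts"] = shifts
    return out
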