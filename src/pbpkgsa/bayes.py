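"""Bayesian calibration by Metropolis-within-Gibbs MCMC.

A chosen subset of PBPK parameters is estimated against plasma-concentration
data while the remaining parameters stay fixed at nominal values.  The data
model is lognormal: for observation i with measured concentration c_i and
model prediction chat_i,

    LL = sum_i [ -(y_i - yhat_i)^2 / (2 s_{j[i]}^2) - 0.5 ln(2 pi s_{j[i]}^2) ]

with y = ln c, yhat = ln chat and one error variance s_j^2 per data type j
(APAP, AG, AS).  Parameters are sampled one component at a time with a
random-walk Metropolis step on the log scale; the error variances are
additional Gibbs components with a log-uniform prior.  Proposal step sizes
adapt toward a 20-40% acceptance rate during burn-in only, so the kept
portion of each chain is a fixed-kernel Markov chain.  Four independent
chains are run by default and compared with the Gelman-Rubin potential scale
reduction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pbpk import COMPOUNDS, ModelConfig, SimulationError, dataset_doses, simulate
from .priors import PriorTable

__all__ = [
    "log_likelihood",
    "McmcConfig",
    "McmcTrace",
    "FitReport",
    "metropolis_within_gibbs",
    "make_pbpk_predictor",
    "run_mcmc",
    "gelman_rubin",
    "fit_report",
]

LOG_FLOOR = 1e-12


def log_likelihood(
    y: np.ndarray, yhat: np.ndarray, s2: np.ndarray, type_idx: np.ndarray
) -> float:
    """Lognormal data log-likelihood.

    ``y``/``yhat`` are log-transformed observed and predicted values; ``s2``
    holds one log-scale error variance per data type and ``type_idx`` maps
    each point to its type.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("error variances must be > 0")
    s2i = s2[np.asarray(type_idx, dtype=int)]
    return float(
        np.sum(-0.5 * (y - yhat) ** 2 / s2i - 0.5 * np.log(2.0 * np.pi * s2i))
    )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; production runs use far more iterations (the
    reference analyses used 300,000), the default is a test scale."""

    n_iter: int = 10_000
    n_chains: int = 4
    burn_in: float = 0.5          # fraction of iterations discarded
    thin: int = 10
    seed: int = 0
    step0: float = 0.25           # initial log-scale proposal sd
    adapt_interval: int = 25
    target_acceptance: tuple[float, float] = (0.2, 0.4)
    s2_bounds: tuple[float, float] = (1e-3, 10.0)
    s2_init: float = 0.1


@dataclass
class McmcTrace:
    """Multi-chain samples of calibrated parameters, error variances and
    log-likelihood (LnData)."""

    params: np.ndarray            # (chains, kept, k) natural units
    s2: np.ndarray                # (chains, kept, n_types)
    lnl: np.ndarray               # (chains, kept)
    names: list[str]
    config: McmcConfig
    acceptance: np.ndarray | None = None

    @property
    def flat(self) -> pd.DataFrame:
        k = self.params.shape[2]
        df = pd.DataFrame(self.params.reshape(-1, k), columns=self.names)
        for j, cpd in enumerate(COMPOUNDS[: self.s2.shape[2]]):
            df[f"s2_{cpd}"] = self.s2[:, :, j].reshape(-1)
        df["LnData"] = self.lnl.reshape(-1)
        return df

    def to_frame(self) -> pd.DataFrame:
        """Long export: iteration, chain, parameter columns, LnData."""
        frames = []
        for c in range(self.params.shape[0]):
            df = pd.DataFrame(self.params[c], columns=self.names)
            for j, cpd in enumerate(COMPOUNDS[: self.s2.shape[2]]):
                df[f"s2_{cpd}"] = self.s2[c, :, j]
            df["LnData"] = self.lnl[c]
            df.insert(0, "iteration", np.arange(len(df)))
            df.insert(1, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def metropolis_within_gibbs(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    step0: np.ndarray | float = 0.25,
    seed: int | np.random.Generator = 0,
    adapt_until: int = 0,
    adapt_interval: int = 25,
    target_acceptance: tuple[float, float] = (0.2, 0.4),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component-at-a-time random-walk Metropolis sampler.

    Proposals are Gaussian per component; step sizes adapt geometrically
    toward the target acceptance window for the first ``adapt_until``
    iterations and are frozen afterwards.  A log-posterior of ``-inf``
    (or an exception mapped to it by the caller) rejects the proposal, so a
    failed model evaluation never aborts the chain.  Returns (samples,
    log-posterior trace, per-component acceptance rate after adaptation).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    k = x.size
    step = np.full(k, step0, dtype=float) if np.isscalar(step0) else np.asarray(step0, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    samples = np.empty((n_iter, k))
    lps = np.empty(n_iter)
    accepted = np.zeros(k)
    proposed = np.zeros(k)
    window_acc = np.zeros(k)
    window_n = np.zeros(k)
    for it in range(n_iter):
        for j in range(k):
            prop = x.copy()
            prop[j] += step[j] * rng.standard_normal()
            lp_prop = log_post(prop)
            proposed[j] += 1
            window_n[j] += 1
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted[j] += 1
                window_acc[j] += 1
        if it < adapt_until and (it + 1) % adapt_interval == 0:
            rate = window_acc / np.maximum(window_n, 1)
            step[rate > target_acceptance[1]] *= 1.4
            step[rate < target_acceptance[0]] /= 1.4
            window_acc[:] = 0
            window_n[:] = 0
            if it + adapt_interval >= adapt_until:
                accepted[:] = 0
                proposed[:] = 0
        samples[it] = x
        lps[it] = lp
    return samples, lps, accepted / np.maximum(proposed, 1)


def make_pbpk_predictor(
    dataset: pd.DataFrame,
    base_params: Mapping[str, float],
    model_config: ModelConfig | None = None,
) -> Callable[[Mapping[str, float]], np.ndarray]:
    """Precompile the dataset layout into a fast predictor.

    The returned callable maps a full parameter dict to the model-predicted
    concentration (mg/L) for every dataset row, simulating each study once.
    """
    dataset = dataset.reset_index(drop=True)
    doses = dataset_doses(dataset)
    studies = []
    for sid, g in dataset.groupby("study_id", sort=False):
        times = np.unique(g["time_h"].to_numpy(dtype=float))
        lookup = {t: i for i, t in enumerate(times)}
        sel = []
        for ci, cpd in enumerate(COMPOUNDS):
            gc = g[g["compound"] == cpd]
            rows = gc.index.to_numpy()
            cols = np.array([lookup[t] for t in gc["time_h"]], dtype=int)
            sel.append((ci, rows, cols))
        studies.append((doses[str(sid)], times, sel))
    n_rows = len(dataset)
    base = dict(base_params)

    def predict(params: Mapping[str, float]) -> np.ndarray:
        full = dict(base)
        full.update(params)
        out = np.empty(n_rows)
        for dose, times, sel in studies:
            res = simulate(full, dose, times, model_config)
            mat = res.plasma.to_numpy()
            for ci, rows, cols in sel:
                out[rows] = mat[cols, ci]
        return out

    return predict


def run_mcmc(
    predict: Callable[[Mapping[str, float]], np.ndarray],
    table: PriorTable,
    calibrate: Sequence[str],
    data: pd.DataFrame,
    config: McmcConfig | None = None,
) -> McmcTrace:
    """Calibrate ``calibrate`` parameters against ``data`` (remaining
    parameters are whatever ``predict`` holds fixed).

    Sampling is on the log scale: truncated-lognormal priors become truncated
    normals, uniform priors keep their natural-scale density (Jacobian
    included), and each data type's error variance is a log-uniform component.
    Deterministic under fixed seeds; identical seeds give identical traces.
    """
    config = config or McmcConfig()
    calibrate = list(calibrate)
    missing = [n for n in calibrate if n not in table]
    if missing:
        raise ValueError(f"parameters not in prior table: {missing}")
    if data.empty:
        raise ValueError("no calibration data")
    data = data.reset_index(drop=True)
    y = np.log(data["conc"].to_numpy(dtype=float))
    types_present = [c for c in COMPOUNDS if (data["compound"] == c).any()]
    type_idx = np.array([types_present.index(c) for c in data["compound"]])
    n_types = len(types_present)
    k = len(calibrate)

    specs = [table[n] for n in calibrate]
    bounds = np.array([[math.log(s.support[0]), math.log(s.support[1])] for s in specs])
    lo_s2, hi_s2 = math.log(config.s2_bounds[0]), math.log(config.s2_bounds[1])

    def log_prior(xlog: np.ndarray) -> float:
        total = 0.0
        for j, s in enumerate(specs):
            v = xlog[j]
            if not (bounds[j, 0] <= v <= bounds[j, 1]):
                return -np.inf
            if s.family == "uniform":
                total += v            # Jacobian of x -> ln x
            else:
                z = (v - math.log(s.loc)) / s.spread
                total += -0.5 * z * z
        for j in range(n_types):
            t = xlog[k + j]
            if not (lo_s2 <= t <= hi_s2):
                return -np.inf
        return total

    def log_post(xlog: np.ndarray) -> float:
        lp = log_prior(xlog)
        if not np.isfinite(lp):
            return -np.inf
        params = {n: math.exp(xlog[j]) for j, n in enumerate(calibrate)}
        try:
            pred = predict(params)
        except SimulationError:
            return -np.inf
        yhat = np.log(np.clip(pred, LOG_FLOOR, None))
        s2 = np.exp(xlog[k:])
        return lp + log_likelihood(y, yhat, s2, type_idx)

    burn = int(config.n_iter * config.burn_in)
    kept = len(range(burn, config.n_iter, config.thin))
    params_out = np.empty((config.n_chains, kept, k))
    s2_out = np.empty((config.n_chains, kept, n_types))
    lnl_out = np.empty((config.n_chains, kept))
    acc = np.empty((config.n_chains, k + n_types))

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        # overdispersed start: a prior draw squeezed toward the prior centre
        x0 = np.empty(k + n_types)
        for j, s in enumerate(specs):
            draw = math.log(s.sample(1, rng)[0])
            centre = 0.5 * (bounds[j, 0] + bounds[j, 1])
            x0[j] = centre + 0.5 * (draw - centre)
        x0[k:] = math.log(config.s2_init)
        samples, lps, a = metropolis_within_gibbs(
            log_post, x0, config.n_iter,
            step0=config.step0, seed=rng,
            adapt_until=burn,
            adapt_interval=config.adapt_interval,
            target_acceptance=config.target_acceptance,
        )
        sel = np.arange(burn, config.n_iter, config.thin)
        params_out[c] = np.exp(samples[sel][:, :k])
        s2_out[c] = np.exp(samples[sel][:, k:])
        # report the data log-likelihood (LnData), not the posterior
        lnl_out[c] = np.array(
            [
                log_likelihood(
                    y,
                    np.log(np.clip(predict(
                        {n: params_out[c, i, j] for j, n in enumerate(calibrate)}
                    ), LOG_FLOOR, None)),
                    s2_out[c, i],
                    type_idx,
                )
                for i, _ in enumerate(sel)
            ]
        )
        acc[c] = a
    return McmcTrace(
        params=params_out, s2=s2_out, lnl=lnl_out,
        names=calibrate, config=config, acceptance=acc,
    )


def gelman_rubin(chains: np.ndarray | McmcTrace) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per sampled quantity.

    ``chains`` is an (m, n, k) array (or an :class:`McmcTrace`, whose
    parameter and variance components are stacked).  Values near 1 indicate
    that the between-chain variance has vanished relative to the within-chain
    variance; < 1.1 is the customary convergence call.
    """
    if isinstance(chains, McmcTrace):
        chains = np.concatenate([chains.params, chains.s2], axis=2)
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, _ = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    means = chains.mean(axis=1)                      # (m, k)
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # (k,)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(var_plus / W)
    return np.where(W > 0, psrf, 1.0)


@dataclass
class FitReport:
    """Accuracy/precision summary of a calibrated model."""

    residuals: np.ndarray          # log10(pred) - log10(obs) per data point
    residual_median: float
    residual_iqr: float
    r2_by_study: pd.Series         # on log10 predictions vs observations
    lnl_summary: dict
    predictions: np.ndarray        # at the posterior median parameters
    pi_low: np.ndarray
    pi_high: np.ndarray
    pi_level: float
    pi_coverage: float
    label: str = ""

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "residual_median": self.residual_median,
                "residual_iqr": self.residual_iqr,
                "r2_min": float(self.r2_by_study.min()),
                "r2_median": float(self.r2_by_study.median()),
                "lnl_median": self.lnl_summary["median"],
                "pi_coverage": self.pi_coverage,
            }
        )


def fit_report(
    trace: McmcTrace,
    data: pd.DataFrame,
    predict: Callable[[Mapping[str, float]], np.ndarray],
    n_ppc: int = 200,
    pi_level: float = 0.95,
    seed: int = 0,
    label: str = "",
) -> FitReport:
    """Posterior model-performance report.

    Point predictions use the posterior median of each calibrated parameter;
    prediction intervals come from posterior predictive draws (parameter draw
    + lognormal measurement noise at the drawn error variance).
    """
    if trace.params.size == 0:
        raise ValueError("empty trace")
    data = data.reset_index(drop=True)
    obs = data["conc"].to_numpy(dtype=float)
    types_present = [c for c in COMPOUNDS if (data["compound"] == c).any()]
    type_idx = np.array([types_present.index(c) for c in data["compound"]])

    flat_p = trace.params.reshape(-1, trace.params.shape[2])
    flat_s2 = trace.s2.reshape(-1, trace.s2.shape[2])
    med = {n: float(np.median(flat_p[:, j])) for j, n in enumerate(trace.names)}
    pred = np.clip(predict(med), LOG_FLOOR, None)
    residuals = np.log10(pred) - np.log10(obs)

    r2 = {}
    log_obs = np.log10(obs)
    log_pred = np.log10(pred)
    for sid, g in data.groupby("study_id", sort=False):
        idx = g.index.to_numpy()
        ss_res = float(((log_obs[idx] - log_pred[idx]) ** 2).sum())
        ss_tot = float(((log_obs[idx] - log_obs[idx].mean()) ** 2).sum())
        r2[str(sid)] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, flat_p.shape[0], size=min(n_ppc, flat_p.shape[0]))
    ppc = np.empty((draws.size, len(data)))
    for i, d in enumerate(draws):
        pars = {n: float(flat_p[d, j]) for j, n in enumerate(trace.names)}
        mu = np.clip(predict(pars), LOG_FLOOR, None)
        sd = np.sqrt(flat_s2[d][type_idx])
        ppc[i] = mu * np.exp(sd * rng.standard_normal(len(data)))
    alpha = (1.0 - pi_level) / 2.0
    pi_low = np.quantile(ppc, alpha, axis=0)
    pi_high = np.quantile(ppc, 1.0 - alpha, axis=0)
    coverage = float(((obs >= pi_low) & (obs <= pi_high)).mean())

    lnl = trace.lnl.reshape(-1)
    lnl_summary = {
        "median": float(np.median(lnl)),
        "mean": float(np.mean(lnl)),
        "sd": float(np.std(lnl, ddof=1)) if lnl.size > 1 else 0.0,
        "q25": float(np.quantile(lnl, 0.25)),
        "q75": float(np.quantile(lnl, 0.75)),
    }
    q25, q75 = np.quantile(residuals, [0.25, 0.75])
    return FitReport(
        residuals=residuals,
        residual_median=float(np.median(residuals)),
        residual_iqr=float(q75 - q25),
        r2_by_study=pd.Series(r2),
        lnl_summary=lnl_summary,
        predictions=pred,
        pi_low=pi_low,
        pi_high=pi_high,
        pi_level=pi_level,
        pi_coverage=coverage,
        label=label,
    )
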