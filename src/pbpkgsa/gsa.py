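"""Global sensitivity analysis engines.

Two families of methods, all operating on the unit hypercube (parameters are
mapped to natural units through their priors, linearly for uniform priors and
log-linearly for truncated lognormal priors):

* **Morris elementary-effects screening** with the Campolongo refinements:
  mean absolute elementary effect mu*, trajectory pools generated by Latin
  Hypercube sampling with the most spread-out subset selected.

* **Variance-based Sobol estimators**: the spectral eFAST estimator and the
  Monte-Carlo Jansen (two-matrix) and Owen (three-matrix) estimators.  All
  report main effect S, total effect ST and their difference (interaction).

Model-evaluation budgets for a base sample size n and p parameters:
Morris n*(p+1), eFAST n*p, Jansen n*(p+2), Owen n*(3p+2).

Estimators accept a vectorised model ``f(U) -> (N,)`` or ``(N, n_out)`` and
compute indices for every output column at once, which is how the per
compound-and-time-point index tables of the PBPK analysis are produced.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .pbpk import COMPOUNDS, DoseSpec, ModelConfig, SimulationError, plasma_outputs
from .priors import PriorTable, unit_to_param

__all__ = [
    "DesignConfig",
    "MorrisIndices",
    "SobolIndices",
    "evaluation_count",
    "morris_design",
    "morris_indices",
    "morris",
    "efast_design",
    "efast_indices",
    "jansen_indices",
    "jansen",
    "owen_indices",
    "owen",
    "sobol_bruteforce_oracle",
    "make_pbpk_adapter",
    "run_gsa",
    "GSA_TIMES",
]

log = logging.getLogger(__name__)

#: representative post-dose sampling times (h) at which indices are computed
GSA_TIMES = (0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0)

_BUDGET = {
    "morris": lambda n, p: n * (p + 1),
    "efast": lambda n, p: n * p,
    "jansen": lambda n, p: n * (p + 2),
    "owen": lambda n, p: n * (3 * p + 2),
}


def evaluation_count(method: str, n: int, p: int) -> int:
    """Total model evaluations used by ``method`` at base sample size n."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    try:
        return _BUDGET[method](n, p)
    except KeyError:
        raise ValueError(f"unknown GSA method {method!r}") from None


@dataclass
class DesignConfig:
    """Settings for one GSA run."""

    method: str = "efast"
    n: int = 1024
    seed: int = 0
    morris_levels: int = 8
    morris_pool: int | None = None  # default 100 * r trajectories
    efast_M: int = 4
    efast_Nr: int = 5

    def __post_init__(self):
        if self.method not in _BUDGET:
            raise ValueError(f"unknown GSA method {self.method!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class MorrisIndices:
    """Elementary-effect summaries, one row per parameter per output."""

    mu: np.ndarray        # (p, n_out) mean elementary effect
    mu_star: np.ndarray   # (p, n_out) mean absolute elementary effect
    sigma: np.ndarray     # (p, n_out) std of elementary effects
    n: int = 0


@dataclass
class SobolIndices:
    """Main/total Sobol indices per parameter per output (clipped to
    0 <= S <= ST <= 1; negative estimates are estimator noise)."""

    S: np.ndarray         # (p, n_out)
    ST: np.ndarray        # (p, n_out)
    method: str = ""
    n: int = 0
    #: per-resample estimates (R, p, n_out), present when the estimator was
    #: run with several random-phase resamples (eFAST)
    S_resamples: np.ndarray | None = None
    ST_resamples: np.ndarray | None = None

    @property
    def interaction(self) -> np.ndarray:
        return self.ST - self.S


def _clip(S, ST):
    S = np.clip(S, 0.0, 1.0)
    ST = np.clip(ST, 0.0, 1.0)
    return S, np.maximum(ST, S)


def _as_2d(y):
    y = np.asarray(y, dtype=float)
    return y[:, None] if y.ndim == 1 else y


# ---------------------------------------------------------------------------
# Morris elementary effects

def _lhs(pool_size: int, p: int, rng) -> np.ndarray:
    cut = (np.arange(pool_size)[:, None] + rng.uniform(size=(pool_size, p))) / pool_size
    for j in range(p):
        cut[:, j] = cut[rng.permutation(pool_size), j]
    return cut


def _build_trajectory(base: np.ndarray, delta: float, grid: np.ndarray, rng) -> np.ndarray:
    """One OAT trajectory of p+1 points; each step moves one coordinate by
    +-delta, staying inside [0, 1]."""
    p = base.size
    direction = rng.choice([-1.0, 1.0], size=p)
    start = np.empty(p)
    for j in range(p):
        # snap the LHS coordinate to a grid level admissible for the move
        lo, hi = (0.0, 1.0 - delta) if direction[j] > 0 else (delta, 1.0)
        ok = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
        start[j] = ok[np.argmin(np.abs(ok - base[j]))]
    order = rng.permutation(p)
    traj = np.empty((p + 1, p))
    traj[0] = start
    x = start.copy()
    for k, j in enumerate(order):
        x = x.copy()
        x[j] += direction[j] * delta
        traj[k + 1] = x
    return np.clip(traj, 0.0, 1.0)


def _trajectory_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Campolongo distance: sum of Euclidean distances between every pair of
    points of two distinct trajectories."""
    if np.array_equal(a, b):
        return 0.0
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return float(d.sum())


def select_trajectories(
    pool: np.ndarray, r: int, brute_force_limit: int = 200_000
) -> np.ndarray:
    """Pick the r trajectories maximising the spread criterion
    sqrt(sum of squared pairwise distances).

    Exhaustive over all C(pool, r) subsets when that count is small enough,
    otherwise greedy (best pair first, then best addition)."""
    m = pool.shape[0]
    if r > m:
        raise ValueError("r exceeds pool size")
    if r == m:
        return np.arange(m)
    dist = np.zeros((m, m))
    for l in range(m):
        for k in range(l + 1, m):
            dist[l, k] = dist[k, l] = _trajectory_distance(pool[l], pool[k])
    d2 = dist ** 2

    if math.comb(m, r) <= brute_force_limit:
        best, best_val = None, -1.0
        for combo in itertools.combinations(range(m), r):
            idx = np.array(combo)
            val = d2[np.ix_(idx, idx)].sum() / 2.0
            if val > best_val:
                best_val, best = val, idx
        return best

    # greedy fallback for the default large pools
    l, k = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [l, k]
    while len(chosen) < r:
        rest = [i for i in range(m) if i not in chosen]
        gains = [d2[i, chosen].sum() for i in rest]
        chosen.append(rest[int(np.argmax(gains))])
    return np.sort(np.array(chosen))


def morris_design(
    p: int,
    r_trajectories: int,
    levels: int = 8,
    pool_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate r OAT trajectories, shape (r, p+1, p), on an even-``levels``
    grid with step delta = levels / (2*(levels-1)); a Latin-Hypercube pool of
    candidate trajectories is thinned by the Campolongo spread criterion."""
    if levels % 2 != 0:
        raise ValueError("levels must be even")
    if pool_size is None:
        # spread-maximising subselection pays off for small designs; at large
        # r the LHS pool itself is the design (selection would cost O(pool^2))
        pool_size = 100 * r_trajectories if r_trajectories <= 20 else r_trajectories
    if r_trajectories > pool_size:
        raise ValueError("r_trajectories exceeds pool_size")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels) / (levels - 1.0)
    bases = _lhs(pool_size, p, rng)
    pool = np.stack([_build_trajectory(b, delta, grid, rng) for b in bases])
    idx = select_trajectories(pool, r_trajectories)
    return pool[idx]


def morris_indices(trajectories: np.ndarray, Y: np.ndarray) -> MorrisIndices:
    """Elementary-effect statistics from trajectory evaluations.

    ``Y`` holds the model output at every trajectory point, shape
    (r, p+1) or (r, p+1, n_out) (or flattened rows in trajectory order).
    """
    traj = np.asarray(trajectories, dtype=float)
    r, pp1, p = traj.shape
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(r, pp1)
    if Y.shape[:1] != (r,) and Y.shape[0] == r * pp1:
        Y = Y.reshape(r, pp1, -1)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    if Y.shape[:2] != (r, pp1):
        raise ValueError("outputs do not align with trajectory rows")
    n_out = Y.shape[2]

    ee = np.full((p, r, n_out), np.nan)
    for t in range(r):
        steps = np.diff(traj[t], axis=0)          # (p, p) one nonzero per row
        for k in range(p):
            j = int(np.argmax(np.abs(steps[k])))
            ee[j, t] = (Y[t, k + 1] - Y[t, k]) / steps[k, j]
    return MorrisIndices(
        mu=ee.mean(axis=1),
        mu_star=np.abs(ee).mean(axis=1),
        sigma=ee.std(axis=1, ddof=1) if r > 1 else np.zeros((p, n_out)),
        n=r,
    )


def morris(
    func: Callable[[np.ndarray], np.ndarray],
    p: int,
    r_trajectories: int,
    levels: int = 8,
    pool_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> MorrisIndices:
    """Convenience wrapper: design, evaluate, summarise."""
    traj = morris_design(p, r_trajectories, levels, pool_size, seed)
    Y = _as_2d(func(traj.reshape(-1, p)))
    return morris_indices(traj, Y.reshape(r_trajectories, p + 1, -1))


# ---------------------------------------------------------------------------
# eFAST

def _efast_frequencies(n: int, M: int, p: int):
    omega_max = (n - 1) // (2 * M)
    comp_max = omega_max // (2 * M)
    if comp_max < 1:
        n_min = 4 * M * M + 1
        raise ValueError(
            f"n={n} too small for eFAST with M={M}; need n >= {n_min}"
        )
    if p == 1:
        comp = np.array([], dtype=int)
    elif comp_max >= p - 1:
        comp = np.floor(np.linspace(1, comp_max, p - 1)).astype(int)
    else:
        comp = 1 + (np.arange(p - 1) % comp_max)
    return omega_max, comp


def efast_design(
    p: int, n: int, M: int = 4, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, int]:
    """Unit-hypercube samples along the eFAST search curves.

    Returns (U, omega_max) with ``U`` of shape (p, n, p): one curve of n
    points per focal parameter, the focal parameter driven at the maximum
    admissible frequency and the complementary parameters at low cycling
    frequencies, all with random phase shift.
    """
    rng = np.random.default_rng(seed)
    omega_max, comp = _efast_frequencies(n, M, p)
    s = 2.0 * np.pi * np.arange(n) / n
    U = np.empty((p, n, p))
    for i in range(p):
        freqs = np.empty(p)
        freqs[i] = omega_max
        freqs[[j for j in range(p) if j != i]] = comp
        phase = rng.uniform(0.0, 2.0 * np.pi, size=p)
        U[i] = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phase[None, :])) / np.pi
    return U, omega_max


def efast_indices_from_outputs(Y: np.ndarray, omega_max: int, M: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Spectral Sobol indices from curve outputs ``Y`` of shape (p, n) or
    (p, n, n_out); returns unclipped (S, ST) of shape (p, n_out)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    p, n, n_out = Y.shape
    F = np.fft.rfft(Y, axis=1) / n
    power = np.abs(F) ** 2          # (p, n_freq, n_out)
    spectrum = 2.0 * power[:, 1: (n - 1) // 2 + 1, :]
    V = spectrum.sum(axis=1)
    if np.any(V <= 0):
        raise ValueError("zero output variance; Sobol indices undefined")
    harmonics = omega_max * np.arange(1, M + 1)
    S = spectrum[:, harmonics - 1, :].sum(axis=1) / V
    low = spectrum[:, : omega_max // 2, :].sum(axis=1)
    ST = 1.0 - low / V
    return S, ST


def efast_indices(
    func: Callable[[np.ndarray], np.ndarray],
    p: int,
    n: int,
    M: int = 4,
    Nr: int = 1,
    seed: int | np.random.Generator = 0,
) -> SobolIndices:
    """eFAST estimate averaged over ``Nr`` random-phase resamples.

    Budget: n*p model evaluations per resample.
    """
    rng = np.random.default_rng(seed)
    S_r, ST_r = [], []
    for _ in range(Nr):
        U, omega_max = efast_design(p, n, M, rng)
        Y = _as_2d(func(U.reshape(-1, p)))
        S, ST = efast_indices_from_outputs(
            Y.reshape(p, n, -1), omega_max, M
        )
        S, ST = _clip(S, ST)
        S_r.append(S)
        ST_r.append(ST)
    S_r, ST_r = np.stack(S_r), np.stack(ST_r)
    S, ST = _clip(S_r.mean(axis=0), ST_r.mean(axis=0))
    return SobolIndices(
        S=S, ST=ST, method="efast", n=n,
        S_resamples=S_r if Nr > 1 else None,
        ST_resamples=ST_r if Nr > 1 else None,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo Sobol estimators

def jansen_indices(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray) -> SobolIndices:
    """Jansen pick-freeze estimator from raw evaluations.

    ``fAB[i]`` is the model at matrix A with column i replaced from B.
    ST_i = mean((fA - fAB_i)^2) / (2V);  S_i = 1 - mean((fB - fAB_i)^2) / (2V)
    with V the sample variance of the pooled base evaluations.
    """
    fA, fB = _as_2d(fA), _as_2d(fB)
    fAB = np.asarray(fAB, dtype=float)
    if fAB.ndim == 2:
        fAB = fAB[:, :, None]
    V = np.concatenate([fA, fB]).var(axis=0, ddof=1)
    if np.any(V <= 0):
        raise ValueError("zero output variance; Sobol indices undefined")
    ST = ((fA[None] - fAB) ** 2).mean(axis=1) / (2.0 * V)
    S = 1.0 - ((fB[None] - fAB) ** 2).mean(axis=1) / (2.0 * V)
    S, ST = _clip(S, ST)
    return SobolIndices(S=S, ST=ST, method="jansen", n=fA.shape[0])


def jansen(
    func: Callable[[np.ndarray], np.ndarray],
    p: int,
    n: int,
    seed: int | np.random.Generator = 0,
    return_evals: bool = False,
):
    """Two-matrix Jansen estimator; budget n*(p+2) model evaluations."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(size=(n, p))
    B = rng.uniform(size=(n, p))
    fA, fB = _as_2d(func(A)), _as_2d(func(B))
    fAB = np.empty((p, n, fA.shape[1]))
    for i in range(p):
        AB = A.copy()
        AB[:, i] = B[:, i]
        fAB[i] = _as_2d(func(AB))
    result = jansen_indices(fA, fB, fAB)
    if return_evals:
        return result, {"fA": fA, "fB": fB, "fAB": fAB}
    return result


def owen_indices(
    fA: np.ndarray, fB: np.ndarray,
    fCA: np.ndarray, fCB: np.ndarray, fBA: np.ndarray,
) -> SobolIndices:
    """Owen three-matrix estimator from raw evaluations.

    With base matrices A, B, C: ``fCA[i]`` = f(C with col i from A),
    ``fCB[i]`` = f(C with col i from B), ``fBA[i]`` = f(B with col i from A).
    Main effect via the correlated-difference identity
    2 V_i = E[(f(C_{i<-A}) - f(C_{i<-B})) (f(B_{i<-A}) - f(B))];
    total effect via Jansen on (B, B_{i<-A}), which differ only in column i.
    """
    fA, fB = _as_2d(fA), _as_2d(fB)
    blocks = []
    for blk in (fCA, fCB, fBA):
        blk = np.asarray(blk, dtype=float)
        blocks.append(blk[:, :, None] if blk.ndim == 2 else blk)
    fCA, fCB, fBA = blocks
    V = np.concatenate([fA, fB]).var(axis=0, ddof=1)
    if np.any(V <= 0):
        raise ValueError("zero output variance; Sobol indices undefined")
    S = ((fCA - fCB) * (fBA - fB[None])).mean(axis=1) / (2.0 * V)
    ST = ((fB[None] - fBA) ** 2).mean(axis=1) / (2.0 * V)
    S, ST = _clip(S, ST)
    return SobolIndices(S=S, ST=ST, method="owen", n=fA.shape[0])


def owen(
    func: Callable[[np.ndarray], np.ndarray],
    p: int,
    n: int,
    seed: int | np.random.Generator = 0,
    return_evals: bool = False,
):
    """Three-matrix Owen estimator; budget n*(3p+2) model evaluations."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(size=(n, p))
    B = rng.uniform(size=(n, p))
    C = rng.uniform(size=(n, p))
    fA, fB = _as_2d(func(A)), _as_2d(func(B))
    n_out = fA.shape[1]
    fCA = np.empty((p, n, n_out))
    fCB = np.empty((p, n, n_out))
    fBA = np.empty((p, n, n_out))
    for i in range(p):
        for target, base, src in ((fCA, C, A), (fCB, C, B), (fBA, B, A)):
            X = base.copy()
            X[:, i] = src[:, i]
            target[i] = _as_2d(func(X))
    result = owen_indices(fA, fB, fCA, fCB, fBA)
    if return_evals:
        return result, {"fA": fA, "fB": fB, "fCA": fCA, "fCB": fCB, "fBA": fBA}
    return result


def sobol_bruteforce_oracle(
    func: Callable[[np.ndarray], np.ndarray],
    p: int,
    n_outer: int,
    n_inner: int,
    seed: int | np.random.Generator = 0,
) -> SobolIndices:
    """Double-loop Monte-Carlo conditional-variance estimate of S and ST.

    Intended as an independent cross-check for cheap analytic functions only;
    budget 2 * p * n_outer * n_inner evaluations.
    """
    rng = np.random.default_rng(seed)
    base = _as_2d(func(rng.uniform(size=(n_outer * n_inner, p))))
    V = base.var(axis=0, ddof=1)
    n_out = base.shape[1]
    S = np.empty((p, n_out))
    ST = np.empty((p, n_out))
    for i in range(p):
        # S_i: variance over x_i of the conditional mean, debiased for the
        # sampling noise of each inner mean
        xi = rng.uniform(size=n_outer)
        cond_means = np.empty((n_outer, n_out))
        mean_noise = np.empty((n_outer, n_out))
        for k in range(n_outer):
            U = rng.uniform(size=(n_inner, p))
            U[:, i] = xi[k]
            fk = _as_2d(func(U))
            cond_means[k] = fk.mean(axis=0)
            mean_noise[k] = fk.var(axis=0, ddof=1) / n_inner
        S[i] = (cond_means.var(axis=0, ddof=1) - mean_noise.mean(axis=0)) / V
        # ST_i: mean over complements of the conditional variance
        cond_vars = np.empty((n_outer, n_out))
        for k in range(n_outer):
            U = np.tile(rng.uniform(size=(1, p)), (n_inner, 1))
            U[:, i] = rng.uniform(size=n_inner)
            cond_vars[k] = _as_2d(func(U)).var(axis=0, ddof=1)
        ST[i] = cond_vars.mean(axis=0) / V
    S, ST = _clip(S, ST)
    return SobolIndices(S=S, ST=ST, method="bruteforce", n=n_outer * n_inner)


# ---------------------------------------------------------------------------
# PBPK adapter and the full index table

def make_pbpk_adapter(
    table: PriorTable,
    names: Sequence[str] | None = None,
    dose: DoseSpec | None = None,
    times: Sequence[float] = GSA_TIMES,
    base_params: dict | None = None,
    model_config: ModelConfig | None = None,
    log_outputs: bool = True,
    failure_policy: str = "fail",
) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap the PBPK model as a unit-hypercube function of the selected
    parameters; unselected parameters stay at ``base_params`` (default:
    nominal values).  Outputs are (log) plasma concentrations, compound-major
    over the requested times.  The returned callable counts evaluations in
    its ``n_evaluations`` attribute.

    ``failure_policy``: 'fail' re-raises an integration failure; 'impute'
    substitutes the nearest successful evaluation of the same batch (logged).
    """
    from .pbpk import build_default_parameters

    if failure_policy not in ("fail", "impute"):
        raise ValueError("failure_policy must be 'fail' or 'impute'")
    names = list(names) if names is not None else table.names
    dose = dose or DoseSpec(1000.0)
    base = dict(base_params or build_default_parameters(table))
    times = np.asarray(times, dtype=float)

    def adapter(U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        values = unit_to_param(table, U, names)
        out = np.empty((U.shape[0], 3 * len(times)))
        failed = []
        for k in range(U.shape[0]):
            params = dict(base)
            params.update(values.iloc[k].to_dict())
            try:
                out[k] = plasma_outputs(
                    params, dose, times, model_config, log=log_outputs
                )
            except SimulationError:
                if failure_policy == "fail":
                    raise
                failed.append(k)
                out[k] = np.nan
        if failed:
            log.warning("imputing %d failed evaluations", len(failed))
            good = np.setdiff1d(np.arange(U.shape[0]), failed)
            if good.size == 0:
                raise SimulationError("every design point failed to integrate")
            for k in failed:
                nearest = good[np.argmin(((U[good] - U[k]) ** 2).sum(axis=1))]
                out[k] = out[nearest]
        adapter.n_evaluations += U.shape[0]
        return out

    adapter.n_evaluations = 0
    adapter.output_index = [
        (cpd, float(t)) for cpd in COMPOUNDS for t in times
    ]
    return adapter


def indices_to_table(
    indices: MorrisIndices | SobolIndices,
    names: Sequence[str],
    output_index: Sequence[tuple[str, float]],
    method: str,
    n: int,
) -> pd.DataFrame:
    """Long-format index table: parameter, compound, time_h, metric, value."""
    if isinstance(indices, MorrisIndices):
        metrics = {"mu": indices.mu, "mu_star": indices.mu_star, "sigma": indices.sigma}
    else:
        metrics = {"S": indices.S, "ST": indices.ST, "interaction": indices.interaction}
    rows = []
    for metric, arr in metrics.items():
        for j, name in enumerate(names):
            for k, (cpd, t) in enumerate(output_index):
                rows.append((name, cpd, t, metric, float(arr[j, k]), method, n))
    return pd.DataFrame(
        rows, columns=["parameter", "compound", "time_h", "metric", "value", "method", "n"]
    )


def run_gsa(
    model: Callable[[np.ndarray], np.ndarray],
    table: PriorTable,
    config: DesignConfig,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Drive a model adapter through the configured design and return the
    full long-format sensitivity index table for every (parameter, compound,
    time point) cell.

    ``model`` is usually the result of :func:`make_pbpk_adapter`; any
    vectorised unit-hypercube function works.
    """
    names = list(names) if names is not None else table.names
    p = len(names)
    if config.method == "morris":
        idx = morris(
            model, p, config.n, config.morris_levels, config.morris_pool, config.seed
        )
    elif config.method == "efast":
        idx = efast_indices(
            model, p, config.n, config.efast_M, config.efast_Nr, config.seed
        )
    elif config.method == "jansen":
        idx = jansen(model, p, config.n, config.seed)
    else:
        idx = owen(model, p, config.n, config.seed)
    output_index = getattr(
        model, "output_index",
        [("out", float(k)) for k in range(np.atleast_2d(idx.mu if isinstance(idx, MorrisIndices) else idx.S).shape[1])],
    )
    table_df = indices_to_table(idx, names, output_index, config.method, config.n)
    table_df.attrs["indices"] = idx
    return table_df
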