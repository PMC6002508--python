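"""Convergence diagnostics for sensitivity indices.

A sensitivity estimate at sample size n has converged when re-estimating it
from resampled designs barely moves it.  Following the resampling approach of
Sarrazin-type convergence analysis, the package quantifies this as the width
of the 95% percentile confidence interval of each index across replicates —
bootstrap resamples of the evaluation rows for the Monte-Carlo estimators
(Jansen, Owen), random phase shifts for eFAST.  The overall convergence index
is the maximum width across all parameters and outputs; below 0.1 the result
is considered acceptably converged.  Morris indices are first normalised so
the largest index per output equals 1, making the same 0.1 threshold a
"10% of maximum" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gsa import SobolIndices, jansen_indices, morris_indices, owen_indices

__all__ = [
    "ConvergenceReport",
    "bootstrap_index_ci",
    "bootstrap_sobol_replicates",
    "morris_replicates",
    "convergence_index",
]

DEFAULT_THRESHOLD = 0.1


@dataclass
class ConvergenceReport:
    """Per-cell CI widths and the max-across-cells convergence index."""

    widths: dict[str, np.ndarray]   # metric -> (p, n_out) CI widths
    index: float                    # max width over metrics, params, outputs
    threshold: float
    method: str

    @property
    def converged(self) -> bool:
        return self.index < self.threshold


def bootstrap_index_ci(replicates: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Percentile CI width across the first axis of ``replicates``.

    ``replicates`` holds B >= 2 re-estimates of an index array; the result has
    the replicate axis removed.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(replicates, alpha, axis=0)
    hi = np.quantile(replicates, 1.0 - alpha, axis=0)
    return hi - lo


def bootstrap_sobol_replicates(
    evals: Mapping[str, np.ndarray],
    estimator: str,
    B: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Bootstrap Jansen/Owen indices by resampling evaluation rows.

    ``evals`` is the raw-evaluation dict returned by
    :func:`pbpkgsa.gsa.jansen` / :func:`pbpkgsa.gsa.owen` with
    ``return_evals=True``; row pairing across the sample matrices is
    preserved.  Returns ``{"S": (B, p, n_out), "ST": (B, p, n_out)}``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = evals["fA"].shape[0]
    S_reps, ST_reps = [], []
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        if estimator == "jansen":
            idx = jansen_indices(
                evals["fA"][rows], evals["fB"][rows], evals["fAB"][:, rows]
            )
        elif estimator == "owen":
            idx = owen_indices(
                evals["fA"][rows], evals["fB"][rows],
                evals["fCA"][:, rows], evals["fCB"][:, rows], evals["fBA"][:, rows],
            )
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        S_reps.append(idx.S)
        ST_reps.append(idx.ST)
    return {"S": np.stack(S_reps), "ST": np.stack(ST_reps)}


def morris_replicates(
    trajectories: np.ndarray,
    Y: np.ndarray,
    B: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Bootstrap Morris mu*/sigma by resampling whole trajectories."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    traj = np.asarray(trajectories, dtype=float)
    r = traj.shape[0]
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != r:
        Y = Y.reshape(r, traj.shape[1], -1)
    mu_reps, sig_reps = [], []
    for _ in range(B):
        rows = rng.integers(0, r, size=r)
        idx = morris_indices(traj[rows], Y[rows])
        mu_reps.append(idx.mu_star)
        sig_reps.append(idx.sigma)
    return {"mu_star": np.stack(mu_reps), "sigma": np.stack(sig_reps)}


def _normalise_per_output(reps: np.ndarray) -> np.ndarray:
    """Scale each replicate so the max across parameters is 1 per output.

    Values at floating-noise level are zeroed first so an exactly-degenerate
    slice (e.g. sigma of a linear model) does not amplify round-off."""
    reps = np.where(np.abs(reps) < 1e-10, 0.0, reps)
    peak = reps.max(axis=1, keepdims=True)
    peak = np.where(peak > 0, peak, 1.0)
    return reps / peak


def convergence_index(
    replicates: Mapping[str, np.ndarray] | SobolIndices,
    method: str,
    threshold: float = DEFAULT_THRESHOLD,
    level: float = 0.95,
) -> ConvergenceReport:
    """Collapse index replicates into a pass/fail convergence report.

    ``replicates`` maps metric name to a (B, p, n_out) array of re-estimated
    indices (an eFAST :class:`SobolIndices` with stored phase-shift resamples
    is accepted directly).  Sobol widths are taken on the raw index scale;
    Morris mu*/sigma replicates are first normalised per output so the
    threshold reads as 10% of the largest index.
    """
    if isinstance(replicates, SobolIndices):
        if replicates.S_resamples is None:
            raise ValueError("SobolIndices carries no resamples; run with Nr >= 2")
        replicates = {"S": replicates.S_resamples, "ST": replicates.ST_resamples}
    if not replicates:
        raise ValueError("no index replicates supplied")
    widths = {}
    for metric, reps in replicates.items():
        reps = np.asarray(reps, dtype=float)
        if method == "morris":
            reps = _normalise_per_output(reps)
        widths[metric] = bootstrap_index_ci(reps, level)
    index = max(float(w.max()) for w in widths.values())
    return ConvergenceReport(widths=widths, index=index, threshold=threshold, method=method)
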