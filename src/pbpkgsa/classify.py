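"""Influential / non-influential parameter classification.

Sensitivity indices are computed per (parameter, compound, time point).  For
fixing decisions only the most sensitive output matters: a parameter is a
candidate for fixing only if *all* its indices are small.  Each parameter is
therefore summarised by its maximum main-type and maximum interaction-type
index across every compound and time point, and labelled influential when
either maximum strictly exceeds the cut-off (0.1 on normalised Morris
indices; 0.01 or 0.05 on Sobol indices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassificationResult",
    "normalize_morris",
    "max_over_outputs",
    "classify",
    "compare_methods",
    "set_report",
]

#: default (main, interaction) metric pairs per method family
METRIC_PAIRS = {
    "morris": ("mu_star", "sigma"),
    "sobol": ("S", "interaction"),
    "sobol_total": ("ST", "interaction"),
}


@dataclass
class ClassificationResult:
    """Per-parameter maxima and labels at one cut-off."""

    frame: pd.DataFrame      # parameter, max_main, max_interaction, label
    cutoff: float
    metrics: tuple[str, str]
    method: str = ""

    @property
    def influential(self) -> list[str]:
        return self.frame.loc[self.frame["label"] == "influential", "parameter"].tolist()

    @property
    def non_influential(self) -> list[str]:
        return self.frame.loc[
            self.frame["label"] == "non-influential", "parameter"
        ].tolist()


def normalize_morris(table: pd.DataFrame, metrics=("mu_star", "sigma")) -> pd.DataFrame:
    """Scale Morris indices so the maximum across parameters is 1 within each
    (compound, time point, metric) slice.  Idempotent; raises on an all-zero
    slice, which would make the output degenerate."""
    out = table.copy()
    for metric in metrics:
        sel = out["metric"] == metric
        if not sel.any():
            continue
        grouped = out.loc[sel].groupby(["compound", "time_h"])["value"]
        peak = grouped.transform("max")
        if (peak <= 0).any():
            bad = out.loc[sel].loc[peak.to_numpy() <= 0, ["compound", "time_h"]]
            raise ValueError(
                f"all-zero index slice for {metric}: "
                f"{bad.drop_duplicates().to_dict('records')}"
            )
        out.loc[sel, "value"] = out.loc[sel, "value"] / peak
    return out


def max_over_outputs(table: pd.DataFrame, metric: str) -> pd.Series:
    """Per-parameter maximum of one metric over all compounds and times."""
    sel = table[table["metric"] == metric]
    if sel.empty:
        raise ValueError(f"metric {metric!r} not present in index table")
    return sel.groupby("parameter", sort=False)["value"].max()


def classify(
    table: pd.DataFrame,
    cutoff: float,
    metrics: tuple[str, str] | str = "sobol",
    normalize: bool = False,
) -> ClassificationResult:
    """Label each parameter influential/non-influential by the OR rule.

    ``metrics`` is a (main, interaction) pair or one of the named pairs in
    :data:`METRIC_PAIRS` ('morris' uses normalised mu*/sigma at cut-off 0.1,
    'sobol' uses S/interaction at 0.01 or 0.05).  A parameter is influential
    iff its max main-type index OR its max interaction-type index is strictly
    greater than the cut-off.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if isinstance(metrics, str):
        try:
            metrics = METRIC_PAIRS[metrics]
        except KeyError:
            raise ValueError(f"unknown metric pair {metrics!r}") from None
    if normalize:
        table = normalize_morris(table, metrics)
    main = max_over_outputs(table, metrics[0])
    inter = max_over_outputs(table, metrics[1]).reindex(main.index)
    label = np.where(
        (main > cutoff) | (inter > cutoff), "influential", "non-influential"
    )
    frame = pd.DataFrame(
        {
            "parameter": main.index,
            "max_main": main.to_numpy(),
            "max_interaction": inter.to_numpy(),
            "label": label,
        }
    ).reset_index(drop=True)
    method = table["method"].iloc[0] if "method" in table.columns else ""
    return ClassificationResult(frame=frame, cutoff=cutoff, metrics=metrics, method=method)


def compare_methods(x, y) -> tuple[float, float]:
    """Pearson r and Spearman rho between two per-parameter index vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return float(r), float(rho)


def set_report(classifications: dict[str, ClassificationResult | set]) -> pd.DataFrame:
    """Membership and pairwise-overlap summary of named influential sets.

    Accepts e.g. ``{"OIP": <classification of the original 21>,
    "FIP_05": ..., "FIP_01": ...}``; plain sets of names also work.  Returns
    a symmetric overlap table whose diagonal holds the set sizes; set
    memberships are attached in ``.attrs['members']``.
    """
    sets = {}
    universes = {}
    for name, res in classifications.items():
        if isinstance(res, (set, frozenset)):
            sets[name] = set(res)
        else:
            sets[name] = set(res.influential)
            universes[name] = frozenset(res.frame["parameter"])
    full = [u for u in universes.values()]
    if full and any(not (u <= max(full, key=len)) for u in full):
        raise ValueError(f"classifications have inconsistent parameter universes")
    names = list(sets)
    overlap = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            overlap.loc[a, b] = len(sets[a] & sets[b])
    overlap.attrs["members"] = {k: sorted(v) for k, v in sets.items()}
    return overlap
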