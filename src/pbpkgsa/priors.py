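"""Prior distributions for the PBPK model parameters.

The human acetaminophen PBPK model carries 58 parameters.  21 of them
("original" subset: metabolism, transport and elimination constants) were
historically estimated from data; the remaining 37 ("additional" subset:
physiological flows/volumes, blood:plasma ratio and tissue:blood partition
coefficients) were historically fixed by expert judgment.  Each parameter is
assigned an independent prior, either

* ``uniform`` on ``[loc, spread]`` in natural units, or
* ``truncated-lognormal``: geometric mean ``loc``, log-scale standard
  deviation ``spread`` (sdlog), truncated at ``loc`` times
  ``exp(±trunc_z * sdlog)``.

Sensitivity-analysis designs operate on the unit hypercube; every parameter is
rescaled so its prior support maps to [0, 1] — linearly in natural units for
uniform priors, linearly in log units for lognormal priors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PriorSpec",
    "PriorTable",
    "load_prior_table",
    "unit_to_param",
    "sample_priors",
]

UNIFORM = "uniform"
LOGNORMAL = "truncated-lognormal"

#: spread assigned to partition-coefficient priors whose uncertainty is not
#: tabulated; a moderate lognormal sdlog with ±2 z truncation keeps them
#: sampleable in full-parameter sensitivity analyses.
DEFAULT_PARTITION_SDLOG = 0.3
DEFAULT_PARTITION_TRUNC_Z = 2.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one parameter.

    ``loc`` is the minimum (uniform) or the geometric mean (lognormal);
    ``spread`` is the maximum (uniform) or sdlog (lognormal); ``trunc_z``
    is the truncation half-width in z-score units (lognormal only).
    """

    name: str
    family: str
    loc: float
    spread: float
    trunc_z: float | None = None
    units: str = "-"
    subset: str = "original"

    def __post_init__(self) -> None:
        if self.family not in (UNIFORM, LOGNORMAL):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.family == UNIFORM:
            if not self.loc < self.spread:
                raise ValueError(f"{self.name}: uniform prior needs min < max")
        else:
            if self.loc <= 0 or self.spread <= 0:
                raise ValueError(f"{self.name}: lognormal prior needs loc, sdlog > 0")
            if self.trunc_z is None or self.trunc_z <= 0:
                raise ValueError(f"{self.name}: lognormal prior needs trunc_z > 0")

    @property
    def support(self) -> tuple[float, float]:
        """Lower/upper bounds of the (truncated) prior support, natural units."""
        if self.family == UNIFORM:
            return self.loc, self.spread
        half = self.trunc_z * self.spread
        return self.loc * np.exp(-half), self.loc * np.exp(half)

    def from_unit(self, u):
        """Map unit-interval coordinates to natural units (vectorised)."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError(f"{self.name}: unit coordinate outside [0, 1]")
        if self.family == UNIFORM:
            return self.loc + u * (self.spread - self.loc)
        lo = np.log(self.loc) - self.trunc_z * self.spread
        hi = np.log(self.loc) + self.trunc_z * self.spread
        return np.exp(lo + u * (hi - lo))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; lognormal via inverse-CDF on the truncated range."""
        if self.family == UNIFORM:
            return rng.uniform(self.loc, self.spread, size=n)
        z = self.trunc_z
        plo, phi = stats.norm.cdf(-z), stats.norm.cdf(z)
        q = stats.norm.ppf(plo + rng.uniform(size=n) * (phi - plo))
        return self.loc * np.exp(q * self.spread)

    def log_density(self, x: float) -> float:
        """Unnormalised log prior density at ``x`` (``-inf`` outside support)."""
        lo, hi = self.support
        if not (lo <= x <= hi):
            return -np.inf
        if self.family == UNIFORM:
            return 0.0
        # density of ln(x) is a truncated normal; Jacobian 1/x
        z = (np.log(x) - np.log(self.loc)) / self.spread
        return -0.5 * z * z - np.log(x)


@dataclass
class PriorTable:
    """Ordered collection of :class:`PriorSpec` with subset bookkeeping."""

    specs: list[PriorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dupes}")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, name: str) -> PriorSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def subset(self, tag_or_names) -> "PriorTable":
        """Restrict to a subset tag (``'original'``/``'additional'``) or names."""
        if isinstance(tag_or_names, str):
            specs = [s for s in self.specs if s.subset == tag_or_names]
        else:
            wanted = list(tag_or_names)
            missing = [n for n in wanted if n not in self]
            if missing:
                raise KeyError(f"unknown parameters: {missing}")
            specs = [self[n] for n in wanted]
        return PriorTable(specs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "family": [s.family for s in self.specs],
                "loc": [s.loc for s in self.specs],
                "spread": [s.spread for s in self.specs],
                "trunc_z": [s.trunc_z for s in self.specs],
                "units": [s.units for s in self.specs],
                "subset": [s.subset for s in self.specs],
            }
        )


def _packaged_csv():
    return importlib.resources.files("pbpkgsa.data").joinpath("apap_priors.csv")


def load_prior_table(
    source=None,
    *,
    partition_sdlog: float = DEFAULT_PARTITION_SDLOG,
    partition_trunc_z: float = DEFAULT_PARTITION_TRUNC_Z,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> PriorTable:
    """Load a prior table from CSV (default: the packaged APAP table).

    Columns: ``name, family, loc, spread, trunc_z, units, subset``.  Lognormal
    rows with a blank spread (the partition coefficients, whose uncertainty is
    not tabulated) receive ``partition_sdlog`` / ``partition_trunc_z``.
    ``overrides`` maps parameter name to field replacements.
    """
    if source is None:
        with importlib.resources.as_file(_packaged_csv()) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    if df.empty:
        raise ValueError("prior table is empty")
    required = {"name", "family", "loc", "spread", "trunc_z", "units", "subset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prior table missing columns: {sorted(missing)}")

    specs = []
    for i, row in df.iterrows():
        fields = {
            "name": str(row["name"]),
            "family": str(row["family"]),
            "loc": float(row["loc"]),
            "spread": row["spread"],
            "trunc_z": row["trunc_z"],
            "units": str(row["units"]),
            "subset": str(row["subset"]),
        }
        if fields["family"] == LOGNORMAL and pd.isna(fields["spread"]):
            fields["spread"] = partition_sdlog
            fields["trunc_z"] = partition_trunc_z
        if overrides and fields["name"] in overrides:
            fields.update(overrides[fields["name"]])
        try:
            fields["spread"] = float(fields["spread"])
            fields["trunc_z"] = (
                None if pd.isna(fields["trunc_z"]) else float(fields["trunc_z"])
            )
            specs.append(PriorSpec(**fields))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"prior table row {i} ({row['name']}): {exc}") from exc
    return PriorTable(specs)


def unit_to_param(
    table: PriorTable, u: Sequence[float] | np.ndarray, names: Iterable[str] | None = None
) -> dict[str, float] | pd.DataFrame:
    """Map unit-hypercube coordinates to natural-unit parameter values.

    ``u`` may be a length-p vector (returns a dict) or an (n, p) matrix
    (returns a DataFrame, one row per design point).  ``names`` selects and
    orders the parameters; default is the table order.
    """
    names = list(names) if names is not None else table.names
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        if u.shape[0] != len(names):
            raise ValueError(f"expected {len(names)} coordinates, got {u.shape[0]}")
        return {n: float(table[n].from_unit(ui)) for n, ui in zip(names, u)}
    if u.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} columns, got {u.shape[1]}")
    return pd.DataFrame(
        {n: table[n].from_unit(u[:, j]) for j, n in enumerate(names)}
    )


def sample_priors(table: PriorTable, n: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` independent parameter vectors from the priors.

    Returns an (n, p) DataFrame in table order.  Identical seeds give
    identical draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({s.name: s.sample(n, rng) for s in table})
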