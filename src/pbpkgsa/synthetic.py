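"""Synthetic PK datasets with the structure of the clinical APAP studies.

The calibration data the workflow targets are single-oral-dose human studies
(325 mg up to roughly 1,400 mg, i.e. 20 mg/kg) with plasma sampling within
12 h of intake and three measured compounds (APAP, APAP-glucuronide,
APAP-sulfate).  The generator simulates the PBPK model at known "true"
parameters per study and multiplies each concentration by lognormal
measurement noise exp(eps), eps ~ Normal(0, sdlog^2), with a compound
specific sdlog.  One representative subject per study; no inter-individual
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pbpk import COMPOUNDS, DoseSpec, ModelConfig, simulate

__all__ = ["StudyDesign", "default_designs", "generate_dataset"]

#: default lognormal measurement noise per compound (typical PK assay spread)
DEFAULT_SDLOG = 0.2

#: sampling schedule matching the sensitivity-analysis time points (h)
DEFAULT_TIMES = (0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0)


@dataclass(frozen=True)
class StudyDesign:
    """One synthetic study: a dose group with a sampling schedule."""

    study_id: str
    dose: float
    per_kg: bool = False
    body_mass: float = 70.0
    times: tuple[float, ...] = DEFAULT_TIMES
    compounds: tuple[str, ...] = COMPOUNDS
    noise_sdlog: Mapping[str, float] | float = DEFAULT_SDLOG

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("times must be strictly increasing and > 0")
        sd = self.noise_sdlog
        vals = sd.values() if isinstance(sd, Mapping) else [sd]
        if any(v < 0 for v in vals):
            raise ValueError("noise sdlog must be >= 0")

    def sdlog_for(self, compound: str) -> float:
        if isinstance(self.noise_sdlog, Mapping):
            return float(self.noise_sdlog[compound])
        return float(self.noise_sdlog)

    @property
    def dose_spec(self) -> DoseSpec:
        return DoseSpec(self.dose, per_kg=self.per_kg, body_mass=self.body_mass)


def default_designs(
    noise_sdlog: Mapping[str, float] | float = DEFAULT_SDLOG,
    include_high_dose: bool = True,
    body_mass: float = 70.0,
) -> list[StudyDesign]:
    """Eight studies, two per dose group: 325 mg, 1,000 mg, 20 mg/kg and
    (configurably) 80 mg/kg."""
    groups = [("325mg", 325.0, False), ("1000mg", 1000.0, False), ("20mgkg", 20.0, True)]
    if include_high_dose:
        groups.append(("80mgkg", 80.0, True))
    designs = []
    for label, dose, per_kg in groups:
        for rep in ("a", "b"):
            designs.append(
                StudyDesign(
                    study_id=f"{label}_{rep}",
                    dose=dose,
                    per_kg=per_kg,
                    body_mass=body_mass,
                    noise_sdlog=noise_sdlog,
                )
            )
    return designs


def generate_dataset(
    true_params: Mapping[str, float],
    designs: Sequence[StudyDesign] | None = None,
    seed: int = 0,
    model_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Simulate every design at ``true_params`` and apply measurement noise.

    Deterministic under ``seed``; with sdlog = 0 the dataset equals the
    noiseless model predictions.  Concentrations are floored at a tiny
    positive value so the lognormal error model stays applicable.
    """
    designs = list(designs) if designs is not None else default_designs()
    if not designs:
        raise ValueError("no study designs supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for d in designs:
        res = simulate(true_params, d.dose_spec, np.asarray(d.times), model_config)
        for cpd in d.compounds:
            conc = np.clip(res.plasma[cpd].to_numpy(), 1e-9, None)
            noisy = conc * np.exp(d.sdlog_for(cpd) * rng.standard_normal(conc.size))
            for t, v in zip(d.times, noisy):
                rows.append(
                    (
                        d.study_id, d.dose, "mg/kg" if d.per_kg else "mg",
                        "oral", t, cpd, v, "mg/L", d.body_mass,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id", "dose", "dose_units", "route", "time_h",
            "compound", "conc", "conc_units", "body_mass_kg",
        ],
    )
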