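"""Physiologically-based pharmacokinetic model for acetaminophen (APAP).

The model tracks APAP and its two conjugated metabolites, APAP-glucuronide
(AG) and APAP-sulfate (AS), after a single oral dose in a human subject.
Transport is blood-flow limited.  Each compound distributes over nine
compartments — arterial blood, venous blood, fat, gut tissue, kidney, liver,
muscle, rapidly perfused and slowly perfused tissue — connected by fractional
cardiac-output flows.  Oral absorption is a stomach → GI-lumen chain with
first-order time constants ``Tg`` (gastric emptying) and ``Tp`` (GI
perfusion), delivering APAP to the liver via the portal circulation.

Hepatic metabolism of APAP:

* CYP (oxidative) pathway: Michaelis–Menten loss, products not tracked.
* Sulfation (SULT) and glucuronidation (UGT): Michaelis–Menten with substrate
  inhibition, ``v = Vmax*C / (Km + C*(1 + C/Ki))``, each multiplied by a
  cofactor occupancy term ``P/(Km_c + P)`` where ``P`` is a normalised
  cofactor pool (PAPS resp. UDPGA) replenished at first-order rate
  ``k_syn*(1 - P)`` and depleted stoichiometrically with conjugation.

Conjugates formed in the liver exit to venous blood through saturable
transporters (``Vmax_AG/Km_AG``, ``Vmax_AS/Km_AS``) and then recirculate with
their own partition coefficients.  All three compounds are cleared renally at
``CLC_x * BW**0.75`` times the arterial concentration.  Plasma concentration
is venous blood concentration divided by the blood:plasma ratio.

Amounts are in µmol, volumes in L, times in h; plasma outputs in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .priors import PriorTable, UNIFORM

__all__ = [
    "MW",
    "DoseSpec",
    "ModelConfig",
    "SimulationResult",
    "SimulationError",
    "build_default_parameters",
    "simulate",
    "plasma_outputs",
    "prior_predictive_check",
    "read_pk_dataset",
    "write_pk_dataset",
]

#: molecular masses (g/mol) for µmol ↔ mg conversion
MW = {"APAP": 151.16, "AG": 327.29, "AS": 231.23}

COMPOUNDS = ("APAP", "AG", "AS")

# state layout: 9 compartments per compound
# (art, ven, fat, gut, kidney, liver, muscle, rapid, slow), then
# stomach, GI lumen, UDPGA pool, PAPS pool, urine x3, cumulative CYP loss
N_COMP = 9
I_STOMACH, I_LUMEN, I_UDPGA, I_PAPS = 27, 28, 29, 30
I_URINE, I_CYP = 31, 34
N_STATE = 35


class SimulationError(RuntimeError):
    """ODE integration failed; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class DoseSpec:
    """Single oral dose: ``amount`` in mg, or mg/kg when ``per_kg`` is set."""

    amount: float
    per_kg: bool = False
    body_mass: float = 70.0

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.body_mass <= 0:
            raise ValueError("body mass must be > 0")

    @property
    def amount_mg(self) -> float:
        return self.amount * self.body_mass if self.per_kg else self.amount

    @property
    def amount_umol(self) -> float:
        return self.amount_mg / MW["APAP"] * 1000.0


@dataclass(frozen=True)
class ModelConfig:
    """Numerical and structural switches for the PBPK simulation."""

    rtol: float = 1e-6
    atol: float = 1e-9
    #: apply the blood:plasma ratio to the conjugates as well as the parent
    bp_for_conjugates: bool = True
    #: nominal cofactor pool size (µmol) converting conjugation flux into
    #: fractional depletion of the normalised UDPGA/PAPS pools
    cofactor_pool_umol: float = 100.0
    #: floor for the lumped rapidly-perfused flow/volume fractions when the
    #: sampled fractions of the named tissues leave no remainder
    closure_floor: float = 1e-3
    mxstep: int = 50000


PARAM_NAMES = None  # set after first table load; simulate() checks the dict


def build_default_parameters(table: PriorTable) -> dict[str, float]:
    """Nominal parameter vector: lognormal priors at the geometric mean,
    uniform priors at the geometric mean of (min, max)."""
    params = {}
    for spec in table:
        if spec.family == UNIFORM:
            params[spec.name] = math.sqrt(spec.loc * spec.spread)
        else:
            params[spec.name] = spec.loc
    return params


# ---------------------------------------------------------------------------
# compiled right-hand side

def _rhs_py(y, t, c):
    dy = np.zeros(y.shape[0])

    # absorption chain (APAP only)
    stomach = y[I_STOMACH]
    lumen = y[I_LUMEN]
    dy[I_STOMACH] = -c[17] * stomach
    dy[I_LUMEN] = c[17] * stomach - c[18] * lumen
    absorption = c[18] * lumen

    udpga = y[I_UDPGA]
    paps = y[I_PAPS]

    # hepatic free APAP concentration drives metabolism
    cliv_apap = y[5] / c[5] / c[39 + 3]
    v_cyp = c[19] * cliv_apap / (c[20] + cliv_apap)
    occ_paps = paps / (c[24] + paps) if paps > 0.0 else 0.0
    occ_udpga = udpga / (c[28] + udpga) if udpga > 0.0 else 0.0
    v_sult = c[21] * cliv_apap / (c[22] + cliv_apap * (1.0 + cliv_apap / c[23])) * occ_paps
    v_ugt = c[25] * cliv_apap / (c[26] + cliv_apap * (1.0 + cliv_apap / c[27])) * occ_udpga

    # saturable hepatic efflux of the conjugates into venous blood
    cliv_ag = y[N_COMP + 5] / c[5]
    cliv_as = y[2 * N_COMP + 5] / c[5]
    v_t_ag = c[29] * cliv_ag / (c[30] + cliv_ag)
    v_t_as = c[31] * cliv_as / (c[32] + cliv_as)

    for ci in range(3):
        o = ci * N_COMP
        p0 = 39 + ci * 7
        cart = y[o + 0] / c[0]
        cven = y[o + 1] / c[1]
        cf = y[o + 2] / c[2] / c[p0 + 0]
        cg = y[o + 3] / c[3] / c[p0 + 1]
        ck = y[o + 4] / c[4] / c[p0 + 2]
        cl = y[o + 5] / c[5] / c[p0 + 3]
        cm = y[o + 6] / c[6] / c[p0 + 4]
        cr = y[o + 7] / c[7] / c[p0 + 5]
        cs = y[o + 8] / c[8] / c[p0 + 6]

        renal = c[36 + ci] * cart

        dy[o + 2] = c[10] * (cart - cf)
        dy[o + 3] = c[11] * (cart - cg)
        dy[o + 4] = c[12] * (cart - ck)
        dy[o + 6] = c[14] * (cart - cm)
        dy[o + 7] = c[15] * (cart - cr)
        dy[o + 8] = c[16] * (cart - cs)

        liver_in = c[13] * cart + c[11] * cg
        liver_out = (c[13] + c[11]) * cl
        dy[o + 5] = liver_in - liver_out

        venous = (
            c[10] * cf + c[12] * ck + c[14] * cm + c[15] * cr + c[16] * cs + liver_out
        )
        dy[o + 0] = c[9] * (cven - cart) - renal
        dy[o + 1] = venous - c[9] * cven
        dy[I_URINE + ci] = renal

    # compound-specific liver source/sink terms
    dy[5] += absorption - v_cyp - v_sult - v_ugt
    dy[N_COMP + 5] += v_ugt - v_t_ag
    dy[2 * N_COMP + 5] += v_sult - v_t_as
    dy[N_COMP + 1] += v_t_ag
    dy[2 * N_COMP + 1] += v_t_as

    dy[I_UDPGA] = c[33] * (1.0 - udpga) - v_ugt / c[35]
    dy[I_PAPS] = c[34] * (1.0 - paps) - v_sult / c[35]
    dy[I_CYP] = v_cyp
    return dy


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _rhs = njit(cache=True)(_rhs_py)
except Exception:  # pragma: no cover
    _rhs = _rhs_py


_REQUIRED = [
    "Tg", "Tp", "CYP_Km", "CYP_VmaxC", "SULT_Km_apap", "SULT_Ki",
    "SULT_Km_paps", "SULT_VmaxC", "UGT_Km", "UGT_Ki", "UGT_Km_GA",
    "UGT_VmaxC", "Km_AG", "Vmax_AG", "Km_AS", "Vmax_AS", "kGA_syn",
    "kPAPS_syn", "CLC_APAP", "CLC_AG", "CLC_AS", "QCC", "VFC", "VKC", "VGC",
    "VLC", "VMC", "VBLAC", "VBLVC", "VSC", "QFC", "QKC", "QGC", "QLBC",
    "QMC", "QSC", "BP_APAP",
] + [f"P{t}_{cpd}" for cpd in ("APAP", "AS", "AG") for t in "FGKLMRS"]


def _compile_params(params: Mapping[str, float], body_mass: float, config: ModelConfig):
    missing = [n for n in _REQUIRED if n not in params]
    if missing:
        raise ValueError(f"missing PBPK parameters: {missing}")
    bw75 = body_mass ** 0.75
    c = np.zeros(63)

    vfracs = [params[k] for k in ("VFC", "VGC", "VKC", "VLC", "VMC", "VSC")]
    vblood = params["VBLAC"] + params["VBLVC"]
    vrap = max(1.0 - sum(vfracs) - vblood, config.closure_floor)
    c[0] = params["VBLAC"] * body_mass
    c[1] = params["VBLVC"] * body_mass
    c[2] = params["VFC"] * body_mass
    c[3] = params["VGC"] * body_mass
    c[4] = params["VKC"] * body_mass
    c[5] = params["VLC"] * body_mass
    c[6] = params["VMC"] * body_mass
    c[7] = vrap * body_mass
    c[8] = params["VSC"] * body_mass

    qc = params["QCC"] * bw75
    qfracs = [params[k] for k in ("QFC", "QGC", "QKC", "QLBC", "QMC", "QSC")]
    qrap = max(1.0 - sum(qfracs), config.closure_floor)
    c[9] = qc
    c[10] = params["QFC"] * qc
    c[11] = params["QGC"] * qc
    c[12] = params["QKC"] * qc
    c[13] = params["QLBC"] * qc
    c[14] = params["QMC"] * qc
    c[15] = qrap * qc
    c[16] = params["QSC"] * qc

    c[17] = 1.0 / params["Tg"]
    c[18] = 1.0 / params["Tp"]
    c[19] = params["CYP_VmaxC"] * bw75
    c[20] = params["CYP_Km"]
    c[21] = params["SULT_VmaxC"] * bw75
    c[22] = params["SULT_Km_apap"]
    c[23] = params["SULT_Ki"]
    c[24] = params["SULT_Km_paps"]
    c[25] = params["UGT_VmaxC"] * bw75
    c[26] = params["UGT_Km"]
    c[27] = params["UGT_Ki"]
    c[28] = params["UGT_Km_GA"]
    c[29] = params["Vmax_AG"]
    c[30] = params["Km_AG"]
    c[31] = params["Vmax_AS"]
    c[32] = params["Km_AS"]
    c[33] = params["kGA_syn"]
    c[34] = params["kPAPS_syn"]
    c[35] = config.cofactor_pool_umol
    c[36] = params["CLC_APAP"] * bw75
    c[37] = params["CLC_AG"] * bw75
    c[38] = params["CLC_AS"] * bw75

    for ci, cpd in enumerate(COMPOUNDS):
        for ti, t in enumerate("FGKLMRS"):
            c[39 + ci * 7 + ti] = params[f"P{t}_{cpd}"]
    bp = params["BP_APAP"]
    c[60] = bp
    c[61] = bp if config.bp_for_conjugates else 1.0
    c[62] = bp if config.bp_for_conjugates else 1.0
    return c


@dataclass
class SimulationResult:
    """Plasma concentration trajectories on a time grid.

    ``plasma`` has one column per compound (mg/L); ``states`` optionally
    carries the full state trajectory (µmol; normalised for cofactors).
    """

    time: np.ndarray
    plasma: pd.DataFrame
    dose: DoseSpec
    states: np.ndarray | None = None

    def concentration(self, compound: str, times=None) -> np.ndarray:
        series = self.plasma[compound].to_numpy()
        if times is None:
            return series
        return np.interp(np.asarray(times, dtype=float), self.time, series)

    def log_plasma(self, floor: float = 1e-12) -> pd.DataFrame:
        return np.log(self.plasma.clip(lower=floor))


def simulate(
    params: Mapping[str, float],
    dose: DoseSpec,
    t_grid: Sequence[float],
    config: ModelConfig | None = None,
    keep_states: bool = False,
) -> SimulationResult:
    """Integrate the PBPK system and return plasma concentrations.

    The grid must be strictly increasing within [0, 24] h is typical; t=0 is
    prepended internally if absent.  Deterministic given inputs.
    """
    config = config or ModelConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D vector")
    if t_grid[0] < 0:
        raise ValueError("t_grid must be non-negative")

    c = _compile_params(params, dose.body_mass, config)
    y0 = np.zeros(N_STATE)
    y0[I_STOMACH] = dose.amount_umol
    y0[I_UDPGA] = 1.0
    y0[I_PAPS] = 1.0

    prepend = t_grid[0] > 0
    t = np.concatenate(([0.0], t_grid)) if prepend else t_grid
    sol, info = odeint(
        _rhs, y0, t, args=(c,), rtol=config.rtol, atol=config.atol,
        mxstep=config.mxstep, full_output=True, tfirst=False,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}")
    if prepend:
        sol = sol[1:]

    plasma = {}
    for ci, cpd in enumerate(COMPOUNDS):
        cven = sol[:, ci * N_COMP + 1] / c[1]          # µmol/L in blood
        conc = cven / c[60 + ci] * MW[cpd] / 1000.0     # mg/L in plasma
        plasma[cpd] = np.clip(conc, 0.0, None)          # guard solver noise
    return SimulationResult(
        time=t_grid,
        plasma=pd.DataFrame(plasma, index=t_grid),
        dose=dose,
        states=sol if keep_states else None,
    )


def plasma_outputs(
    params: Mapping[str, float],
    dose: DoseSpec,
    times: Sequence[float],
    config: ModelConfig | None = None,
    log: bool = False,
    floor: float = 1e-12,
) -> np.ndarray:
    """Flat output vector (compound-major: APAP then AG then AS at each
    requested time) used as the model adapter for GSA and MCMC."""
    res = simulate(params, dose, np.asarray(times, dtype=float), config)
    out = np.concatenate([res.plasma[cpd].to_numpy() for cpd in COMPOUNDS])
    if log:
        out = np.log(np.clip(out, floor, None))
    return out


# ---------------------------------------------------------------------------
# PK dataset I/O

DATASET_COLUMNS = [
    "study_id", "dose", "dose_units", "route", "time_h",
    "compound", "conc", "conc_units", "body_mass_kg",
]


def read_pk_dataset(source) -> pd.DataFrame:
    """Read a PK observation CSV and validate its schema.

    Columns: study_id, dose, dose_units (mg | mg/kg), route, time_h,
    compound (APAP | AG | AS), conc (mg/L), conc_units, body_mass_kg.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [col for col in DATASET_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"PK dataset missing columns: {missing}")
    bad = set(df["compound"]) - set(COMPOUNDS)
    if bad:
        raise ValueError(f"unknown compounds in dataset: {sorted(bad)}")
    if (df["conc"] <= 0).any():
        raise ValueError("concentrations must be positive")
    return df


def write_pk_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def dataset_doses(df: pd.DataFrame) -> dict[str, DoseSpec]:
    """One DoseSpec per study_id in the dataset."""
    doses = {}
    for sid, g in df.groupby("study_id", sort=False):
        row = g.iloc[0]
        doses[str(sid)] = DoseSpec(
            amount=float(row["dose"]),
            per_kg=str(row["dose_units"]).strip() == "mg/kg",
            body_mass=float(row["body_mass_kg"]),
        )
    return doses


def predict_dataset(
    params: Mapping[str, float], df: pd.DataFrame, config: ModelConfig | None = None
) -> np.ndarray:
    """Model-predicted concentration (mg/L) for every dataset row."""
    pred = np.empty(len(df))
    doses = dataset_doses(df)
    for sid, g in df.groupby("study_id", sort=False):
        times = np.unique(g["time_h"].to_numpy(dtype=float))
        res = simulate(params, doses[str(sid)], times, config)
        for cpd, gc in g.groupby("compound", sort=False):
            pred[gc.index.to_numpy()] = res.concentration(
                cpd, gc["time_h"].to_numpy(dtype=float)
            )
    return pred


def prior_predictive_check(
    table: PriorTable,
    dataset: pd.DataFrame,
    n_draws: int,
    seed: int,
    config: ModelConfig | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fraction of observations inside the central ``level`` band of the
    prior predictive distribution, per compound (plus an 'all' row)."""
    from .priors import sample_priors

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if dataset.empty:
        raise ValueError("dataset is empty")
    dataset = dataset.reset_index(drop=True)
    draws = sample_priors(table, n_draws, seed)
    preds = np.empty((n_draws, len(dataset)))
    for k in range(n_draws):
        preds[k] = predict_dataset(draws.iloc[k].to_dict(), dataset, config)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(preds, alpha, axis=0)
    hi = np.quantile(preds, 1.0 - alpha, axis=0)
    obs = dataset["conc"].to_numpy(dtype=float)
    inside = (obs >= lo) & (obs <= hi)
    rows = []
    for cpd in COMPOUNDS:
        mask = (dataset["compound"] == cpd).to_numpy()
        if mask.any():
            rows.append((cpd, inside[mask].mean(), int(mask.sum())))
    rows.append(("all", inside.mean(), len(dataset)))
    return pd.DataFrame(rows, columns=["compound", "coverage", "n_obs"])
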