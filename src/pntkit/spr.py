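"""SPR 1:1 binding kinetics and alanine-scan hot-spot analysis.

Sensorgrams are modelled with the pseudo-first-order 1:1 Langmuir scheme
used by standard biosensor evaluation software: during association at
analyte concentration C,

    R(t) = R_eq * (1 - exp(-(kon*C + koff) * t)),   R_eq = Rmax*C/(C + KD),

and after the association phase ends at t_a the response decays as
R(t_a) * exp(-koff*(t - t_a)).  A single (kon, koff, Rmax) set is fitted
globally across the concentration series; KD = koff/kon by construction,
with relative standard errors combined in quadrature.

Alanine-scan effects are expressed as ddG = R*T*ln(KD_mut / KD_ref) at
298.15 K; mutations with ddG strictly greater than 6 kJ/mol are classified
as binding hot spots, and each mutant is also binned by the nearest decade
of its KD fold-change (~1x, ~10x, ~100x, ~1000x).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

__all__ = [
    "Kinetic1to1",
    "Sensorgram",
    "KineticFit",
    "STANDARD_CONCENTRATIONS_M",
    "WEAK_BINDER_CONCENTRATIONS_M",
    "HOTSPOT_THRESHOLD_KJ",
    "simulate_sensorgram",
    "fit_global",
    "kd_from_rates",
    "ddg",
    "classify_scan",
]

R_GAS_KJ = 8.314e-3   # kJ mol^-1 K^-1
T_STANDARD = 298.15   # K (25 C)

#: analyte concentration series for high-affinity binders (nanomolar KD)
STANDARD_CONCENTRATIONS_M = (0.2e-9, 2e-9, 20e-9, 40e-9, 60e-9)
#: series used when binding is weakened (KD above the standard range)
WEAK_BINDER_CONCENTRATIONS_M = (20e-9, 200e-9, 2000e-9, 4000e-9, 6000e-9)

HOTSPOT_THRESHOLD_KJ = 6.0
FOLD_LABELS = {0: "~1x", 1: "~10x", 2: "~100x", 3: "~1000x"}


@dataclass
class Kinetic1to1:
    """1:1 Langmuir interaction parameters."""

    kon: float            # M^-1 s^-1
    koff: float           # s^-1
    Rmax: float           # RU
    offset: float = 0.0   # RU baseline

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.Rmax) <= 0:
            raise ValueError("kon, koff and Rmax must all be positive")

    @property
    def KD(self) -> float:
        return self.koff / self.kon


@dataclass
class Sensorgram:
    """One SPR trace at a single analyte concentration."""

    concentration_M: float
    times_s: np.ndarray
    response_RU: np.ndarray
    t_assoc_end_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if self.concentration_M <= 0:
            raise ValueError("analyte concentration must be positive")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.response_RU)):
            raise ValueError("non-finite response values")


@dataclass
class KineticFit:
    kon: float
    koff: float
    Rmax: float
    kon_se: float | None
    koff_se: float | None
    Rmax_se: float | None
    KD: float
    KD_se: float | None
    rms_residual: float
    warnings: list[str] = field(default_factory=list)


def _model_response(model: Kinetic1to1, C: float, t: np.ndarray, t_a: float) -> np.ndarray:
    k_obs = model.kon * C + model.koff
    R_eq = model.Rmax * C / (C + model.KD)
    assoc = R_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_a)))
    R_ta = R_eq * (1.0 - math.exp(-k_obs * t_a))
    dissoc = R_ta * np.exp(-model.koff * np.clip(t - t_a, 0.0, None))
    return model.offset + np.where(t <= t_a, assoc, dissoc)


def simulate_sensorgram(
    model: Kinetic1to1,
    concentration_M: float,
    t_grid_s: np.ndarray,
    t_assoc_end_s: float,
    noise_sd_RU: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Sensorgram:
    """Closed-form 1:1 sensorgram with optional Gaussian noise."""
    t = np.asarray(t_grid_s, dtype=float)
    if not (t[0] <= t_assoc_end_s <= t[-1]):
        raise ValueError("association end time must lie within the time grid")
    R = _model_response(model, concentration_M, t, t_assoc_end_s)
    if noise_sd_RU > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        R = R + rng.normal(0.0, noise_sd_RU, size=R.shape)
    return Sensorgram(concentration_M, t, R, t_assoc_end_s)


def fit_global(
    sensorgrams: list[Sensorgram],
    init: Kinetic1to1 | None = None,
    fit_offset: bool = False,
) -> KineticFit:
    """Globally fit one (kon, koff, Rmax) across a concentration series.

    Rmax is shared across all traces (single surface).  Standard errors come
    from the fit covariance; KD = koff/kon with relative SEs combined in
    quadrature.
    """
    if len(sensorgrams) < 3:
        raise ValueError("global fit needs at least 3 concentrations")
    concs = [s.concentration_M for s in sensorgrams]
    if init is None:
        R_top = max(float(np.max(s.response_RU)) for s in sensorgrams)
        init = Kinetic1to1(kon=1e5, koff=1e-3, Rmax=max(R_top, 1.0))

    params = Parameters()
    params.add("log_kon", value=math.log10(init.kon), min=0.0, max=10.0)
    params.add("log_koff", value=math.log10(init.koff), min=-8.0, max=2.0)
    params.add("Rmax", value=init.Rmax, min=1e-6)
    params.add("offset", value=0.0, vary=fit_offset)

    def resid(p):
        m = Kinetic1to1(10.0 ** p["log_kon"].value, 10.0 ** p["log_koff"].value,
                        p["Rmax"].value, p["offset"].value)
        return np.concatenate([
            _model_response(m, s.concentration_M, s.times_s, s.t_assoc_end_s) - s.response_RU
            for s in sensorgrams
        ])

    result = minimize(resid, params)
    if not result.success:
        raise RuntimeError(
            "global 1:1 fit did not converge: "
            f"{result.message}; rms residual {np.sqrt(np.mean(result.residual**2)):.3g} RU"
        )
    kon = 10.0 ** result.params["log_kon"].value
    koff = 10.0 ** result.params["log_koff"].value
    Rmax = float(result.params["Rmax"].value)
    ln10 = math.log(10.0)
    kon_se = result.params["log_kon"].stderr
    koff_se = result.params["log_koff"].stderr
    kon_se = kon * ln10 * kon_se if kon_se is not None else None
    koff_se = koff * ln10 * koff_se if koff_se is not None else None
    KD, KD_se = kd_from_rates(kon, koff, kon_se or 0.0, koff_se or 0.0)
    rms = float(np.sqrt(np.mean(result.residual**2)))

    fit = KineticFit(kon, koff, Rmax, kon_se, koff_se,
                     result.params["Rmax"].stderr, KD, KD_se, rms)
    if not (min(concs) / 100.0 <= KD <= max(concs) * 100.0):
        msg = (f"fitted KD {KD:.3g} M lies >100x outside the analyte "
               f"concentration range [{min(concs):.3g}, {max(concs):.3g}] M")
        fit.warnings.append(msg)
        _warnings.warn(msg, stacklevel=2)
    return fit


def kd_from_rates(
    kon: float, koff: float, kon_se: float = 0.0, koff_se: float = 0.0
) -> tuple[float, float]:
    """KD = koff/kon with relative errors combined in quadrature."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    KD = koff / kon
    KD_se = KD * math.hypot(koff_se / koff, kon_se / kon)
    return KD, KD_se


def ddg(
    kd_mut: float,
    kd_ref: float,
    kd_mut_se: float = 0.0,
    kd_ref_se: float = 0.0,
    T: float = T_STANDARD,
) -> tuple[float, float]:
    """Binding free-energy change R*T*ln(KD_mut/KD_ref) in kJ/mol, with SE."""
    if kd_mut <= 0 or kd_ref <= 0:
        raise ValueError("dissociation constants must be positive")
    value = R_GAS_KJ * T * math.log(kd_mut / kd_ref)
    se = R_GAS_KJ * T * math.hypot(kd_mut_se / kd_mut, kd_ref_se / kd_ref)
    return value, se


def classify_scan(
    table: pd.DataFrame,
    reference: str = "None",
    hotspot_threshold_kJ: float = HOTSPOT_THRESHOLD_KJ,
    T: float = T_STANDARD,
) -> pd.DataFrame:
    """Annotate an alanine-scan table with ddG, hot-spot flags and fold bins.

    ``table`` needs columns mutation, KD_nM and optionally KD_se_nM; the
    reference row is the construct with the unmodified interface.  Returns a
    copy with ddG_calc_kJmol, ddG_calc_se, hotspot and fold_category columns
    (the reference row itself is never a hot spot).
    """
    if reference not in set(table["mutation"]):
        raise ValueError(f"reference entry {reference!r} missing from scan table")
    df = table.copy().reset_index(drop=True)
    ref_row = df.loc[df["mutation"] == reference].iloc[0]
    kd_ref = float(ref_row["KD_nM"])
    kd_ref_se = float(ref_row.get("KD_se_nM", 0.0) or 0.0)

    vals, ses, hot, folds = [], [], [], []
    for _, row in df.iterrows():
        kd = float(row["KD_nM"])
        kd_se = float(row.get("KD_se_nM", 0.0) or 0.0)
        if row["mutation"] == reference:
            vals.append(0.0)
            ses.append(0.0)
            hot.append(False)
            folds.append(FOLD_LABELS[0])
            continue
        value, se = ddg(kd, kd_ref, kd_se, kd_ref_se, T=T)
        vals.append(value)
        ses.append(se)
        hot.append(value > hotspot_threshold_kJ)
        decade = int(np.clip(round(math.log10(kd / kd_ref)), 0, 3))
        folds.append(FOLD_LABELS[decade])
    df["ddG_calc_kJmol"] = vals
    df["ddG_calc_se"] = ses
    df["hotspot"] = hot
    df["fold_category"] = folds
    return df
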