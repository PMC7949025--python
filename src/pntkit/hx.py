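"""Amide hydrogen-exchange (HX) protection analysis.

Serial HSQC peak intensities recorded after transfer into D2O decay as

    I_t = I_0 * exp(-k_obs * t),

and the protection factor of an amide is PF = k_pred / k_obs, the ratio of
its predicted random-coil exchange rate (see :mod:`pntkit.intrinsic`) to the
observed rate.  Under EX2 conditions log PF maps onto the free energy of the
opening equilibrium that permits exchange, dG_HX = 2.303 * R * T * log10(PF),
so the most protected amides report on (near-)global unfolding.

Not every amide yields a rate: residues that exchange before the first
spectrum carry only an upper bound on log PF (status ``fast_limit``), and
residues that show no significant decay over the full acquisition window
carry a lower bound set by the largest measured PF in the same sample
(status ``slow_limit``).  Both bounds are first-class results here, never
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.stats import median_abs_deviation

from .intrinsic import IntrinsicRateModel, predict_intrinsic_rates

__all__ = [
    "R_GAS_KJ",
    "IntensitySeries",
    "DecayFit",
    "ProtectionRecord",
    "read_hx_table",
    "fit_decay",
    "protection",
    "censor_limits",
    "analyze_hx",
    "protection_frame",
]

#: gas constant, kJ mol^-1 K^-1
R_GAS_KJ = 8.314e-3

#: default minimum fractional intensity loss over the window to call a decay
#: "significant" (below it the residue is censored as a slow exchanger)
MIN_DECAY_FRAC = 0.25


@dataclass
class IntensitySeries:
    """Time course of one amide's peak intensity after transfer into D2O.

    Intensities are scaled per acquisition count (divide by number of scans)
    before analysis, assuming a linear detector.
    """

    residue: int
    times_s: np.ndarray
    intensities: np.ndarray
    n_scans: np.ndarray | None = None
    temperature_K: float = 294.15
    pH_star: float = 7.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if len(self.times_s) < 3:
            raise ValueError("need at least 3 samples to characterize a decay")
        if np.any(self.times_s < 0) or np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities")
        if self.n_scans is not None:
            self.n_scans = np.asarray(self.n_scans, dtype=float)
            if self.n_scans.shape != self.times_s.shape:
                raise ValueError("n_scans must match the sample count")
            self.intensities = self.intensities / self.n_scans
            self.n_scans = None  # applied once

    @property
    def t_first(self) -> float:
        return float(self.times_s[0])

    @property
    def t_last(self) -> float:
        return float(self.times_s[-1])


@dataclass
class DecayFit:
    """Single-exponential fit of one intensity series (or its censor status)."""

    k_obs: float | None
    k_obs_se: float | None
    I0: float | None
    I0_se: float | None
    status: str                     # measured | fast_limit | slow_limit
    rms_residual: float | None = None
    noise_floor: float = 0.0


@dataclass
class ProtectionRecord:
    residue: int
    k_pred: float
    status: str
    k_obs: float | None = None
    k_obs_se: float | None = None
    pf: float | None = None
    log_pf: float | None = None          # point estimate, or the bound itself
    dG_kJmol: float | None = None
    bound_direction: str | None = None   # None | 'upper' | 'lower' (on log PF)
    warnings: list[str] = field(default_factory=list)


def read_hx_table(path_or_buffer, temperature_K: float = 294.15, pH_star: float = 7.0) -> list[IntensitySeries]:
    """Load a TSV of (residue, time_s, intensity[, n_scans]) into per-residue series."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    required = {"residue", "time_s", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"HX table must have columns {sorted(required)}")
    out = []
    for resnum, grp in df.groupby("residue"):
        grp = grp.sort_values("time_s")
        out.append(
            IntensitySeries(
                residue=int(resnum),
                times_s=grp["time_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                n_scans=grp["n_scans"].to_numpy() if "n_scans" in grp else None,
                temperature_K=temperature_K,
                pH_star=pH_star,
            )
        )
    return out


def _estimate_noise_floor(I: np.ndarray) -> float:
    """3x a trend-robust noise estimate from successive sample differences.

    Differencing removes the slow exponential trend; the scaled MAD of the
    differences (divided by sqrt(2)) estimates the per-sample noise sigma.
    """
    sigma = median_abs_deviation(np.diff(I), scale="normal") / math.sqrt(2.0)
    return 3.0 * float(sigma)


def fit_decay(
    series: IntensitySeries,
    noise_floor: float | None = None,
    min_decay_frac: float = MIN_DECAY_FRAC,
) -> DecayFit:
    """Fit I_t = I_0 exp(-k_obs t) by unweighted nonlinear least squares.

    Censoring rules: fewer than 3 samples above the noise floor means the
    amide exchanged before it could be characterized (``fast_limit``); a
    fitted fractional intensity loss over the window below ``min_decay_frac``
    means no significant exchange (``slow_limit``).
    """
    t, I = series.times_s, series.intensities
    if noise_floor is None:
        noise_floor = _estimate_noise_floor(I)

    # An amide that exchanged before the first spectrum shows no signal from
    # the start: judge by the mean of the earliest samples against the floor.
    if float(np.mean(I[:3])) <= noise_floor:
        return DecayFit(None, None, None, None, "fast_limit", noise_floor=noise_floor)

    # start values: I0 from the earliest points, k from two independent
    # guesses (log-linear slope; first crossing of I0/e) — keep the better fit
    I0_guess = max(float(np.mean(I[:2])), 1e-12)
    k_guesses = []
    pos = I > max(noise_floor, 1e-12)
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(I[pos]), 1)[0]
        if slope < 0:
            k_guesses.append(-slope)
    below = np.nonzero(I < I0_guess / math.e)[0]
    k_guesses.append(1.0 / t[below[0]] if below.size else 0.1 / series.t_last)

    def resid(p):
        return p["I0"].value * np.exp(-p["k"].value * t) - I

    result = None
    for k_guess in k_guesses:
        params = Parameters()
        params.add("I0", value=I0_guess, min=0.0)
        params.add("k", value=k_guess, min=0.0)
        candidate = minimize(resid, params)
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate
    k = float(result.params["k"].value)
    I0 = float(result.params["I0"].value)
    k_se = result.params["k"].stderr
    I0_se = result.params["I0"].stderr
    rms = float(np.sqrt(np.mean(result.residual**2)))

    if 1.0 - math.exp(-k * series.t_last) < min_decay_frac:
        return DecayFit(None, None, I0, I0_se, "slow_limit", rms, noise_floor)
    return DecayFit(k, k_se, I0, I0_se, "measured", rms, noise_floor)


def censor_limits(
    series: IntensitySeries,
    k_pred: float,
    max_measured_log_pf: float,
    noise_floor: float,
    I0_ref: float,
) -> dict[str, float]:
    """Log PF bounds implied by the acquisition window.

    Fast exchangers vanished before the first spectrum, so their observed
    rate is at least ln(I0/I_noise)/t_first and

        log PF <= log10(k_pred * t_first / ln(I0 / I_noise)).

    Slow exchangers get a lower bound equal to the largest measured log PF
    in the same sample (the window cannot distinguish anything slower).
    """
    if series.t_first <= 0:
        raise ValueError("undefined first observation time: t_first must be > 0")
    if noise_floor <= 0 or I0_ref <= noise_floor:
        raise ValueError("need 0 < noise_floor < I0_ref to place a detection bound")
    detect_ratio = math.log(I0_ref / noise_floor)
    upper = math.log10(k_pred * series.t_first / detect_ratio)
    return {"upper": upper, "lower": max_measured_log_pf}


def protection(
    fit: DecayFit,
    k_pred: float,
    T: float = 298.15,
    residue: int = 0,
    bounds: dict[str, float] | None = None,
) -> ProtectionRecord:
    """Protection factor and dG_HX from a decay fit, honouring censor status.

    ``T`` is the temperature used for the free-energy conversion (default
    298.15 K; the exchange experiment itself may run at a different
    temperature, which only enters k_pred).
    """
    if k_pred <= 0 or not math.isfinite(k_pred):
        raise ValueError(f"k_pred must be positive and finite, got {k_pred}")
    rec = ProtectionRecord(residue=residue, k_pred=k_pred, status=fit.status)
    slope = 2.303 * R_GAS_KJ * T  # kJ/mol per log PF unit

    if fit.status == "measured":
        rec.k_obs = fit.k_obs
        rec.k_obs_se = fit.k_obs_se
        rec.pf = k_pred / fit.k_obs
        rec.log_pf = math.log10(rec.pf)
        rec.dG_kJmol = slope * rec.log_pf
        if fit.k_obs > 10.0 * k_pred:
            rec.warnings.append(
                f"k_obs exceeds the intrinsic rate >10-fold (PF={rec.pf:.2g}); "
                "likely mis-assignment or wrong intrinsic-rate inputs"
            )
    elif fit.status == "fast_limit":
        if bounds is not None:
            rec.log_pf = bounds["upper"]
            rec.dG_kJmol = slope * rec.log_pf
        rec.bound_direction = "upper"
    elif fit.status == "slow_limit":
        if bounds is not None:
            rec.log_pf = bounds["lower"]
            rec.dG_kJmol = slope * rec.log_pf
        rec.bound_direction = "lower"
    else:
        raise ValueError(f"unknown fit status {fit.status!r}")
    return rec


def analyze_hx(
    series_list: list[IntensitySeries],
    model: IntrinsicRateModel,
    dG_temperature_K: float = 298.15,
    noise_floor: float | None = None,
    min_decay_frac: float = MIN_DECAY_FRAC,
) -> list[ProtectionRecord]:
    """Full per-residue HX pipeline: intrinsic rates, decay fits, PF/censoring.

    Residues without an intrinsic-rate prediction (prolines, the first
    residue) are skipped.  Slow-exchanger lower bounds use the largest
    measured log PF of this sample, fast-exchanger upper bounds the
    median fitted I0 as the reference intensity.
    """
    k_pred = predict_intrinsic_rates(model)
    fits: dict[int, DecayFit] = {}
    for s in series_list:
        if s.residue not in k_pred.index or not math.isfinite(k_pred[s.residue]):
            continue
        fits[s.residue] = fit_decay(s, noise_floor=noise_floor, min_decay_frac=min_decay_frac)

    measured_log_pf = [
        math.log10(k_pred[r] / f.k_obs) for r, f in fits.items() if f.status == "measured"
    ]
    max_log_pf = max(measured_log_pf) if measured_log_pf else float("nan")
    I0_values = [f.I0 for f in fits.values() if f.I0 is not None]
    I0_ref = float(np.median(I0_values)) if I0_values else float("nan")
    floors = [f.noise_floor for f in fits.values() if f.noise_floor > 0]
    floor_ref = float(np.median(floors)) if floors else float("nan")

    series_by_res = {s.residue: s for s in series_list}
    records = []
    for resnum, fit in sorted(fits.items()):
        bounds = None
        if fit.status == "fast_limit":
            floor = fit.noise_floor if fit.noise_floor > 0 else floor_ref
            I0 = fit.I0 if fit.I0 is not None else I0_ref
            bounds = censor_limits(series_by_res[resnum], float(k_pred[resnum]),
                                   max_log_pf, floor, I0)
        elif fit.status == "slow_limit":
            bounds = {"lower": max_log_pf}
        records.append(
            protection(fit, float(k_pred[resnum]), T=dG_temperature_K,
                       residue=resnum, bounds=bounds)
        )
    return records


def protection_frame(records: list[ProtectionRecord]) -> pd.DataFrame:
    """Protection records as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "residue": r.residue,
                "k_pred_s": r.k_pred,
                "k_obs_s": r.k_obs,
                "k_obs_se_s": r.k_obs_se,
                "log_PF": r.log_pf,
                "dG_kJmol": r.dG_kJmol,
                "status": r.status,
                "bound_direction": r.bound_direction or "",
            }
            for r in records
        ]
    )
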