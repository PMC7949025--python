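"""Synthetic datasets with the statistical structure of the real experiments.

Every generator is seeded and emits a machine-readable truth table alongside
the data, so parameter-recovery and classification tests can compare the
pipeline output against known ground truth without any instrument data.

What is emulated (and what is not) per data kind:

* ``gen_helix_bundle`` builds an ideal-geometry backbone (phi = -57,
  psi = -47 within helices, extended elsewhere) for the 86-residue construct
  — realistic backbone H-bonding, no side chains beyond the amide plane.
* ``gen_trajectory`` adds independent per-atom Gaussian displacements with a
  per-residue sigma profile — correct second moments (RMSF), no correlated
  collective modes unless requested through the sigma profile.
* ``gen_hx_dataset`` produces serial-spectrum intensity decays on the real
  acquisition schedule (5-min spectra, then 20-min spectra back-to-back,
  hourly, then intermittent out to 3 months) with constant spectral noise.
* ``gen_scan_dataset`` simulates noisy 1:1 sensorgrams at the experimental
  concentration series for a table of per-mutant rate constants.
* ``gen_shift_tables`` perturbs a base shift table at a chosen interface set
  against a small-background of shift noise elsewhere.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .csp import ShiftTable
from .datasets import CONSTRUCT_SEQUENCE, CONSTRUCT_START
from .hx import MIN_DECAY_FRAC, IntensitySeries
from .intrinsic import IntrinsicRateModel, predict_intrinsic_rates
from .md import Trajectory
from .spr import (
    STANDARD_CONCENTRATIONS_M,
    WEAK_BINDER_CONCENTRATIONS_M,
    Kinetic1to1,
    Sensorgram,
    ddg,
    kd_from_rates,
    simulate_sensorgram,
)
from .structures import Atom, HelixAnnotation, Residue, Structure

__all__ = [
    "gen_helix_bundle",
    "gen_trajectory",
    "gen_hx_dataset",
    "default_hx_schedule",
    "expected_hx_status",
    "gen_scan_dataset",
    "gen_shift_tables",
    "make_base_shift_table",
]

# Backbone internal coordinates (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_OMEGA = 180.0
HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-180.0, 180.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Position a fourth atom from three reference atoms (NeRF construction)."""
    theta, chi = math.radians(theta_deg), math.radians(chi_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d2 = np.array([-r * math.cos(theta),
                   r * math.sin(theta) * math.cos(chi),
                   r * math.sin(theta) * math.sin(chi)])
    return c + d2[0] * bc_hat + d2[1] * m_hat + d2[2] * n_hat


def _build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates for a chain with the given per-residue torsions."""
    n_res = len(phi_psi)
    coords: list[dict[str, np.ndarray]] = []
    # first residue laid out in the xy-plane
    N = np.zeros(3)
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        prev = coords[i - 1]
        N_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CA_i = _place(prev["CA"], prev["C"], N_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        C_i = _place(prev["C"], N_i, CA_i, _B_CA_C, _A_N_CA_C, phi_i)
        coords.append({"N": N_i, "CA": CA_i, "C": C_i})
    # carbonyl oxygens: O_i anti to the next amide nitrogen
    for i in range(n_res):
        psi_i = phi_psi[i][1]
        c = coords[i]
        c["O"] = _place(c["N"], c["CA"], c["C"], _B_C_O, _A_CA_C_O, psi_i + 180.0)
    return coords


def gen_helix_bundle(
    segments: HelixAnnotation,
    seed: int | None = None,
    sequence: str = CONSTRUCT_SEQUENCE,
    first_residue: int = CONSTRUCT_START,
    chain_id: str = "A",
) -> Structure:
    """Ideal-geometry backbone: helical torsions inside the segments, extended linkers.

    Deterministic for a given annotation and sequence (the seed argument is
    accepted for generator-API uniformity but the construction has no random
    component).
    """
    del seed
    n_res = len(sequence)
    phi_psi = []
    for i in range(n_res):
        resnum = first_residue + i
        phi_psi.append(HELIX_PHI_PSI if segments.contains(resnum) else EXTENDED_PHI_PSI)
    backbone = _build_backbone(phi_psi)
    chain = []
    for i, atoms in enumerate(backbone):
        res = Residue(number=first_residue + i, code=sequence[i], chain_id=chain_id)
        for name in ("N", "CA", "C", "O"):
            element = "O" if name == "O" else ("N" if name == "N" else "C")
            res.atoms.append(Atom(name=name, element=element, xyz=atoms[name]))
        chain.append(res)
    return Structure(chains={chain_id: chain})


def gen_trajectory(
    ref: Structure,
    sigma_profile: dict[int, float] | pd.Series | float,
    n_frames: int,
    interval_ps: float = 100.0,
    seed: int | None = None,
    rigid_jitter_deg: float = 0.0,
) -> Trajectory:
    """Gaussian-fluctuation trajectory about a reference structure.

    Each atom of residue r is displaced by independent N(0, sigma(r)^2) noise
    per Cartesian component in every frame, giving an expected all-atom RMSF
    of sqrt(3)*sigma(r).  Optional small random rigid-body rotations/
    translations emulate imperfect frame alignment.
    """
    rng = np.random.default_rng(seed)
    base = ref.coordinates()
    sigmas = []
    for res in ref.residues:
        if isinstance(sigma_profile, (int, float)):
            s = float(sigma_profile)
        elif isinstance(sigma_profile, pd.Series):
            s = float(sigma_profile[res.number])
        elif (res.chain_id, res.number) in sigma_profile:   # chain-resolved keys
            s = float(sigma_profile[(res.chain_id, res.number)])
        else:
            s = float(sigma_profile[res.number])
        if s < 0:
            raise ValueError(f"negative fluctuation sigma for residue {res.number}")
        sigmas.extend([s] * len(res.atoms))
    sigma_arr = np.array(sigmas)[None, :, None]

    frames = base[None, :, :] + rng.normal(0.0, 1.0, size=(n_frames, len(sigmas), 3)) * sigma_arr
    if rigid_jitter_deg > 0:
        from scipy.spatial.transform import Rotation
        center = base.mean(axis=0)
        for f in range(n_frames):
            rot = Rotation.from_euler(
                "xyz", rng.normal(0.0, rigid_jitter_deg, size=3), degrees=True
            ).as_matrix()
            shift = rng.normal(0.0, 0.5, size=3)
            frames[f] = (frames[f] - center) @ rot.T + center + shift
    return Trajectory(topology=ref, frames=frames, interval_ps=interval_ps)


# ---------------------------------------------------------------------------
# HX


def default_hx_schedule() -> np.ndarray:
    """Spectrum mid-times (s) mimicking the serial-HSQC acquisition pattern.

    Twelve ~5-min spectra, then ~20-min spectra back-to-back for ~3 h, one
    per hour out to ~24 h, then intermittent spectra up to 3 months; the
    first observation falls ~5 min after transfer into D2O.
    """
    t = [300.0 + 300.0 * i for i in range(12)]                      # 5-min spectra
    t += [t[-1] + 1200.0 * (i + 1) for i in range(9)]               # 20-min block
    t += [t[-1] + 3600.0 * (i + 1) for i in range(21)]              # hourly, ~24 h
    days = [2, 3, 5, 7, 10, 14, 21, 30, 45, 60, 90]
    t += [d * 86400.0 for d in days]
    return np.array(t)


def expected_hx_status(
    log_pf: float,
    k_pred: float,
    times_s: np.ndarray,
    noise_frac: float,
    min_decay_frac: float = MIN_DECAY_FRAC,
) -> tuple[str, bool]:
    """Ground-truth censor status implied by k_pred and the schedule.

    Mirrors the detection physics on the noise-free signal: the mean of the
    first three spectra below a 3-sigma noise floor -> fast_limit; total
    decay over the window below the significance floor -> slow_limit;
    otherwise measured.

    Also returns a ``marginal`` flag marking residues whose noise-free signal
    sits within the noise of one of those decision boundaries — for them the
    observed status is a coin toss by construction, so classification tests
    should not score them.
    """
    if math.isinf(log_pf):
        return "slow_limit", False
    k_obs = k_pred / 10.0 ** log_pf
    floor_frac = 3.0 * noise_frac
    clean = np.exp(-k_obs * times_s)
    early_mean = float(np.mean(clean[:3]))
    decay_frac = 1.0 - math.exp(-k_obs * times_s[-1])
    # 2-sigma bands around the detection and significance boundaries
    fast_band = 2.0 * noise_frac / math.sqrt(3.0)
    marginal = (abs(early_mean - floor_frac) < fast_band
                or abs(decay_frac - min_decay_frac) < 0.05)
    if early_mean <= floor_frac:
        return "fast_limit", marginal
    if decay_frac < min_decay_frac:
        return "slow_limit", marginal
    return "measured", marginal


def gen_hx_dataset(
    truth_log_pf: dict[int, float] | pd.Series,
    pH_star: float = 7.0,
    temperature_K: float = 294.15,
    schedule_s: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
    I0: float = 100.0,
    sequence: str = CONSTRUCT_SEQUENCE,
    first_residue: int = CONSTRUCT_START,
) -> tuple[list[IntensitySeries], pd.DataFrame]:
    """Serial-spectrum intensity decays for a per-residue log PF truth profile.

    Observed rates are k_pred/10^logPF from the same intrinsic-rate model the
    analysis uses; intensities carry additive spectral noise of standard
    deviation ``noise_frac * I0`` (constant in RU, as peak-height noise in a
    spectrum does not scale with the peak).  Returns the series plus a truth
    table with the expected censor status of every residue.
    """
    if schedule_s is None:
        schedule_s = default_hx_schedule()
    rng = np.random.default_rng(seed)
    model = IntrinsicRateModel(sequence=sequence, first_residue=first_residue,
                               pH_star=pH_star, temperature_K=temperature_K)
    k_pred = predict_intrinsic_rates(model)

    series_list: list[IntensitySeries] = []
    truth_rows = []
    for resnum in sorted(dict(truth_log_pf)):
        log_pf = float(dict(truth_log_pf)[resnum])
        if resnum not in k_pred.index or not math.isfinite(k_pred[resnum]):
            continue
        kp = float(k_pred[resnum])
        k_obs = 0.0 if math.isinf(log_pf) else kp / 10.0 ** log_pf
        clean = I0 * np.exp(-k_obs * schedule_s)
        noisy = clean + rng.normal(0.0, noise_frac * I0, size=clean.shape)
        series_list.append(IntensitySeries(residue=resnum, times_s=schedule_s.copy(),
                                           intensities=noisy,
                                           temperature_K=temperature_K, pH_star=pH_star))
        status, marginal = expected_hx_status(log_pf, kp, schedule_s, noise_frac)
        truth_rows.append({
            "residue": resnum,
            "log_pf_true": log_pf,
            "k_pred_s": kp,
            "k_obs_true_s": k_obs,
            "expected_status": status,
            "marginal": marginal,
        })
    return series_list, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# SPR


def gen_scan_dataset(
    truth_rates: pd.DataFrame,
    reference: str = "None",
    concentrations_M: tuple[float, ...] | None = None,
    noise_sd_RU: float = 1.0,
    seed: int | None = None,
    Rmax: float = 100.0,
    t_assoc_s: float = 240.0,
    t_total_s: float = 600.0,
    dt_s: float = 1.0,
) -> tuple[dict[str, list[Sensorgram]], pd.DataFrame]:
    """Noisy 1:1 sensorgram sets for a per-mutant rate-constant truth table.

    ``truth_rates`` needs columns mutation, kon, koff.  Unless an explicit
    series is given, each mutant is run at the standard nanomolar analyte
    series, or at the weak-binder series when its true KD exceeds the top
    standard concentration (mirroring the experimental protocol).  The truth
    table gains derived KD, ddG vs the reference, and hot-spot flags.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.arange(0.0, t_total_s + dt_s / 2, dt_s)
    datasets: dict[str, list[Sensorgram]] = {}
    rows = []
    kd_ref = None
    for _, row in truth_rates.iterrows():
        if row["mutation"] == reference:
            kd_ref, _ = kd_from_rates(float(row["kon"]), float(row["koff"]))
    if kd_ref is None:
        raise ValueError(f"reference entry {reference!r} missing from truth table")

    for _, row in truth_rates.iterrows():
        model = Kinetic1to1(kon=float(row["kon"]), koff=float(row["koff"]), Rmax=Rmax)
        kd, _ = kd_from_rates(model.kon, model.koff)
        if concentrations_M is not None:
            concs = concentrations_M
        elif kd > max(STANDARD_CONCENTRATIONS_M):
            concs = WEAK_BINDER_CONCENTRATIONS_M
        else:
            concs = STANDARD_CONCENTRATIONS_M
        datasets[row["mutation"]] = [
            simulate_sensorgram(model, C, t_grid, t_assoc_s, noise_sd_RU, rng)
            for C in concs
        ]
        value, _ = ddg(kd, kd_ref)
        rows.append({
            "mutation": row["mutation"],
            "kon_true": model.kon,
            "koff_true": model.koff,
            "KD_true_nM": kd * 1e9,
            "ddG_true_kJmol": value,
            "hotspot_true": bool(row["mutation"] != reference and value > 6.0),
        })
    return datasets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSP


def make_base_shift_table(
    sequence: str = CONSTRUCT_SEQUENCE,
    first_residue: int = CONSTRUCT_START,
    seed: int | None = None,
    state: str = "free",
) -> ShiftTable:
    """Random but typical amide shift table (1H 7.5-9.3, 15N 105-130 ppm).

    Prolines and the N-terminal residue carry no amide row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, aa in enumerate(sequence):
        if i == 0 or aa == "P":
            continue
        rows.append({
            "residue": first_residue + i,
            "delta_H_ppm": rng.uniform(7.5, 9.3),
            "delta_N_ppm": rng.uniform(105.0, 130.0),
        })
    return ShiftTable(shifts=pd.DataFrame(rows), state=state)


def gen_shift_tables(
    base: ShiftTable,
    interface: set[int],
    dh_range_ppm: tuple[float, float] = (0.1, 0.4),
    dn_range_ppm: tuple[float, float] = (0.5, 2.0),
    background_sd_ppm: float = 0.01,
    seed: int | None = None,
) -> tuple[ShiftTable, ShiftTable, pd.DataFrame]:
    """Free/bound shift-table pair with localized interface perturbations.

    Interface residues receive uniform-magnitude 1H and 15N perturbations of
    random sign; all other residues get small Gaussian background changes on
    both nuclei.  Returns (free, bound, truth) where truth lists the true
    per-residue perturbations.
    """
    missing = set(interface) - base.residues
    if missing:
        raise ValueError(f"interface residues {sorted(missing)} absent from base table")
    rng = np.random.default_rng(seed)
    free_df = base.shifts.copy().reset_index(drop=True)
    bound_df = free_df.copy()
    resnums = free_df["residue"].astype(int).to_numpy()
    on_iface = np.isin(resnums, list(interface))
    n = len(resnums)
    dh = np.where(on_iface,
                  rng.uniform(*dh_range_ppm, n) * rng.choice([-1.0, 1.0], n),
                  rng.normal(0.0, background_sd_ppm, n) if background_sd_ppm > 0 else 0.0)
    dn = np.where(on_iface,
                  rng.uniform(*dn_range_ppm, n) * rng.choice([-1.0, 1.0], n),
                  rng.normal(0.0, background_sd_ppm, n) if background_sd_ppm > 0 else 0.0)
    bound_df["delta_H_ppm"] += dh
    bound_df["delta_N_ppm"] += dn
    truth = pd.DataFrame({"residue": resnums, "delta_H_true": dh,
                          "delta_N_true": dn, "interface": on_iface})
    free = ShiftTable(shifts=free_df, state="free", pH=base.pH)
    bound = ShiftTable(shifts=bound_df, state="bound", pH=base.pH)
    return free, bound, truth
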