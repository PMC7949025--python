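"""Trajectory rigidity statistics for helical-bundle domains.

Covers the quantities used to characterize PNT-domain dynamics: backbone
RMSD time series after least-squares superposition, per-residue all-atom
RMSF about the trajectory-average structure, chain-vs-chain delta-RMSF with
a +-0.3 Angstrom interface-rigidification classification, principal
component analysis of the coordinate covariance, and backbone hydrogen-bond
persistence (trajectory-mean amide-N to carbonyl-O distance, bonded at
<= 3.5 Angstrom inclusive) for comparison with HX protection.

Trajectories are consumed from multi-model PDB text, keeping the package
free of binary-format dependencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .hx import ProtectionRecord
from .structures import BACKBONE_ATOMS, Structure, read_models, write_structure

__all__ = [
    "Trajectory",
    "superpose",
    "rmsd_series",
    "rmsf",
    "delta_rmsf",
    "pca",
    "hbond_persistence",
    "compare_hbond_pf",
    "HBOND_CUTOFF_A",
    "DELTA_RMSF_THRESHOLD_A",
]

HBOND_CUTOFF_A = 3.5
DELTA_RMSF_THRESHOLD_A = 0.3
CORE_RANGE = (57, 120)   # rigid helical core used for alignments


@dataclass
class Trajectory:
    """Multi-frame coordinate set over a fixed topology."""

    topology: Structure
    frames: np.ndarray       # (n_frames, n_atoms, 3), Angstrom
    interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.interval_ps <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.interval_ps / 1000.0

    def atom_index(
        self,
        residue_range: tuple[int, int] | None = None,
        atom_class: str = "all",
        chain_id: str | None = None,
    ) -> np.ndarray:
        """Indices into the atom axis, deterministic (chain, residue, atom) order."""
        idx: list[int] = []
        i = 0
        for res in self.topology.residues:
            for atom in res.atoms:
                keep = True
                if chain_id is not None and res.chain_id != chain_id:
                    keep = False
                if residue_range is not None and not (residue_range[0] <= res.number <= residue_range[1]):
                    keep = False
                if atom_class == "backbone" and atom.name not in BACKBONE_ATOMS:
                    keep = False
                if keep:
                    idx.append(i)
                i += 1
        return np.array(idx, dtype=int)

    @classmethod
    def from_pdb_text(cls, pdb_text: str, interval_ps: float = 100.0) -> "Trajectory":
        models = read_models(pdb_text)
        topo = models[0]
        frames = np.stack([m.coordinates() for m in models])
        return cls(topology=topo, frames=frames, interval_ps=interval_ps)

    def to_pdb_text(self) -> str:
        chunks = []
        topo = self.topology
        for i, frame in enumerate(self.frames, start=1):
            topo.set_coordinates(frame)
            chunks.append(write_structure(topo, model_number=i))
        return "".join(chunks)


# ---------------------------------------------------------------------------
# Superposition


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch).

    Returns (rotation matrix, translation, rmsd) such that
    ``mobile @ R.T + t`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("superpose needs two equal (n>=3, 3) coordinate sets")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(m0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry: superposition undefined")
    rot, rssd = Rotation.align_vectors(r0, m0)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    rmsd = rssd / math.sqrt(mobile.shape[0])
    return R, t, float(rmsd)


def _fit_frames(frames: np.ndarray, fit_idx: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit-index atoms."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        R, t, _ = superpose(frame[fit_idx], reference)
        out[i] = frame @ R.T + t
    return out


# ---------------------------------------------------------------------------
# RMSD / RMSF


def rmsd_series(
    traj: Trajectory,
    residue_range: tuple[int, int] = (47, 123),
    atom_class: str = "backbone",
    chain_id: str | None = None,
) -> pd.DataFrame:
    """Backbone RMSD of each frame to frame 0 after superposition on the selection."""
    idx = traj.atom_index(residue_range, atom_class, chain_id)
    if idx.size == 0:
        raise ValueError(f"empty selection: residues {residue_range}, {atom_class}")
    ref = traj.frames[0, idx]
    rmsds = []
    for frame in traj.frames:
        _, _, r = superpose(frame[idx], ref)
        rmsds.append(r)
    return pd.DataFrame({
        "time_ns": traj.times_ns,
        "rmsd_A": rmsds,
        "selection": f"{atom_class} {residue_range[0]}-{residue_range[1]}",
    })


def rmsf(
    traj: Trajectory,
    chain_id: str | None = None,
    fit_range: tuple[int, int] = CORE_RANGE,
    n_align_passes: int = 2,
) -> pd.DataFrame:
    """Per-residue all-atom RMSF about the trajectory-average structure.

    Frames are aligned on the core backbone to the time-average structure
    (iterated ``n_align_passes`` times so the average is self-consistent),
    then RMSF(atom) = sqrt(<|r - <r>|^2>) and each residue reports the
    unweighted mean over its atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_idx = traj.atom_index(fit_range, "backbone", chain_id)
    if fit_idx.size == 0:
        fit_idx = traj.atom_index(None, "backbone", chain_id)
    frames = traj.frames
    reference = frames[0, fit_idx]
    for _ in range(max(1, n_align_passes)):
        frames = _fit_frames(traj.frames, fit_idx, reference)
        reference = frames[:, fit_idx].mean(axis=0)
    mean_xyz = frames.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((frames - mean_xyz) ** 2, axis=2), axis=0))

    rows = []
    i = 0
    for res in traj.topology.residues:
        n = len(res.atoms)
        if chain_id is None or res.chain_id == chain_id:
            rows.append({
                "chain": res.chain_id,
                "residue": res.number,
                "rmsf_A": float(per_atom[i:i + n].mean()),
            })
        i += n
    return pd.DataFrame(rows)


def delta_rmsf(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    threshold_A: float = DELTA_RMSF_THRESHOLD_A,
) -> pd.DataFrame:
    """Per-residue RMSF difference a - b with a three-way classification.

    With a = the V112R-like chain and b = the A93D-like chain, values above
    +threshold mean the residue fluctuates less in the A93D-like chain
    (``reduced_in_b``) and values below -threshold the converse
    (``reduced_in_a``); everything else is ``neutral``.
    """
    a = profile_a.set_index("residue")["rmsf_A"]
    b = profile_b.set_index("residue")["rmsf_A"]
    if set(a.index) != set(b.index):
        raise ValueError("RMSF profiles cover different residues: cannot join")
    delta = (a - b.reindex(a.index)).sort_index()
    cls = np.where(delta > threshold_A, "reduced_in_b",
                   np.where(delta < -threshold_A, "reduced_in_a", "neutral"))
    return pd.DataFrame({
        "residue": delta.index,
        "delta_rmsf_A": delta.to_numpy(),
        "classification": cls,
    })


# ---------------------------------------------------------------------------
# PCA


def pca(
    traj: Trajectory,
    residue_range: tuple[int, int] = CORE_RANGE,
    atom_class: str = "backbone",
    chain_id: str | None = None,
    align: bool = True,
    n_components: int = 10,
) -> dict:
    """PCA of the aligned selected-coordinate covariance.

    Returns eigenvalues (descending, A^2), variance fractions, and per-frame
    projections on the first ``n_components`` components.
    """
    if traj.n_frames < 10:
        raise ValueError("PCA needs at least 10 frames")
    idx = traj.atom_index(residue_range, atom_class, chain_id)
    if idx.size == 0:
        raise ValueError("empty selection for PCA")
    frames = traj.frames
    if align:
        frames = _fit_frames(frames, idx, frames[0, idx])
    X = frames[:, idx, :].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 1e-12:
        raise ValueError("zero total variance: PCA undefined on a static trajectory")
    k = min(n_components, len(evals))
    return {
        "eigenvalues": evals,
        "variance_fractions": evals / total,
        "projections": Xc @ evecs[:, :k],
        "components": evecs[:, :k],
    }


# ---------------------------------------------------------------------------
# Backbone hydrogen-bond persistence


def hbond_persistence(
    traj: Trajectory,
    cutoff_A: float = HBOND_CUTOFF_A,
    exclude_adjacent: bool = True,
    mode: str = "mean",
) -> pd.DataFrame:
    """Trajectory-mean closest carbonyl-O partners for every amide nitrogen.

    For each non-proline amide N, the two candidate backbone carbonyl
    oxygens with the smallest trajectory-mean N...O distance are reported
    (excluding the residue itself and its predecessor, whose carbonyl is
    covalently adjacent, unless ``exclude_adjacent=False``).  The amide is
    flagged bonded when the smallest mean distance is <= the cutoff
    (inclusive).  ``mode='per_frame'`` instead averages the per-frame
    minimum distance before applying the cutoff.
    """
    if mode not in ("mean", "per_frame"):
        raise ValueError("mode must be 'mean' or 'per_frame'")
    residues = traj.topology.residues
    n_atoms_before: list[int] = []
    i = 0
    for res in residues:
        n_atoms_before.append(i)
        i += len(res.atoms)

    def atom_pos(res_i: int, name: str) -> int | None:
        res = residues[res_i]
        for j, atom in enumerate(res.atoms):
            if atom.name == name:
                return n_atoms_before[res_i] + j
        return None

    donors = []     # (residue list index, atom index of N)
    acceptors = []  # (residue list index, atom index of O)
    for ri, res in enumerate(residues):
        n_idx = atom_pos(ri, "N")
        o_idx = atom_pos(ri, "O")
        if n_idx is not None and res.code != "P":
            donors.append((ri, n_idx))
        if o_idx is not None:
            acceptors.append((ri, o_idx))
    if not donors or not acceptors:
        return pd.DataFrame(columns=["chain", "residue", "partner_1", "mean_dist_1_A",
                                     "partner_2", "mean_dist_2_A", "bonded"])

    N = traj.frames[:, [a for _, a in donors], :]
    O = traj.frames[:, [a for _, a in acceptors], :]
    # accumulate mean pairwise distances frame by frame to bound memory
    mean_d = np.zeros((len(donors), len(acceptors)))
    min_d = np.full((traj.n_frames, len(donors)), np.inf)
    mask = np.zeros((len(donors), len(acceptors)), dtype=bool)
    for di, (ri, _) in enumerate(donors):
        for ai, (rj, _) in enumerate(acceptors):
            if residues[ri].chain_id != residues[rj].chain_id:
                continue
            gap = residues[ri].number - residues[rj].number
            if gap == 0 or (exclude_adjacent and gap == 1):
                mask[di, ai] = True
    for f in range(traj.n_frames):
        d = np.linalg.norm(N[f][:, None, :] - O[f][None, :, :], axis=2)
        mean_d += d
        d_masked = np.where(mask, np.inf, d)
        min_d[f] = d_masked.min(axis=1)
    mean_d /= traj.n_frames
    mean_d[mask] = np.inf

    rows = []
    for di, (ri, _) in enumerate(donors):
        order = np.argsort(mean_d[di])
        a1, a2 = order[0], order[1] if len(order) > 1 else order[0]
        label = lambda ai: f"{residues[acceptors[ai][0]].chain_id}{residues[acceptors[ai][0]].number}"
        if mode == "mean":
            bonded = bool(mean_d[di, a1] <= cutoff_A)
        else:
            bonded = bool(min_d[:, di].mean() <= cutoff_A)
        rows.append({
            "chain": residues[ri].chain_id,
            "residue": residues[ri].number,
            "partner_1": label(a1),
            "mean_dist_1_A": float(mean_d[di, a1]),
            "partner_2": label(a2),
            "mean_dist_2_A": float(mean_d[di, a2]),
            "bonded": bonded,
        })
    return pd.DataFrame(rows)


def compare_hbond_pf(
    hbonds: pd.DataFrame,
    protection: list[ProtectionRecord],
    log_pf_floor: float = 3.0,
    chain_id: str | None = None,
) -> dict:
    """2x2 contingency of H-bonded vs HX-protected residues.

    A residue counts as protected when its measured log PF exceeds the floor
    or it is a slow-limit non-exchanger; fast-limit residues and measured
    log PF at or below the floor count as unprotected.
    """
    if not protection:
        raise ValueError("empty protection record list")
    hb = hbonds if chain_id is None else hbonds[hbonds["chain"] == chain_id]
    bonded_by_res = dict(zip(hb["residue"].astype(int), hb["bonded"]))
    counts = {"bonded_protected": 0, "bonded_unprotected": 0,
              "unbonded_protected": 0, "unbonded_unprotected": 0}
    shared = 0
    for rec in protection:
        if rec.residue not in bonded_by_res:
            continue
        shared += 1
        if rec.status == "slow_limit":
            protected = True
        elif rec.status == "fast_limit":
            protected = False
        else:
            protected = rec.log_pf is not None and rec.log_pf > log_pf_floor
        bonded = bool(bonded_by_res[rec.residue])
        key = f"{'bonded' if bonded else 'unbonded'}_{'protected' if protected else 'unprotected'}"
        counts[key] += 1
    if shared == 0:
        raise ValueError("no residues shared between H-bond table and protection records")
    return counts
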