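"""Intrinsic (random-coil) amide hydrogen exchange rate prediction.

Implements the poly-DL-alanine reference scheme for protium-to-deuterium
exchange: the unstructured-chain rate of each backbone amide is the sum of
acid-, base- and water-catalyzed terms,

    k_pred = k_A [D+] A_L A_R  +  k_B [OD-] B_L B_R  +  k_W B_L B_R,

with the reference rates measured on poly-DL-alanine at 293.15 K and
side-chain correction factors (A, B pairs) applied for the residue carrying
the amide ("left" column of that residue type) and its preceding neighbor
("right" column).  Temperature is handled by Arrhenius scaling with
per-term activation energies, deuteroxide concentration via the D2O ion
product, and the titratable side chains (Asp, Glu, His) by population-
weighted mixing of the protonated and deprotonated factors.

By convention pH* is the uncorrected pH-meter reading of the D2O sample;
an optional +0.4 glass-electrode correction to pD is available but off by
default.  Prolines have no amide proton and receive no prediction, nor does
the first residue of the chain (its alpha-amine is not a peptide amide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntrinsicRateModel", "predict_intrinsic_rates"]

# Reference poly-DL-alanine rates for H->D exchange at 293.15 K.
# Units: k_A, k_B in M^-1 min^-1 (log10), k_W in min^-1 (log10).
_LOG_KA_REF = 1.62
_LOG_KB_REF = 10.05
_LOG_KW_REF = -1.5

#: ion product of D2O (molar) at 293.15 K, -log10
_PKD = 15.05

# Activation energies, cal/mol, for Arrhenius correction of each term.
_EA_ACID = 14_000.0
_EA_BASE = 17_000.0
_EA_WATER = 19_000.0
_R_CAL = 1.987  # cal mol^-1 K^-1
_T_REF = 293.15

# Side-chain correction factors, log10 scale, H->D exchange.
# Keys: one-letter code (with charge variants for D/E/H and the two Pro
# isomers).  Columns: (acid_L, acid_R, base_L, base_R) where the L value of a
# residue applies to its own amide and the R value to the following residue's
# amide.
_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A":   ( 0.00,  0.00,  0.00,  0.00),
    "R":   (-0.59, -0.32,  0.08,  0.22),
    "N":   (-0.58, -0.13,  0.49,  0.32),
    "D-":  ( 0.90,  0.58, -0.30, -0.18),
    "D0":  (-0.90, -0.12,  0.69,  0.60),
    "C":   (-0.54, -0.46,  0.62,  0.55),
    "G":   (-0.22,  0.22,  0.27,  0.17),
    "Q":   (-0.47, -0.27,  0.06,  0.20),
    "E-":  (-0.90,  0.31, -0.51, -0.15),
    "E0":  (-0.60, -0.27,  0.24,  0.39),
    "H+":  (-0.80, -0.51,  0.80,  0.83),
    "H0":  ( 0.00,  0.00, -0.10,  0.14),
    "I":   (-0.91, -0.59, -0.73, -0.23),
    "L":   (-0.57, -0.13, -0.58, -0.21),
    "K":   (-0.56, -0.29, -0.04,  0.12),
    "M":   (-0.64, -0.28, -0.01,  0.11),
    "F":   (-0.52, -0.43, -0.24,  0.06),
    "P":   ( 0.00, -0.19,  0.00, -0.24),   # trans
    "Pc":  ( 0.00, -0.85,  0.00,  0.60),   # cis (not used by default)
    "S":   (-0.44, -0.39,  0.37,  0.30),
    "T":   (-0.79, -0.47, -0.07,  0.20),
    "W":   (-0.40, -0.44, -0.41, -0.11),
    "Y":   (-0.41, -0.37, -0.27,  0.05),
    "V":   (-0.74, -0.30, -0.70, -0.14),
}

# Chain-terminus contributions: the N-terminal amine affects the second
# residue's amide (R-type), the C-terminal carboxylate affects the last
# residue's amide (L-type).
_NTERM_R = {"acid": -1.32, "base": 1.62}
_CTERM_L = {"acid": 0.96, "base": -1.80}

#: side-chain pKa values in D2O used for factor mixing
_SIDECHAIN_PKA = {"D": 4.48, "E": 4.93, "H": 7.42}


def _mixed_factor(code: str, col: int, pD: float) -> float:
    """Linear correction factor for one residue/column, titrating D/E/H."""
    if code in ("D", "E", "H"):
        pka = _SIDECHAIN_PKA[code]
        frac_prot = 1.0 / (1.0 + 10.0 ** (pD - pka))
        prot_key = f"{code}0" if code != "H" else "H+"
        deprot_key = f"{code}-" if code != "H" else "H0"
        return frac_prot * 10.0 ** _FACTORS[prot_key][col] + (1 - frac_prot) * 10.0 ** _FACTORS[deprot_key][col]
    return 10.0 ** _FACTORS[code][col]


def _arrhenius(ea_cal: float, T: float) -> float:
    return np.exp(-ea_cal / _R_CAL * (1.0 / T - 1.0 / _T_REF))


@dataclass
class IntrinsicRateModel:
    """Sequence-specific intrinsic exchange rate predictor.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string of the construct.
    first_residue:
        Author number of ``sequence[0]`` (construct offset).
    pH_star:
        pH-meter reading of the D2O sample, uncorrected for the isotope
        effect (used directly as pD unless ``apply_glass_correction``).
    temperature_K:
        Sample temperature in Kelvin.
    apply_glass_correction:
        Add +0.4 to obtain pD from the meter reading (off by default).
    exchange_regime:
        Only protium-to-deuterium ("HD") is supported.
    """

    sequence: str
    first_residue: int
    pH_star: float
    temperature_K: float
    apply_glass_correction: bool = False
    exchange_regime: str = "HD"
    warnings: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError("need at least two residues: the first has no peptide amide")
        bad = sorted(set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY"))
        if bad:
            raise ValueError(f"unknown residue letter(s) {bad} in sequence")
        if not 0.0 <= self.pH_star <= 14.0:
            raise ValueError(f"pH* {self.pH_star} outside 0-14")
        if self.exchange_regime != "HD":
            raise ValueError("only the H->D exchange regime is implemented")

    @property
    def pD(self) -> float:
        return self.pH_star + (0.4 if self.apply_glass_correction else 0.0)

    def rates(self) -> pd.Series:
        """Per-residue k_pred in s^-1, indexed by author residue number.

        The first residue and prolines carry NaN (no exchangeable peptide
        amide prediction).
        """
        T = self.temperature_K
        pD = self.pD
        conc_d = 10.0 ** (-pD)
        conc_od = 10.0 ** (pD - _PKD)
        ka = 10.0 ** _LOG_KA_REF * _arrhenius(_EA_ACID, T)
        kb = 10.0 ** _LOG_KB_REF * _arrhenius(_EA_BASE, T)
        kw = 10.0 ** _LOG_KW_REF * _arrhenius(_EA_WATER, T)

        seq = self.sequence
        n = len(seq)
        out = np.full(n, np.nan)
        for i in range(1, n):
            if seq[i] == "P":
                continue
            acid = _mixed_factor(seq[i], 0, pD) * _mixed_factor(seq[i - 1], 1, pD)
            base = _mixed_factor(seq[i], 2, pD) * _mixed_factor(seq[i - 1], 3, pD)
            if i == 1:
                acid *= 10.0 ** _NTERM_R["acid"]
                base *= 10.0 ** _NTERM_R["base"]
            if i == n - 1:
                acid *= 10.0 ** _CTERM_L["acid"]
                base *= 10.0 ** _CTERM_L["base"]
            k_min = ka * conc_d * acid + kb * conc_od * base + kw * base
            out[i] = k_min / 60.0  # min^-1 -> s^-1
        index = pd.RangeIndex(self.first_residue, self.first_residue + n, name="residue")
        return pd.Series(out, index=index, name="k_pred_s")


def predict_intrinsic_rates(model: IntrinsicRateModel) -> pd.Series:
    """Per-residue intrinsic exchange rate constants (s^-1); NaN for prolines."""
    return model.rates()
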