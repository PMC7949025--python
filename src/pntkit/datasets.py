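"""Reference data for the ETV6 PNT domain system.

The construct analysed throughout the package spans ETV6 residues 40-125
(author numbering; residue 40 follows the thrombin cleavage site, M43 is the
alternative translation start).  Two monomerizing variants are used: A93D
blocks the mid-loop (ML) surface and V112E/R blocks the end-helix (EH)
surface; the complementary pair forms a defined heterodimer that models one
unit of the head-to-tail polymer.

The alanine-scan kinetic tables below are the published fitted rate constants
for analytes binding the complementary immobilized ligand: `EH_SCAN` mutates
the EH-surface of the A93D-PNT domain, `ML_SCAN` mutates the ML-surface of
the V112E-PNT domain.  They are inputs to the ΔΔG / hot-spot pipeline, not
outputs of it.
"""

from __future__ import annotations

import pandas as pd

from .structures import HelixAnnotation, InterfaceAnnotation

__all__ = [
    "CONSTRUCT_START",
    "CONSTRUCT_SEQUENCE",
    "construct_residue",
    "ETV6_HELICES",
    "ML_SURFACE",
    "EH_SURFACE",
    "EH_SCAN",
    "ML_SCAN",
    "scan_table",
]

#: first residue number of the construct (author numbering)
CONSTRUCT_START = 40

#: ETV6 residues 40-125 (one-letter); index 0 is residue 40
CONSTRUCT_SEQUENCE = (
    "ALRMEEDSIR"  # 40-49
    "LPAHLRLQPI"  # 50-59
    "YWSRDDVAQW"  # 60-69
    "LKWAENEFSL"  # 70-79
    "RPIDSNTFEM"  # 80-89
    "NGKALLLLTK"  # 90-99
    "EDFRYRSPHS"  # 100-109
    "GDVLYELLQH"  # 110-119
    "ILKQRK"      # 120-125
)


def construct_residue(number: int) -> str:
    """One-letter code of the construct residue at an author-numbered position."""
    idx = number - CONSTRUCT_START
    if not 0 <= idx < len(CONSTRUCT_SEQUENCE):
        raise ValueError(f"residue {number} outside construct range 40-125")
    return CONSTRUCT_SEQUENCE[idx]


#: the four alpha-helices of the PNT domain fold
ETV6_HELICES = HelixAnnotation(segments=[
    ("H1", 63, 76),
    ("H2", 91, 94),
    ("H3", 99, 105),
    ("H4", 110, 122),
])

# Default interface annotations = the residue sets probed by alanine scanning.
_EH_SCANNED = {47, 48, 76, 77, 78, 79, 80, 99, 100, 103, 107, 108, 111, 112, 114, 115, 116, 119}
_ML_SCANNED = {59, 63, 85, 88, 89, 90, 92, 96, 97, 98, 100, 101, 104, 105}

EH_SURFACE = InterfaceAnnotation(surface="EH", residues=frozenset(_EH_SCANNED))
ML_SURFACE = InterfaceAnnotation(surface="ML", residues=frozenset(_ML_SCANNED))


def _scan_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["mutation", "kon", "kon_se", "koff", "koff_se", "KD_nM", "KD_se_nM", "ddG_kJmol", "ddG_se"],
    )
    return df.set_index("mutation", drop=False)


# Alanine scan of the EH-surface on the A93D-PNT domain (analyte) binding the
# immobilized V112E-PNT domain.  Columns: fitted kon (M^-1 s^-1) and koff (s^-1)
# with SEs, derived K_D (nM) and ddG (kJ/mol) with propagated errors as printed.
EH_SCAN = _scan_frame([
    ("None",  2.0e5, 0.03e5, 1.5e-3, 0.01e-3,  7.5, 0.10,  None, None),
    ("S47A",  2.1e5, 0.02e5, 1.4e-3, 0.01e-3,  6.9, 0.09, -0.2, 0.05),
    ("I48A",  3.4e5, 0.03e5, 4.0e-3, 0.03e-3,  12., 0.15,  1.2, 0.05),
    ("E76A",  6.2e5, 0.10e5, 6.2e-3, 0.08e-3,  9.9, 0.20,  0.7, 0.06),
    ("F77A",  3.4e4, 0.11e4, 1.5e-2, 0.04e-2, 450., 21.0, 10.2, 0.12),
    ("S78A",  2.8e6, 0.58e6, 9.3e-3, 1.8e-3,   3.3, 0.96, -2.0, 0.71),
    ("L79A",  8.1e3, 0.10e3, 1.6e-3, 0.03e-3, 200., 4.0,   8.2, 0.06),
    ("R80A",  9.1e4, 0.11e4, 2.9e-3, 0.02e-3,  32., 0.4,   3.6, 0.05),
    ("K99A",  2.4e3, 0.02e3, 2.3e-3, 0.01e-3, 930., 9.0,  12.0, 0.04),
    ("E100A", 3.1e5, 0.02e5, 1.5e-3, 0.01e-3,  5.0, 0.04, -1.0, 0.04),
    ("R103A", 2.5e5, 0.27e5, 5.4e-3, 0.48e-3,  21., 3.0,   2.6, 0.35),
    ("P107A", 2.6e5, 0.03e5, 2.1e-3, 0.01e-3,  8.1, 0.10,  0.2, 0.05),
    ("H108A", 2.6e5, 0.02e5, 1.4e-3, 0.005e-3, 5.4, 0.04, -0.8, 0.04),
    ("D111A", 3.3e3, 0.04e3, 1.4e-3, 0.02e-3, 420., 8.0,   9.9, 0.06),
    ("V112A", 2.0e4, 0.06e4, 1.1e-2, 0.02e-2, 550., 19.0, 10.7, 0.09),
    ("Y114A", 3.5e4, 0.04e4, 4.5e-3, 0.03e-3, 130., 2.0,   7.1, 0.05),
    ("E115A", 2.3e5, 0.08e5, 2.5e-3, 0.06e-3,  11., 0.5,   1.0, 0.12),
    ("L116A", 2.3e5, 0.004e5, 7.6e-4, 0.02e-4, 3.3, 0.01, -2.0, 0.04),
    ("H119A", 2.7e5, 0.02e5, 3.4e-3, 0.02e-3,  13., 0.12,  1.4, 0.04),
])

# Alanine scan of the ML-surface on the V112E-PNT domain (analyte) binding the
# immobilized A93D-PNT domain.
ML_SCAN = _scan_frame([
    ("None",  4.4e5, 0.09e5, 2.3e-3, 0.03e-3,   5.1, 0.13,  None, None),
    ("I59A",  4.3e5, 0.03e5, 2.5e-3, 0.01e-3,   5.8, 0.05,  0.3, 0.06),
    ("R63A",  3.6e5, 0.04e5, 5.4e-3, 0.05e-3,   15., 0.2,   2.7, 0.07),
    ("N85A",  3.5e5, 0.04e5, 3.4e-3, 0.03e-3,   9.9, 0.13,  1.6, 0.07),
    ("E88A",  5.0e5, 0.03e5, 4.0e-3, 0.02e-3,   8.1, 0.07,  1.1, 0.06),
    ("M89A",  9.7e4, 0.16e4, 3.3e-2, 0.03e-2,  340., 6.0,  10.4, 0.08),
    ("N90A",  7.8e4, 0.20e4, 3.7e-2, 0.10e-2,  480., 17.0, 11.3, 0.11),
    ("K92A",  3.5e5, 0.06e5, 2.2e-2, 0.04e-2,   62., 1.6,   6.2, 0.09),
    ("L96A",  9.5e3, 1.3e3,  9.5e-3, 1.1e-3,  1000., 180., 13.1, 0.45),
    ("L97A",  9.8e4, 0.16e4, 6.8e-2, 0.06e-2,  700., 13.0, 12.2, 0.08),
    ("T98A",  6.2e5, 0.05e5, 5.4e-3, 0.04e-3,   8.8, 0.09,  1.3, 0.07),
    ("E100A", 5.0e5, 0.04e5, 3.5e-3, 0.02e-3,   7.0, 0.07,  0.8, 0.07),
    ("D101A", 6.3e3, 0.12e3, 2.5e-3, 0.04e-3,  400., 10.0, 10.8, 0.09),
    ("Y104A", 7.3e5, 0.10e5, 1.5e-2, 0.02e-2,   21., 0.37,  3.5, 0.08),
    ("R105A", 2.3e3, 0.11e3, 5.4e-3, 0.11e-3, 2340., 120., 15.2, 0.14),
])


def scan_table(surface: str) -> pd.DataFrame:
    """The published alanine-scan kinetics for one surface ('EH' or 'ML')."""
    if surface == "EH":
        return EH_SCAN.copy()
    if surface == "ML":
        return ML_SCAN.copy()
    raise ValueError(f"surface must be 'EH' or 'ML', got {surface!r}")
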