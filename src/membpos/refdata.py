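"""Literature-reported orientation values for membrane-bound CYP 2C9/2C19.

These tables hold published summary statistics for the membrane positioning
of the two isoforms: coarse-grained simulation summaries (mean/SD of the
alpha and beta orientation angles, axial centre-of-mass distances of the
linker, F'-G' region and globular domain from the bilayer centre, and the
assigned orientation class), all-atom simulation summaries including the
TM tilt and heme-tilt angles, and heme-tilt values from independent studies
and the OPM (Orientations of Proteins in Membranes) database.  They serve
as classifier inputs and cross-checks; nothing in this package fits to
them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cg_orientation_summary",
    "aa_orientation_summary",
    "heme_tilt_comparison",
    "REPORTED_SEQUENCE_IDENTITY_2C9_2C19",
    "REPORTED_SEQUENCE_IDENTITY_2C8_2C19",
]

#: Reported positional sequence identity between CYP 2C9 and CYP 2C19 (%).
REPORTED_SEQUENCE_IDENTITY_2C9_2C19 = 91.2
#: Reported sequence identity between CYP 2C8 and CYP 2C19 (%), alignment-based.
REPORTED_SEQUENCE_IDENTITY_2C8_2C19 = 78.0

_CG_ROWS = [
    # system, alpha_mean, alpha_sd, beta_mean, beta_sd,
    # d_linker, d_linker_sd, d_fg, d_fg_sd, d_globular, d_globular_sd,
    # n_simulations, class
    ("2C9:S1", 89, 7, 112, 7, 25, 4, 28, 4, 43, 2, 10, "A"),
    ("2C9:S2", 91, 8, 118, 14, 26, 4, 27, 4, 42, 2, 5, "A"),
    ("2C9:S3", 92, 7, 109, 7, None, None, 28, 2, 46, 2, 1, "A"),
    ("2C9:M1", 94, 6, 119, 8, 20, 2, 25, 2, 46, 2, 6, "A"),
    ("2C9:M2", 92, 8, 120, 12, 19, 2, 25, 2, 46, 2, 6, "A"),
    ("2C9:M3", 95, 6, 138, 6, 22, 2, 24, 2, 48, 2, 6, "B"),
    ("2C9:M4", 85, 9, 106, 9, 25, 2, 26, 3, 47, 2, 5, "A"),
    ("mt2C9", 98, 7, 129, 10, 27, 4, 29, 4, 44, 2, 5, "A/B"),
    ("2C19:S1", 100, 7, 137, 10, 21, 2, 26, 2, 47, 2, 10, "B"),
    ("2C19:S2", 97, 8, 137, 12, 20, 2, 25, 2, 48, 2, 5, "B"),
    ("2C19:S3", 106, 5, 133, 6, None, None, 27, 2, 46, 2, 1, "B"),
    ("mt2C19", 95, 8, 127, 13, 19, 2, 25, 3, 46, 2, 5, "A/B"),
]


def cg_orientation_summary() -> pd.DataFrame:
    """Published coarse-grained orientation summary for 12 CYP 2C systems.

    S systems are crystal-structure based (S3: globular domain only), M
    systems use alternative homology models of CYP 2C9, and mt systems are
    the interface-residue chimeras.  Angles in degrees, distances in
    angstrom.
    """
    return pd.DataFrame(
        _CG_ROWS,
        columns=[
            "system", "alpha_mean", "alpha_sd", "beta_mean", "beta_sd",
            "d_linker", "d_linker_sd", "d_fg", "d_fg_sd",
            "d_globular", "d_globular_sd", "n_simulations", "class",
        ],
    )


_AA_ROWS = [
    # system, alpha, alpha_sd, beta, beta_sd, gamma, gamma_sd,
    # heme_tilt, heme_tilt_sd, d_globular, d_globular_sd, class, time_ns
    ("2C9:CG:S1", 91.9, None, 111.9, None, 17.6, None, 30.2, None, 45.0, None, "A", 10000),
    ("2C9:SIM1", 74.8, 4.3, 119.9, 4.5, 11.9, 5.3, 43.2, 4.8, 45.5, 1.5, "A", 216.88),
    ("2C9:SIM2", 95.9, 4.4, 123.3, 4.9, 13.5, 4.1, 39.8, 4.9, 48.3, 2.3, "A", 156.1),
    ("2C9:CG:S2", 90.5, None, 111.8, None, 13.9, None, 33.8, None, 42.3, None, "A", 10000),
    ("2C9:SIM3", 86.6, 4.1, 126.8, 3.0, 5.9, 2.7, 40.1, 5.5, 44.2, 0.9, "A/B", 50.6),
    ("2C19:CG:S1", 99.6, None, 135.3, None, 13.0, None, 52.4, None, 46.7, None, "B", 10000),
    ("2C19:SIM1", 106.3, 4.2, 148.6, 5.1, 25.4, 7.8, 60.5, 4.5, 46.2, 2.6, "B", 108.4),
    ("2C19:SIM2", 97.0, 5.0, 140.1, 4.2, 25.3, 4.6, 58.1, 5.3, 45.8, 1.6, "B", 113.4),
    ("2C19:CG:S2", 99.5, None, 133.3, None, 10.2, None, 45.9, None, 50.3, None, "B", 10000),
    ("2C19:SIM3", 94.9, 4.8, 135.8, 6.6, 17.2, 4.1, 55.4, 6.5, 46.0, 1.6, "B", 95.2),
]


def aa_orientation_summary() -> pd.DataFrame:
    """Published all-atom orientation summary (representative CG starting
    structures and the three production simulations per isoform)."""
    return pd.DataFrame(
        _AA_ROWS,
        columns=[
            "system", "alpha", "alpha_sd", "beta", "beta_sd", "gamma",
            "gamma_sd", "heme_tilt", "heme_tilt_sd", "d_globular",
            "d_globular_sd", "class", "time_ns",
        ],
    )


_HEME_TILT_ROWS = [
    ("CYP2C9", "MD POPC/LIPID14", "1R9O", 41.5, "40-43 +/- 5"),
    ("CYP2C9", "MD POPC/GAFF (run 1)", "1R9O", 44.0, "44 +/- 4"),
    ("CYP2C9", "MD POPC/GAFF (run 2)", "1R9O", 41.0, "41 +/- 4"),
    ("CYP2C9", "MD DOPC/Berger", "1OG2", 55.0, "55 +/- 5"),
    ("CYP2C9", "MD DOPC/Berger", "1OG2", 61.0, "61 +/- 4"),
    ("CYP2C9", "OPM database", "1R9O", 59.8, "59.8"),
    ("CYP2C9", "OPM database", "1OG5", 71.9, "71.9"),
    ("CYP2C19", "MD POPC/LIPID14", "4GQS", 58.0, "55-61 +/- 5"),
    ("CYP2C19", "OPM database", "4GQS", 74.0, "74.0"),
]


def heme_tilt_comparison() -> pd.DataFrame:
    """Heme-tilt angles (degrees) for CYP 2C9/2C19 from simulations and OPM."""
    return pd.DataFrame(
        _HEME_TILT_ROWS,
        columns=["protein", "source", "pdb_id", "heme_tilt_mid", "reported"],
    )
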