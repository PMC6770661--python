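"""Pure geometric kernels for membrane-positioning analysis.

Conventions
-----------
* The membrane normal is the +z axis.
* ``alpha``/``beta``-type angles between an orientation vector and the normal
  are reported *unfolded* in [0, 180] degrees; helix tilt and heme tilt are
  folded to [0, 90] degrees (a helix axis and a plane have no head/tail).
* The heme tilt is the plane-line angle between the best-fit plane through
  the four heme nitrogens and the z axis: ``90 deg - fold(angle(normal, z))``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .core import ConfigurationError, Frame, ResolvedSegments

__all__ = [
    "center_of_mass",
    "axis_vector",
    "angle_to_normal",
    "fold_angle",
    "tilt_angle",
    "plane_normal",
    "heme_tilt",
    "axial_distances",
    "superpose",
    "superpose_trajectory",
    "rmsd",
    "rmsf_bfactor",
    "ELEMENT_MASSES",
]

Z_AXIS = np.array([0.0, 0.0, 1.0])

# Standard atomic masses (u) for the elements that occur in protein/lipid
# heavy atoms plus hydrogen and heme iron.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "FE": 55.845,
}


def _element_masses(atom_names: np.ndarray) -> np.ndarray:
    masses = np.empty(len(atom_names))
    for i, name in enumerate(atom_names):
        stripped = str(name).strip().lstrip("0123456789")
        key = "FE" if stripped[:2].upper() == "FE" else stripped[:1].upper()
        try:
            masses[i] = ELEMENT_MASSES[key]
        except KeyError:
            raise ConfigurationError(
                f"cannot infer element mass for atom name {name!r}"
            ) from None
    return masses


def center_of_mass(
    positions: np.ndarray,
    masses: np.ndarray | None = None,
    atom_names: np.ndarray | None = None,
    weighting: str = "uniform",
) -> np.ndarray:
    """Weighted mean position of a particle set.

    ``weighting="uniform"`` treats every particle equally (appropriate for
    coarse-grained beads); ``weighting="element"`` infers masses from atom
    names unless explicit ``masses`` are given.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("center of mass of an empty particle set")
    if masses is None and weighting == "element":
        if atom_names is None:
            raise ConfigurationError("element weighting requires atom names")
        masses = _element_masses(np.asarray(atom_names, dtype=object))
    if masses is None:
        return positions.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    return (positions * masses[:, None]).sum(axis=0) / masses.sum()


def axis_vector(
    frame: Frame,
    residue_range: tuple[int, int],
    backbone: frozenset | set = frozenset({"CA", "BB"}),
    terminal_n: int = 4,
    exclude_residue_names: frozenset | set = frozenset(),
) -> np.ndarray:
    """Axis of a helical segment from its terminal residue groups.

    The vector runs from the centre of mass of the backbone particles of the
    *first* ``terminal_n`` residues of the range to that of the *last*
    ``terminal_n`` residues.
    """
    lo, hi = residue_range
    mask = (
        (frame.residue_numbers >= lo)
        & (frame.residue_numbers <= hi)
        & np.isin(frame.atom_names, list(backbone))
    )
    if exclude_residue_names:
        mask &= ~np.isin(frame.residue_names, list(exclude_residue_names))
    resnums = frame.residue_numbers[mask]
    unique = np.unique(resnums)
    if unique.size < 2 * terminal_n:
        raise ValueError(
            f"range {lo}-{hi} has only {unique.size} backbone residues; "
            f"need at least {2 * terminal_n} for terminal-{terminal_n} axis"
        )
    pos = frame.positions[mask]
    first = pos[np.isin(resnums, unique[:terminal_n])]
    last = pos[np.isin(resnums, unique[-terminal_n:])]
    return last.mean(axis=0) - first.mean(axis=0)


def angle_to_normal(v: np.ndarray) -> float:
    """Unfolded angle (degrees, [0, 180]) between ``v`` and the membrane normal."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))


def fold_angle(theta: float) -> float:
    """Fold an angle in degrees to [0, 90] (axis without head/tail)."""
    return min(theta, 180.0 - theta)


def tilt_angle(v: np.ndarray) -> float:
    """Folded angle (degrees, [0, 90]) between an axis and the membrane normal."""
    return fold_angle(angle_to_normal(v))


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Least-squares unit normal of the plane through >= 3 points."""
    points = np.asarray(points, dtype=float)
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30) or s[0] < 1e-12:
        raise ValueError("points are collinear or coincident; plane undefined")
    return vt[2]


def heme_tilt(frame: Frame, heme_indices: np.ndarray) -> float:
    """Tilt (degrees, [0, 90]) of the heme plane relative to the membrane.

    Defined as the plane-line angle between the least-squares plane through
    the four nitrogen atoms coordinating the iron and the z axis.  A heme
    lying flat in the membrane plane therefore has a tilt of 90 degrees
    (the z axis is perpendicular to its plane), a heme standing upright 0.
    """
    pts = frame.positions[np.asarray(heme_indices)]
    if len(pts) != 4:
        raise ConfigurationError(f"heme tilt needs exactly 4 particles, got {len(pts)}")
    n = plane_normal(pts)
    return 90.0 - fold_angle(angle_to_normal(n))


def axial_distances(
    frame: Frame, resolved: ResolvedSegments
) -> tuple[float, float | None, float]:
    """Axial (|z|) distances of segment centres of mass from the bilayer centre.

    Returns ``(d_globular, d_linker, d_fg)`` in angstrom; ``d_linker`` is
    ``None`` when the segment map has no linker (truncated constructs).  The
    bilayer centre is the z centre of mass of all lipid particles.
    """
    if resolved.lipid_all.size == 0:
        raise ConfigurationError("no lipid particles; cannot locate bilayer centre")
    z_bilayer = frame.positions[resolved.lipid_all, 2].mean()

    def dist(name: str) -> float:
        return float(abs(frame.positions[resolved[name], 2].mean() - z_bilayer))

    d_linker = dist("linker") if "linker" in resolved.ranges else None
    return dist("globular"), d_linker, dist("fprime_gprime")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared deviation between matched coordinate sets (no fit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` best fits ``reference``; the returned RMSD is the
    minimum over all rigid transforms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("superposition requires equal selected atom counts")
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("superposition needs at least 3 non-collinear points")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    fitted = mob_c @ matrix.T
    translation = reference.mean(axis=0) - mobile.mean(axis=0) @ matrix.T
    return matrix, translation, rmsd(fitted, ref_c)


def superpose_trajectory(coords: np.ndarray, selection: np.ndarray,
                         reference: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto a reference using a selection of atoms.

    ``coords`` is ``(n_frames, n_atoms, 3)``; the fit is computed on
    ``selection`` and applied to all atoms.  ``reference`` defaults to the
    selection coordinates of the first frame.
    """
    coords = np.asarray(coords, dtype=float)
    selection = np.asarray(selection)
    if reference is None:
        reference = coords[0, selection]
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        matrix, translation, _ = superpose(coords[i, selection], reference)
        out[i] = coords[i] @ matrix.T + translation
    return out


_B_FACTOR_CONST = 8.0 * np.pi**2 / 3.0


def rmsf_bfactor(
    coords: np.ndarray,
    selection: np.ndarray,
    residue_numbers: np.ndarray,
):
    """Per-residue B-factors from positional fluctuations about the mean.

    ``B_i = (8 pi^2 / 3) <|r_i - <r_i>|^2>`` per selected atom, averaged over
    the atoms of each residue; frames must already be superposed onto a
    common reference.  Returns ``(residue_number_array, B_array)`` in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("B-factors require at least 2 frames")
    sel = np.asarray(selection)
    sub = coords[:, sel, :]
    mean = sub.mean(axis=0)
    msf = ((sub - mean) ** 2).sum(axis=2).mean(axis=0)  # per-atom <|dr|^2>
    b_atom = _B_FACTOR_CONST * msf
    resnums = np.asarray(residue_numbers)[sel]
    unique = np.unique(resnums)
    b_res = np.array([b_atom[resnums == r].mean() for r in unique])
    return unique, b_res
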