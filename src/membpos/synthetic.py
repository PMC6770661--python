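"""Synthetic membrane-anchored rigid-body systems with analytic ground truth.

The generator emulates the geometry of a cytochrome P450 anchored to a
phospholipid bilayer: a rigid pseudo-protein with labelled helical segments
(TM anchor, linker, globular domain containing C/F/I helices, an F'-G'
cluster and a planar four-nitrogen pseudo-heme), positioned over a planar
two-leaflet pseudo-bilayer whose particles carry head (PO4) and tail (C1A,
C2A) labels.  Every emitted trajectory comes with a per-frame ground-truth
orientation series computed in closed form from the applied rotation — an
oracle path independent of the analysis kernels, so parameter-recovery
tests are not self-fulfilling.

No physics is simulated: frames are rigid-body poses with optional
spherical-interpolation drift between two orientations and optional
isotropic Gaussian positional jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .core import (
    Frame,
    HemeSelection,
    InfeasibleTargetError,
    SegmentMap,
    Trajectory,
)
from .seqcompare import SequenceRecord

__all__ = [
    "DriftSpec",
    "SyntheticSpec",
    "class_a_spec",
    "class_b_spec",
    "feasible_beta_interval",
    "solve_pose_rotation",
    "build_body",
    "pose_body",
    "build_bilayer",
    "emit_trajectory",
    "recovery_target_grid",
    "synthetic_isoform_pair",
    "INTERFACE_SUBSTITUTIONS",
]

_Z = np.array([0.0, 0.0, 1.0])
_RES_SPACING = 1.5  # A per residue along a straight helix run

# Segment layout of the pseudo-protein (author numbering, inclusive ranges).
TM_RANGE = (3, 21)
LINKER_RANGE = (22, 49)
GLOBULAR_RANGE = (50, 130)
C_HELIX_RANGE = (60, 67)
F_HELIX_RANGE = (80, 87)
FG_RANGE = (95, 102)
I_HELIX_RANGE = (110, 125)
HEME_RESID = 600


@dataclass(frozen=True)
class DriftSpec:
    """Drift from the initial orientation to a final one at ``switch_frame``.

    Poses are spherically interpolated (every intermediate frame is a rigid
    pose) up to ``switch_frame`` and held constant afterwards.
    """

    final_alpha: float
    final_beta: float
    final_d_globular: float | None = None
    switch_frame: int = 0


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth targets and noise/drift settings for one synthetic system.

    Angles in degrees, distances in angstrom.  The defaults reproduce the
    class-A orientation regime typical of membrane-bound CYP 2C9 (alpha ~90,
    beta ~112, TM tilt ~15, heme tilt ~40, globular-domain height ~43 A);
    :func:`class_b_spec` gives the CYP 2C19-like class-B regime.
    """

    alpha: float = 90.0
    beta: float = 112.0
    gamma: float = 15.0
    heme_tilt: float = 40.0
    d_globular: float = 43.0
    v1_v2_angle: float = 80.0  # fixed body-frame angle between v1 and v2
    include_heme: bool = True
    include_tm: bool = True
    half_thickness: float = 19.0
    grid_n: int = 8
    grid_spacing: float = 8.0
    jitter_sigma: float = 0.0
    n_frames: int = 1
    drift: DriftSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 180.0 and 0.0 <= self.beta <= 180.0):
            raise ValueError("alpha and beta must lie in [0, 180] degrees")
        if not (0.0 <= self.gamma <= 90.0 and 0.0 <= self.heme_tilt <= 90.0):
            raise ValueError("gamma and heme tilt must lie in [0, 90] degrees")
        if self.half_thickness <= 0:
            raise ValueError("bilayer half-thickness must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def class_a_spec(**overrides) -> SyntheticSpec:
    """Class-A orientation regime (CYP 2C9-like)."""
    return replace(SyntheticSpec(), **overrides)


def class_b_spec(**overrides) -> SyntheticSpec:
    """Class-B orientation regime (CYP 2C19-like)."""
    base = SyntheticSpec(alpha=100.0, beta=137.0, gamma=13.0,
                         heme_tilt=58.0, d_globular=47.0)
    return replace(base, **overrides)


# --------------------------------------------------------------------------
# pose solving


def feasible_beta_interval(alpha: float, delta: float) -> tuple[float, float]:
    """Reachable beta interval for a given alpha and body-frame v1/v2 angle.

    Spherical triangle inequality: the polar angles of two unit vectors a
    fixed angle ``delta`` apart satisfy ``|alpha - delta| <= beta <=
    min(alpha + delta, 360 - alpha - delta)``.
    """
    return abs(alpha - delta), min(alpha + delta, 360.0 - alpha - delta)


def solve_pose_rotation(alpha: float, beta: float, delta: float) -> Rotation:
    """Rotation taking the body frame (v1 = +z, v2 at ``delta`` in xz) to lab.

    The returned rotation maps body v1 to a lab vector at polar angle
    ``alpha`` and body v2 to polar angle ``beta``; the residual degree of
    freedom (rotation about z) is fixed by placing v1 in the lab xz plane.
    """
    lo, hi = feasible_beta_interval(alpha, delta)
    a, b, d = np.radians([alpha, beta, delta])
    a1 = np.array([np.sin(a), 0.0, np.cos(a)])
    sin_a = np.sin(a)
    if sin_a < 1e-12:
        if abs(beta - (delta if np.cos(a) > 0 else 180.0 - delta)) > 1e-9:
            raise InfeasibleTargetError(
                f"beta={beta} unreachable for alpha={alpha} with v1/v2 angle "
                f"{delta}; feasible beta interval is [{lo:.6g}, {hi:.6g}]"
            )
        a2 = np.array([np.sin(b), 0.0, np.cos(b)])
    else:
        x = (np.cos(d) - np.cos(a) * np.cos(b)) / sin_a
        y_sq = np.sin(b) ** 2 - x**2
        if y_sq < -1e-9:
            raise InfeasibleTargetError(
                f"beta={beta} unreachable for alpha={alpha} with v1/v2 angle "
                f"{delta}; feasible beta interval is [{lo:.6g}, {hi:.6g}]"
            )
        a2 = np.array([x, np.sqrt(max(y_sq, 0.0)), np.cos(b)])
    # Orthonormal triads: body (z, x, y) -> lab (a1, orth(a2), a1 x orth(a2)).
    f1 = a1
    f2 = a2 - np.dot(a2, a1) * a1
    n2 = np.linalg.norm(f2)
    if n2 < 1e-12:
        # v2 parallel to v1 (delta ~ 0 or 180): pick any orthogonal direction.
        f2 = np.array([np.cos(a), 0.0, -np.sin(a)])
    else:
        f2 = f2 / n2
    f3 = np.cross(f1, f2)
    F = np.column_stack([f1, f2, f3])
    E = np.column_stack([_Z, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])])
    return Rotation.from_matrix(F @ E.T)


# --------------------------------------------------------------------------
# body construction


@dataclass
class BodyModel:
    """Rigid pseudo-protein in its body frame plus stored reference vectors."""

    positions: np.ndarray  # (n, 3) body-frame coordinates
    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    segmap: SegmentMap
    v1_body: np.ndarray
    v2_body: np.ndarray
    v3_body: np.ndarray | None
    heme_normal_body: np.ndarray | None
    spec: SyntheticSpec
    globular_mask: np.ndarray = field(init=False)
    linker_mask: np.ndarray = field(init=False)
    fg_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rn = self.residue_numbers
        self.globular_mask = (rn >= GLOBULAR_RANGE[0]) & (rn <= GLOBULAR_RANGE[1])
        self.linker_mask = (rn >= LINKER_RANGE[0]) & (rn <= LINKER_RANGE[1])
        self.fg_mask = (rn >= FG_RANGE[0]) & (rn <= FG_RANGE[1])


def _helix_run(res_range: tuple[int, int], center: np.ndarray,
               direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = res_range
    resnums = np.arange(lo, hi + 1)
    offsets = (resnums - resnums.mean()) * _RES_SPACING
    direction = direction / np.linalg.norm(direction)
    return center + offsets[:, None] * direction, resnums


def build_body(spec: SyntheticSpec) -> BodyModel:
    """Construct the rigid pseudo-protein scaffold in its body frame.

    The I-helix runs along the body z axis (its terminal four-residue axis
    is the body-frame v1); C- and F-helix stubs realise a body-frame v2 at
    the fixed ``spec.v1_v2_angle`` to v1; the TM segment and the planar
    four-nitrogen pseudo-heme are oriented so that, under the pose solved
    for ``(alpha, beta)``, the TM tilt and heme tilt meet their targets.
    """
    lo, hi = I_HELIX_RANGE
    if hi - lo + 1 < 8:
        raise ValueError("I-helix must span at least 8 residues")
    delta = np.radians(spec.v1_v2_angle)
    u2_body = np.array([np.sin(delta), 0.0, np.cos(delta)])
    rot = solve_pose_rotation(spec.alpha, spec.beta, spec.v1_v2_angle)
    R = rot.as_matrix()

    chunks_pos: list[np.ndarray] = []
    chunks_res: list[np.ndarray] = []

    # I-helix along body z through the origin.
    pos, res = _helix_run(I_HELIX_RANGE, np.array([0.0, 0.0, 0.0]), _Z)
    chunks_pos.append(pos)
    chunks_res.append(res)

    # C-helix stub; the F-helix stub is placed so that the vector from the
    # centre of mass of the first four C residues to that of the last four F
    # residues is exactly 24 A along u2_body.
    x_hat = np.array([1.0, 0.0, 0.0])
    c_center = np.array([-10.0, 7.0, -6.0])
    c_pos, c_res = _helix_run(C_HELIX_RANGE, c_center, x_hat)
    com_c_first = c_pos[:4].mean(axis=0)
    target_f_last = com_c_first + 24.0 * u2_body
    n_f = F_HELIX_RANGE[1] - F_HELIX_RANGE[0] + 1
    f_res = np.arange(F_HELIX_RANGE[0], F_HELIX_RANGE[1] + 1)
    f_offsets = (f_res - f_res.mean()) * _RES_SPACING
    # centre such that CoM of the last four residues hits the target
    last4_mean_offset = f_offsets[-4:].mean()
    f_center = target_f_last - last4_mean_offset * x_hat
    f_pos = f_center + f_offsets[:, None] * x_hat
    chunks_pos.extend([c_pos, f_pos])
    chunks_res.extend([c_res, f_res])

    # Globular filler on a deterministic spiral shell around the origin.
    filler_res = np.array(
        [r for r in range(GLOBULAR_RANGE[0], GLOBULAR_RANGE[1] + 1)
         if not (C_HELIX_RANGE[0] <= r <= C_HELIX_RANGE[1]
                 or F_HELIX_RANGE[0] <= r <= F_HELIX_RANGE[1]
                 or FG_RANGE[0] <= r <= FG_RANGE[1]
                 or I_HELIX_RANGE[0] <= r <= I_HELIX_RANGE[1])]
    )
    t = np.linspace(0.0, 4.0 * np.pi, filler_res.size)
    filler_pos = np.column_stack(
        [12.0 * np.cos(t), 12.0 * np.sin(t), np.linspace(-10.0, 10.0, t.size)]
    )
    chunks_pos.append(filler_pos)
    chunks_res.append(filler_res)

    # Interim globular centre of mass (before the F'-G' cluster is placed).
    interim = np.vstack([pos, c_pos, f_pos, filler_pos])
    g0 = interim.mean(axis=0)
    # Lab "down" direction expressed in the body frame: placing the F'-G'
    # cluster below the globular centre puts it nearest the membrane.
    down_body = R.T @ (-_Z)
    fg_center = g0 + 17.0 * down_body
    fg_res = np.arange(FG_RANGE[0], FG_RANGE[1] + 1)
    fg_offsets = (fg_res - fg_res.mean()) * 1.2
    fg_axis = np.array([1.0, 0.0, 0.0])
    fg_pos = fg_center + fg_offsets[:, None] * fg_axis
    chunks_pos.append(fg_pos)
    chunks_res.append(fg_res)

    positions = np.vstack(chunks_pos)
    resnums = np.concatenate(chunks_res)
    atom_names = np.full(len(resnums), "BB", dtype=object)
    resnames = np.full(len(resnums), "ALA", dtype=object)

    globular_mask = (resnums >= GLOBULAR_RANGE[0]) & (resnums <= GLOBULAR_RANGE[1])
    g_body = positions[globular_mask].mean(axis=0)

    v3_body = None
    if spec.include_tm:
        gam = np.radians(spec.gamma)
        v3_body = R.T @ np.array([np.sin(gam), 0.0, np.cos(gam)])
        # TM centred, in the lab frame of the *initial* pose, at the bilayer
        # midplane directly below the globular domain.
        d0 = spec.d_globular
        tm_center_body = R.T @ np.array([0.0, 0.0, -d0]) + g_body
        tm_pos, tm_res = _helix_run(TM_RANGE, tm_center_body, v3_body)
        # Linker beads on a straight path from the TM top to the globular rim.
        tm_top = tm_pos[-1]
        anchor = g_body + 16.0 * down_body
        n_link = LINKER_RANGE[1] - LINKER_RANGE[0] + 1
        frac = np.linspace(0.05, 0.95, n_link)[:, None]
        link_pos = tm_top + frac * (anchor - tm_top)
        link_res = np.arange(LINKER_RANGE[0], LINKER_RANGE[1] + 1)
        positions = np.vstack([tm_pos, link_pos, positions])
        resnums = np.concatenate([tm_res, link_res, resnums])
        atom_names = np.concatenate(
            [np.full(len(tm_res) + len(link_res), "BB", dtype=object), atom_names]
        )
        resnames = np.concatenate(
            [np.full(len(tm_res) + len(link_res), "ALA", dtype=object), resnames]
        )

    heme_normal_body = None
    if spec.include_heme:
        theta_n = np.radians(90.0 - spec.heme_tilt)
        n_lab = np.array([np.sin(theta_n), 0.0, np.cos(theta_n)])
        heme_normal_body = R.T @ n_lab
        # Orthonormal in-plane axes of the heme plane.
        ref = _Z if abs(heme_normal_body[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(heme_normal_body, ref)
        u /= np.linalg.norm(u)
        w = np.cross(heme_normal_body, u)
        heme_center = g_body + np.array([2.0, -2.0, 0.0])
        fe_n = 2.05  # Fe-N coordination distance
        heme_pos = heme_center + fe_n * np.array([u, -u, w, -w])
        positions = np.vstack([positions, heme_pos])
        resnums = np.concatenate([resnums, np.full(4, HEME_RESID)])
        atom_names = np.concatenate(
            [atom_names, np.array(["NA", "NB", "NC", "ND"], dtype=object)]
        )
        resnames = np.concatenate(
            [resnames, np.full(4, "HEM", dtype=object)]
        )

    segmap = SegmentMap(
        tm_helix=TM_RANGE if spec.include_tm else None,
        linker=LINKER_RANGE if spec.include_tm else None,
        globular=GLOBULAR_RANGE,
        c_helix=C_HELIX_RANGE,
        f_helix=F_HELIX_RANGE,
        i_helix=I_HELIX_RANGE,
        fprime_gprime=FG_RANGE,
        heme=HemeSelection() if spec.include_heme else None,
        lipid_residue_names=frozenset({"POP", "POPC"}),
        lipid_head=frozenset({"PO4"}),
        lipid_tail=frozenset({"C1A", "C2A"}),
        backbone=frozenset({"CA", "BB"}),
    )
    return BodyModel(
        positions=positions,
        atom_names=atom_names,
        residue_numbers=resnums,
        residue_names=resnames,
        segmap=segmap,
        v1_body=_Z.copy(),
        v2_body=u2_body,
        v3_body=v3_body,
        heme_normal_body=heme_normal_body,
        spec=spec,
    )


# --------------------------------------------------------------------------
# posing and ground truth


def _angle_deg(v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(v[2] / np.linalg.norm(v), -1, 1))))


def _fold(theta: float) -> float:
    return min(theta, 180.0 - theta)


def _ground_truth(body: BodyModel, R: np.ndarray, lab_positions: np.ndarray,
                  d_globular: float) -> dict:
    truth = {
        "alpha": _angle_deg(R @ body.v1_body),
        "beta": _angle_deg(R @ body.v2_body),
        "gamma": _fold(_angle_deg(R @ body.v3_body)) if body.v3_body is not None
        else np.nan,
        "heme_tilt": 90.0 - _fold(_angle_deg(R @ body.heme_normal_body))
        if body.heme_normal_body is not None else np.nan,
        "d_globular": float(d_globular),
        "d_linker": float(abs(lab_positions[body.linker_mask, 2].mean()))
        if body.linker_mask.any() else np.nan,
        "d_fg": float(abs(lab_positions[body.fg_mask, 2].mean())),
    }
    return truth


def pose_body(
    body: BodyModel,
    alpha: float | None = None,
    beta: float | None = None,
    d_globular: float | None = None,
    xy_center: tuple[float, float] = (0.0, 0.0),
) -> tuple[Frame, dict]:
    """Rigidly place the body over the bilayer midplane at target orientation.

    Returns the lab-frame protein :class:`Frame` (no lipids) and the
    analytic ground-truth orientation record.  Targets default to the
    body's own spec; the bilayer midplane is z = 0.
    """
    spec = body.spec
    alpha = spec.alpha if alpha is None else alpha
    beta = spec.beta if beta is None else beta
    d_globular = spec.d_globular if d_globular is None else d_globular
    rot = solve_pose_rotation(alpha, beta, spec.v1_v2_angle)
    R = rot.as_matrix()
    g_body = body.positions[body.globular_mask].mean(axis=0)
    t = np.array([xy_center[0], xy_center[1], d_globular]) - R @ g_body
    lab = body.positions @ R.T + t
    frame = Frame(
        atom_names=body.atom_names,
        residue_numbers=body.residue_numbers,
        residue_names=body.residue_names,
        positions=lab,
        segment_ids=np.full(len(lab), "P", dtype=object),
    )
    return frame, _ground_truth(body, R, lab, d_globular)


# --------------------------------------------------------------------------
# bilayer


def build_bilayer(spec: SyntheticSpec) -> Frame:
    """Planar two-leaflet pseudo-bilayer on a square grid.

    Each grid site carries, per leaflet, one head particle (PO4) at
    z = +/- half_thickness and two tail particles (C1A, C2A) at 6 and 12 A
    below the head plane.  The construction is mirror-symmetric, so the
    bilayer z centre of mass is exactly 0.
    """
    h = spec.half_thickness
    s = spec.grid_spacing
    n = spec.grid_n
    xs = (np.arange(n) + 0.5) * s
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])

    pos_list, name_list, resid_list = [], [], []
    resid = 1001
    tail_dz = (6.0, 12.0)
    for leaflet in (+1.0, -1.0):
        for x, y in sites:
            pos_list.append([x, y, leaflet * h])
            name_list.append("PO4")
            resid_list.append(resid)
            for dz, nm in zip(tail_dz, ("C1A", "C2A")):
                pos_list.append([x, y, leaflet * (h - dz)])
                name_list.append(nm)
                resid_list.append(resid)
            resid += 1

    box_xy = n * s
    box_z = 2.0 * (abs(spec.d_globular) + 60.0)
    return Frame(
        atom_names=np.array(name_list, dtype=object),
        residue_numbers=np.array(resid_list),
        residue_names=np.full(len(pos_list), "POP", dtype=object),
        positions=np.array(pos_list),
        segment_ids=np.full(len(pos_list), "L", dtype=object),
        box=np.array([box_xy, box_xy, box_z]),
    )


# --------------------------------------------------------------------------
# trajectory emission


def emit_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, pd.DataFrame, SegmentMap]:
    """Emit a synthetic trajectory plus its ground-truth orientation series.

    Per frame, the posed body is combined with the static bilayer; every
    particle then receives isotropic Gaussian jitter of width
    ``spec.jitter_sigma``.  With a :class:`DriftSpec`, the pose is
    spherically interpolated from the initial to the final orientation up to
    the switch frame and held constant afterwards.  All randomness comes
    from one generator seeded with ``spec.seed``; identical specs produce
    bit-identical trajectories.
    """
    body = build_body(spec)
    bilayer = build_bilayer(spec)
    center = (bilayer.box[0] / 2.0, bilayer.box[1] / 2.0)

    rot0 = solve_pose_rotation(spec.alpha, spec.beta, spec.v1_v2_angle)
    d0 = spec.d_globular
    if spec.drift is not None:
        drift = spec.drift
        if not 0 < drift.switch_frame <= spec.n_frames:
            raise ValueError("drift switch frame must lie within the trajectory")
        rot1 = solve_pose_rotation(drift.final_alpha, drift.final_beta,
                                   spec.v1_v2_angle)
        slerp = Slerp([0.0, 1.0], Rotation.concatenate([rot0, rot1]))
        d1 = d0 if drift.final_d_globular is None else drift.final_d_globular
    g_body = body.positions[body.globular_mask].mean(axis=0)

    rng = np.random.default_rng(spec.seed)
    n_protein = len(body.positions)
    n_total = n_protein + bilayer.n_atoms
    coords = np.empty((spec.n_frames, n_total, 3))
    truth_rows = []
    for k in range(spec.n_frames):
        if spec.drift is None:
            R = rot0.as_matrix()
            d = d0
        else:
            f = min(k / spec.drift.switch_frame, 1.0)
            R = slerp([f]).as_matrix()[0]
            d = d0 + f * (d1 - d0)
        t = np.array([center[0], center[1], d]) - R @ g_body
        lab = body.positions @ R.T + t
        truth_rows.append(_ground_truth(body, R, lab, d))
        coords[k, :n_protein] = lab
        coords[k, n_protein:] = bilayer.positions
    if spec.jitter_sigma > 0:
        coords += rng.normal(0.0, spec.jitter_sigma, size=coords.shape)

    traj = Trajectory(
        atom_names=np.concatenate([body.atom_names, bilayer.atom_names]),
        residue_numbers=np.concatenate(
            [body.residue_numbers, bilayer.residue_numbers]
        ),
        residue_names=np.concatenate([body.residue_names, bilayer.residue_names]),
        coordinates=coords,
        segment_ids=np.concatenate(
            [np.full(n_protein, "P", dtype=object), bilayer.segment_ids]
        ),
        box=bilayer.box,
    )
    truth = pd.DataFrame(truth_rows)
    truth.index.name = "frame"
    truth.attrs["seed"] = spec.seed
    return traj, truth, body.segmap


def recovery_target_grid(delta: float = 80.0) -> list[SyntheticSpec]:
    """Feasible orientation-target grid for parameter-recovery scoring.

    Spans alpha in [70, 110], beta in [100, 150], TM tilt in [0, 30] and
    heme tilt in [30, 75]; targets violating the spherical feasibility
    constraint for the given body-frame v1/v2 angle are dropped.
    """
    targets = []
    for alpha, beta, (gamma, tilt) in product(
        (70.0, 90.0, 110.0),
        (100.0, 125.0, 150.0),
        ((0.0, 30.0), (15.0, 52.0), (30.0, 75.0)),
    ):
        lo, hi = feasible_beta_interval(alpha, delta)
        if not lo <= beta <= hi:
            continue
        targets.append(
            SyntheticSpec(alpha=alpha, beta=beta, gamma=gamma, heme_tilt=tilt,
                          v1_v2_angle=delta)
        )
    return targets


# --------------------------------------------------------------------------
# synthetic isoform sequences

#: Membrane-interface residue swaps distinguishing the two isoforms
#: (linker, beta-strand 1-2, B-C loop, F'-G' helices), plus the two
#: active-site differences at 208 and 362.
INTERFACE_SUBSTITUTIONS = {
    46: ("G", "D"),
    72: ("K", "E"),
    73: ("P", "R"),
    99: ("I", "H"),
    220: ("S", "P"),
    221: ("P", "T"),
}
_ACTIVE_SITE_SUBSTITUTIONS = {208: ("L", "V"), 362: ("L", "I")}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def synthetic_isoform_pair(length: int = 490) -> tuple[SequenceRecord, SequenceRecord]:
    """Deterministic synthetic stand-in for the CYP 2C9/2C19 isoform pair.

    Two ``length``-residue sequences (default 490, the length of both real
    isoforms) differing at exactly 43 positions, i.e. 91.2 % positional
    identity, with the six membrane-interface substitutions
    (G46D, K72E, P73R, I99H, S220P, P221T) and the two active-site ones
    (L208V, L362I) pinned at their canonical positions.  These are
    *synthetic* sequences for offline testing, not the UniProt entries
    (P11712/P33261); supply real FASTA files for production comparisons.
    """
    n_diff = 43
    rng = np.random.default_rng(20040328)
    base = rng.choice(list(_AA), size=length)
    pinned = {**INTERFACE_SUBSTITUTIONS, **_ACTIVE_SITE_SUBSTITUTIONS}
    seq_a = base.copy()
    seq_b = base.copy()
    for pos, (ra, rb) in pinned.items():
        seq_a[pos - 1] = ra
        seq_b[pos - 1] = rb
    # Remaining substitutions at deterministic positions away from the
    # pinned ones.
    candidates = np.array(
        [p for p in range(1, length + 1) if p not in pinned], dtype=int
    )
    extra = rng.choice(candidates, size=n_diff - len(pinned), replace=False)
    for pos in extra:
        current = seq_a[pos - 1]
        alternatives = [aa for aa in _AA if aa != current]
        seq_b[pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
    return (
        SequenceRecord(id="synthetic_isoform_A", residues="".join(seq_a)),
        SequenceRecord(id="synthetic_isoform_B", residues="".join(seq_b)),
    )
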