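"""Per-residue protein-lipid contact occupancy.

A residue is counted as contacting the lipid head (tail) region in a frame
when any of its particles lies within the cutoff distance (default 5 A) of
any lipid head (tail) particle.  Head particles default to the phosphate
group (atomistic P/O1x or coarse-grained PO4 bead); tail particles are the
acyl-chain carbons/beads.  Occupancy is the percentage of analysed frames
with a contact.  Distances apply the minimal-image convention in x and y
only: the membrane is periodic in-plane while the protein never wraps in z
in slab geometries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ConfigurationError, SegmentMap, Trajectory, resolve_segments

__all__ = ["contact_occupancy", "occupancy_report"]


def _min_image_contact(
    protein_xyz: np.ndarray,
    lipid_xyz: np.ndarray,
    box_xy: np.ndarray | None,
    cutoff: float,
) -> np.ndarray:
    """Boolean per protein particle: any lipid particle within cutoff."""
    if lipid_xyz.size == 0:
        return np.zeros(len(protein_xyz), dtype=bool)
    delta = protein_xyz[:, None, :] - lipid_xyz[None, :, :]
    if box_xy is not None:
        for ax in (0, 1):
            delta[:, :, ax] -= box_xy[ax] * np.round(delta[:, :, ax] / box_xy[ax])
    dist2 = (delta**2).sum(axis=2)
    return (dist2 <= cutoff * cutoff).any(axis=1)


def contact_occupancy(
    traj: Trajectory,
    segmap: SegmentMap,
    cutoff: float = 5.0,
    window: tuple[int, int] | None = None,
    stride: int = 1,
    include_hydrogens: bool = False,
) -> pd.DataFrame:
    """Per-residue head/tail contact occupancy over an analysis window.

    Returns a DataFrame with columns ``residue_number``, ``residue_name``,
    ``head_pct``, ``tail_pct`` and attribute ``n_frames`` (the occupancy
    denominator: frames in the window after striding).  Hydrogens are
    excluded by default for atomistic input since the cutoff is calibrated
    on heavy atoms.
    """
    if cutoff <= 0:
        raise ConfigurationError("contact cutoff must be positive")
    resolved = resolve_segments(traj, segmap)
    if resolved.lipid_head.size == 0 or resolved.lipid_tail.size == 0:
        raise ConfigurationError(
            "lipid head and tail particle name sets must both match particles"
        )

    is_lipid = np.isin(traj.residue_names, list(segmap.lipid_residue_names))
    protein_mask = ~is_lipid
    if segmap.heme is not None:
        protein_mask &= ~np.isin(traj.residue_names, list(segmap.heme.residue_names))
    if not include_hydrogens:
        names = np.array([str(n).strip() for n in traj.atom_names])
        is_h = np.char.startswith(np.char.lstrip(names, "0123456789"), "H")
        protein_mask &= ~is_h
    protein_idx = np.flatnonzero(protein_mask)
    if protein_idx.size == 0:
        raise ConfigurationError("no protein particles for contact analysis")

    n = traj.n_frames
    start, stop = (0, n) if window is None else window
    if not (0 <= start < stop <= n):
        raise ValueError(f"window ({start}, {stop}) invalid for {n} frames")
    frames = range(start, stop, stride)
    if len(frames) == 0:
        raise ValueError("empty contact analysis window")

    box_xy = None if traj.box is None else traj.box[:2]
    resnums = traj.residue_numbers[protein_idx]
    unique_res = np.unique(resnums)
    res_pos = np.searchsorted(unique_res, resnums)
    head_counts = np.zeros(unique_res.size, dtype=int)
    tail_counts = np.zeros(unique_res.size, dtype=int)

    for f in frames:
        xyz = traj.coordinates[f]
        p = xyz[protein_idx]
        head_hit = _min_image_contact(p, xyz[resolved.lipid_head], box_xy, cutoff)
        tail_hit = _min_image_contact(p, xyz[resolved.lipid_tail], box_xy, cutoff)
        head_res = np.zeros(unique_res.size, dtype=bool)
        tail_res = np.zeros(unique_res.size, dtype=bool)
        np.logical_or.at(head_res, res_pos, head_hit)
        np.logical_or.at(tail_res, res_pos, tail_hit)
        head_counts += head_res
        tail_counts += tail_res

    n_frames = len(frames)
    first_name = {}
    for i, r in enumerate(resnums):
        first_name.setdefault(int(r), str(traj.residue_names[protein_idx[i]]))
    out = pd.DataFrame(
        {
            "residue_number": unique_res,
            "residue_name": [first_name[int(r)] for r in unique_res],
            "head_pct": 100.0 * head_counts / n_frames,
            "tail_pct": 100.0 * tail_counts / n_frames,
        }
    )
    out.attrs["n_frames"] = n_frames
    out.attrs["cutoff"] = cutoff
    return out


def occupancy_report(
    table: pd.DataFrame, annotations: dict | None = None
) -> pd.DataFrame:
    """Annotate and filter an occupancy table for reporting.

    ``annotations`` maps labels (e.g. secondary-structure elements or
    substrate recognition sites) to inclusive residue ranges; every residue
    row receives all overlapping labels, joined with ``;``.  Residues with
    zero head and tail occupancy are dropped; the result is sorted by
    residue number.
    """
    out = table[(table["head_pct"] > 0) | (table["tail_pct"] > 0)].copy()
    out = out.sort_values("residue_number").reset_index(drop=True)
    labels = []
    for r in out["residue_number"]:
        hits = []
        for label, (lo, hi) in (annotations or {}).items():
            if lo <= r <= hi:
                hits.append(label)
        labels.append(";".join(hits))
    out["annotations"] = labels
    out.attrs.update(table.attrs)
    return out
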