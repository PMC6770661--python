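"""Per-frame orientation records, summaries, classification and convergence.

The orientation of the globular domain above the bilayer is described per
frame by:

* ``alpha`` — angle between v1 (I-helix axis, terminal four-residue centres
  of mass) and the membrane normal, degrees in [0, 180];
* ``beta`` — angle between v2 (centre of mass of the first four C-helix
  residues to that of the last four F-helix residues) and the normal;
* ``gamma`` — TM-helix tilt, folded to [0, 90];
* ``heme_tilt`` — plane-line angle of the four heme nitrogens to the normal,
  [0, 90]; NaN when the model carries no heme (coarse-grained runs);
* ``d_globular``, ``d_linker``, ``d_fg`` — axial distances (angstrom) of the
  globular domain, linker and F'-G' centres of mass from the bilayer centre.

Orientations are assigned to class A (beta < 125), A/B (125 <= beta <= 130)
or B (beta > 130); the thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, ResolvedSegments, SegmentMap, Trajectory
from . import geometry

__all__ = [
    "ORIENTATION_FIELDS",
    "REPRESENTATIVE_FIELDS",
    "orientation_series",
    "classify",
    "SummaryRow",
    "summarize",
    "ConvergenceReport",
    "detect_convergence",
    "RepresentativeFrame",
    "select_representative_frame",
    "distribution_table",
]

ORIENTATION_FIELDS = (
    "alpha", "beta", "gamma", "heme_tilt", "d_globular", "d_linker", "d_fg"
)
#: Fields monitored when picking a representative frame for back-mapping.
REPRESENTATIVE_FIELDS = ("alpha", "beta", "gamma", "d_globular", "d_fg")

DEFAULT_CLASS_THRESHOLDS = (125.0, 130.0)


def _terminal_group_indices(
    traj: Trajectory, resolved: ResolvedSegments, segment: str, terminal_n: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    if segment not in resolved.backbone_ranges:
        raise ConfigurationError(
            f"segment map lacks the {segment} range required for orientation"
        )
    idx = resolved.backbone_ranges[segment]
    resnums = traj.residue_numbers[idx]
    unique = np.unique(resnums)
    if unique.size < 2 * terminal_n:
        raise ConfigurationError(
            f"segment {segment} has only {unique.size} backbone residues; "
            f"need {2 * terminal_n}"
        )
    first = idx[np.isin(resnums, unique[:terminal_n])]
    last = idx[np.isin(resnums, unique[-terminal_n:])]
    return first, last


def _angles_to_z(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero orientation vector")
    return np.degrees(np.arccos(np.clip(vectors[:, 2] / norms, -1.0, 1.0)))


def orientation_series(
    traj: Trajectory,
    segmap: SegmentMap,
    resolved: ResolvedSegments | None = None,
    terminal_n: int = 4,
) -> pd.DataFrame:
    """Compute one orientation record per frame of a trajectory.

    Returns a DataFrame indexed by frame with the columns of
    :data:`ORIENTATION_FIELDS`.  When the segment map declares no heme
    (coarse-grained models), ``heme_tilt`` is NaN and
    ``df.attrs["heme_absent"]`` is True.  The z axis is oriented so the
    globular domain lies above the bilayer centre; frames violating the
    convention are flipped and listed in ``df.attrs["z_flipped_frames"]``.
    """
    if resolved is None:
        from .core import resolve_segments

        resolved = resolve_segments(traj, segmap)
    coords = traj.coordinates
    n_frames = coords.shape[0]

    if resolved.lipid_all.size == 0:
        raise ConfigurationError("no lipid particles; cannot locate bilayer centre")
    z_bilayer = coords[:, resolved.lipid_all, 2].mean(axis=1)

    # Sign convention: globular domain above the bilayer centre.
    z_glob = coords[:, resolved["globular"], 2].mean(axis=1)
    sign = np.where(z_glob >= z_bilayer, 1.0, -1.0)
    flipped = np.flatnonzero(sign < 0)

    def seg_axis(segment: str) -> np.ndarray:
        first, last = _terminal_group_indices(traj, resolved, segment, terminal_n)
        vec = coords[:, last, :].mean(axis=1) - coords[:, first, :].mean(axis=1)
        vec = vec.copy()
        vec[:, 2] *= sign
        return vec

    # v1: along the I-helix; v2: first four C-helix to last four F-helix residues.
    v1 = seg_axis("i_helix")
    c_first, _ = _terminal_group_indices(traj, resolved, "c_helix", terminal_n)
    _, f_last = _terminal_group_indices(traj, resolved, "f_helix", terminal_n)
    v2 = coords[:, f_last, :].mean(axis=1) - coords[:, c_first, :].mean(axis=1)
    v2[:, 2] *= sign

    alpha = _angles_to_z(v1)
    beta = _angles_to_z(v2)

    if "tm_helix" in resolved.ranges:
        v3 = seg_axis("tm_helix")
        gamma = np.minimum(_angles_to_z(v3), 180.0 - _angles_to_z(v3))
    else:
        gamma = np.full(n_frames, np.nan)

    if resolved.heme is not None:
        pts = coords[:, resolved.heme, :]
        centered = pts - pts.mean(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if np.any(s[:, 1] < 1e-9 * np.maximum(s[:, 0], 1e-30)):
            raise ValueError("degenerate heme nitrogen geometry")
        normals = vt[:, 2, :]
        theta = np.degrees(np.arccos(np.clip(np.abs(normals[:, 2]), -1.0, 1.0)))
        heme = 90.0 - theta
    else:
        heme = np.full(n_frames, np.nan)

    def seg_dist(segment: str) -> np.ndarray:
        if segment not in resolved.ranges:
            return np.full(n_frames, np.nan)
        return np.abs(coords[:, resolved[segment], 2].mean(axis=1) - z_bilayer)

    df = pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
            "heme_tilt": heme,
            "d_globular": seg_dist("globular"),
            "d_linker": seg_dist("linker"),
            "d_fg": seg_dist("fprime_gprime"),
        }
    )
    df.index.name = "frame"
    df.attrs["heme_absent"] = resolved.heme is None
    df.attrs["z_flipped_frames"] = flipped.tolist()
    return df


def classify(
    beta: float, thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS
) -> str:
    """Assign an orientation class from the beta angle.

    ``A`` below the lower threshold, ``A/B`` in the closed interval between
    the thresholds, ``B`` above the upper threshold.  With the default
    125/130 thresholds this reproduces the published class assignments for
    the CYP 2C9 (class A) and CYP 2C19 (class B) orientation regimes.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ConfigurationError("class thresholds must be strictly increasing")
    if not (0.0 <= beta <= 180.0) or not np.isfinite(beta):
        raise ValueError(f"beta angle {beta} outside [0, 180]")
    if beta < lo:
        return "A"
    if beta <= hi:
        return "A/B"
    return "B"


def _resolve_window(n: int, window) -> tuple[int, int]:
    """Normalize a window spec to a half-open frame range (start, stop)."""
    if window is None:
        return 0, n
    if isinstance(window, tuple) and len(window) == 2 and window[0] == "last_fraction":
        frac = float(window[1])
        if not 0 < frac <= 1:
            raise ValueError("last_fraction must be in (0, 1]")
        start = n - max(1, int(round(frac * n)))
        return start, n
    start, stop = int(window[0]), int(window[1])
    if start < 0 or stop > n or stop <= start:
        raise ValueError(f"window ({start}, {stop}) invalid for series of length {n}")
    return start, stop


@dataclass
class SummaryRow:
    """Mean/SD of each orientation field over an analysis window."""

    means: dict
    sds: dict
    window: tuple[int, int]
    stride: int
    n_used: int
    orientation_class: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in ORIENTATION_FIELDS:
            rows.append({"field": f, "mean": self.means[f], "sd": self.sds[f]})
        df = pd.DataFrame(rows)
        df.attrs["class"] = self.orientation_class
        return df


def summarize(
    series: pd.DataFrame,
    window=("last_fraction", 0.9),
    stride: int = 1,
    thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS,
) -> SummaryRow:
    """Sample mean and SD over a strided window; class from the mean beta.

    The default window, the last 90 % of the series, mirrors the common
    practice of summarising production trajectories over their converged
    tail (e.g. the last 9 us of a 10 us run).
    """
    start, stop = _resolve_window(len(series), window)
    sub = series.iloc[start:stop:stride]
    if len(sub) == 0:
        raise ValueError("empty summary window")
    means = {f: float(sub[f].mean()) for f in ORIENTATION_FIELDS if f in sub}
    sds = {f: float(sub[f].std(ddof=0)) for f in ORIENTATION_FIELDS if f in sub}
    return SummaryRow(
        means=means,
        sds=sds,
        window=(start, stop),
        stride=stride,
        n_used=len(sub),
        orientation_class=classify(means["beta"], thresholds),
    )


DEFAULT_CONVERGENCE_FIELDS = ("beta", "d_globular")
DEFAULT_TOLERANCES = {
    "alpha": 2.0, "beta": 2.0, "gamma": 2.0, "heme_tilt": 2.0,
    "d_globular": 1.0, "d_linker": 1.0, "d_fg": 1.0,
}


@dataclass
class ConvergenceReport:
    converged: bool
    start_frame: int | None
    monitored: tuple
    window_size: int
    tolerances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged != (self.start_frame is not None):
            raise ValueError("start_frame must be set iff converged")


def detect_convergence(
    series: pd.DataFrame,
    fields: tuple = DEFAULT_CONVERGENCE_FIELDS,
    window_size: int | None = None,
    tolerances: dict | None = None,
) -> ConvergenceReport:
    """Find the earliest frame after which the orientation stops changing.

    The series is tiled into non-overlapping windows of ``window_size``
    frames aligned with the *final* window; the converged region extends
    backwards from the end for as long as every window's mean of every
    monitored field lies within the per-field tolerance of the final
    window's mean (a partial leading window is included in the check, so a
    fully stationary series converges from frame 0).  The series counts as
    converged only when at least two windows agree, so a monotone drift
    spanning the whole series is reported as not converged.  ``window_size``
    defaults to 10 % of the series length; tolerances default to 2 degrees
    for angles and 1 angstrom for distances, matching the scale of typical
    converged-run standard deviations.
    """
    n = len(series)
    if window_size is None:
        window_size = max(1, n // 10)
    if n < 2 * window_size:
        raise ValueError(
            f"series of {n} frames shorter than two windows of {window_size}"
        )
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    values = series[list(fields)].to_numpy(dtype=float)
    final_mean = values[n - window_size:].mean(axis=0)
    tol_vec = np.array([tol[f] for f in fields])

    def window_ok(lo: int, hi: int) -> bool:
        win_mean = values[lo:hi].mean(axis=0)
        return bool(np.all(np.abs(win_mean - final_mean) <= tol_vec))

    start = n - window_size
    while start - window_size >= 0 and window_ok(start - window_size, start):
        start -= window_size
    if 0 < start < window_size and window_ok(0, start):
        start = 0
    converged = start <= n - 2 * window_size
    return ConvergenceReport(
        converged=converged,
        start_frame=start if converged else None,
        monitored=tuple(fields),
        window_size=window_size,
        tolerances={f: tol[f] for f in fields},
    )


@dataclass
class RepresentativeFrame:
    frame: int
    max_relative_deviation: float
    within_tolerance: bool
    monitored: tuple


def select_representative_frame(
    series: pd.DataFrame,
    window=None,
    fields: tuple = REPRESENTATIVE_FIELDS,
    rel_tol: float = 0.01,
) -> RepresentativeFrame:
    """Pick the frame whose monitored values best match the window means.

    The representative frame (used e.g. as the seed structure for
    back-mapping a coarse-grained pose to all-atom resolution) must have
    every monitored value within ``rel_tol`` (default 1 %) relative
    deviation of its mean over the converged window.  Among qualifying
    frames the one minimising the maximum relative deviation is returned;
    when no frame qualifies the minimiser is returned flagged
    ``within_tolerance=False``.
    """
    start, stop = _resolve_window(len(series), window)
    fields = tuple(f for f in fields if f in series and series[f].notna().all())
    sub = series.iloc[start:stop]
    if len(sub) == 0:
        raise ValueError("empty representative-frame window")
    values = sub[list(fields)].to_numpy(dtype=float)
    means = values.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("zero mean in monitored field; relative deviation undefined")
    rel_dev = np.abs(values - means) / np.abs(means)
    max_dev = rel_dev.max(axis=1)
    best = int(np.argmin(max_dev))
    return RepresentativeFrame(
        frame=int(sub.index[best]),
        max_relative_deviation=float(max_dev[best]),
        within_tolerance=bool(max_dev[best] <= rel_tol),
        monitored=fields,
    )


def distribution_table(
    values, bin_width: float, value_range: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Normalized histogram of an orientation field (density sums to 1/width).

    Returns columns ``bin_left``, ``bin_right``, ``density`` with
    ``sum(density) * bin_width == 1``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no values to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if value_range is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = value_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )
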