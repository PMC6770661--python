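"""Core containers: frames, trajectories, segment maps.

Coordinates are Cartesian and in angstroms throughout.  Residue numbering is
always the *author* numbering carried by the input file (1-based, matching the
UniProt-aligned numbering conventional for cytochrome P450s); nothing in this
package ever renumbers residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ParseError",
    "StructureError",
    "ConfigurationError",
    "InfeasibleTargetError",
    "Frame",
    "Trajectory",
    "HemeSelection",
    "SegmentMap",
    "ResolvedSegments",
    "resolve_segments",
]


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class StructureError(ValueError):
    """Parsed input violates a structural requirement (e.g. model mismatch)."""


class ConfigurationError(ValueError):
    """A segment map or run configuration is inconsistent with the input."""


class InfeasibleTargetError(ValueError):
    """A requested synthetic orientation target is geometrically unreachable."""


def _as_str_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class Frame:
    """One set of particle coordinates with identity metadata.

    Parameters
    ----------
    atom_names, residue_numbers, residue_names, segment_ids
        Per-particle identity, in file order.
    positions
        ``(n, 3)`` array of coordinates in angstrom.
    box
        Orthorhombic box edge lengths ``(lx, ly, lz)`` in angstrom, or
        ``None`` when the input carried no box.
    """

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    positions: np.ndarray
    segment_ids: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        n = len(self.positions)
        self.atom_names = _as_str_array(self.atom_names, n, "atom_names")
        self.residue_names = _as_str_array(self.residue_names, n, "residue_names")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.residue_numbers.shape != (n,):
            raise ValueError("residue_numbers must match particle count")
        if self.segment_ids is None:
            self.segment_ids = np.full(n, "A", dtype=object)
        else:
            self.segment_ids = _as_str_array(self.segment_ids, n, "segment_ids")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if n and self.residue_numbers.min() < 1:
            raise ValueError("residue numbers must be >= 1 (author numbering)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box edge lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def with_positions(self, positions: np.ndarray) -> "Frame":
        return replace(self, positions=np.asarray(positions, dtype=float))


@dataclass
class Trajectory:
    """A time-ordered stack of frames sharing one particle identity.

    Particle order is identical in every frame (enforced at construction by
    the readers and the generator); ``coordinates`` has shape
    ``(n_frames, n_atoms, 3)``.
    """

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    coordinates: np.ndarray
    segment_ids: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        n = self.coordinates.shape[1]
        self.atom_names = _as_str_array(self.atom_names, n, "atom_names")
        self.residue_names = _as_str_array(self.residue_names, n, "residue_names")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.residue_numbers.shape != (n,):
            raise ValueError("residue_numbers must match particle count")
        if self.segment_ids is None:
            self.segment_ids = np.full(n, "A", dtype=object)
        else:
            self.segment_ids = _as_str_array(self.segment_ids, n, "segment_ids")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(
            atom_names=self.atom_names,
            residue_numbers=self.residue_numbers,
            residue_names=self.residue_names,
            positions=self.coordinates[i],
            segment_ids=self.segment_ids,
            box=self.box,
        )

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @staticmethod
    def from_frames(frames: list[Frame]) -> "Trajectory":
        if not frames:
            raise StructureError("no frames")
        first = frames[0]
        for i, f in enumerate(frames[1:], start=2):
            if f.n_atoms != first.n_atoms:
                raise StructureError(
                    f"atom count mismatch in model {i}: "
                    f"{f.n_atoms} != {first.n_atoms}"
                )
            if not (
                np.array_equal(f.atom_names, first.atom_names)
                and np.array_equal(f.residue_numbers, first.residue_numbers)
            ):
                raise StructureError(f"particle identity mismatch in model {i}")
        return Trajectory(
            atom_names=first.atom_names,
            residue_numbers=first.residue_numbers,
            residue_names=first.residue_names,
            coordinates=np.stack([f.positions for f in frames]),
            segment_ids=first.segment_ids,
            box=first.box,
        )


ResidueRange = tuple[int, int]

# Helices whose axis is taken between terminal four-residue centres of mass
# must be long enough that the two terminal groups do not overlap.
_MIN_AXIS_SPAN = 8


@dataclass(frozen=True)
class HemeSelection:
    """Selection of the four heme nitrogens coordinating the iron."""

    residue_names: frozenset = frozenset({"HEM", "HEC"})
    atom_names: frozenset = frozenset({"NA", "NB", "NC", "ND"})


@dataclass
class SegmentMap:
    """Named residue-range annotations driving every geometric construction.

    Ranges are inclusive ``(first, last)`` pairs in author numbering.  The
    canonical CYP annotation (the defaults used by the synthetic generator
    differ) is: TM helix 3-21, linker 22-49, globular domain 50-490,
    I-helix 286-316, F'-G' helices 210-220.  The C- and F-helix ranges that
    define the v2 orientation vector are not standardized and must come from
    user configuration.
    """

    tm_helix: ResidueRange | None
    linker: ResidueRange | None
    globular: ResidueRange
    c_helix: ResidueRange | None
    f_helix: ResidueRange | None
    i_helix: ResidueRange | None
    fprime_gprime: ResidueRange | None
    heme: HemeSelection | None = None
    lipid_residue_names: frozenset = frozenset({"POP", "POPC"})
    lipid_head: frozenset = frozenset({"P", "O11", "O12", "O13", "O14", "PO4"})
    lipid_tail: frozenset = frozenset()
    backbone: frozenset = frozenset({"CA", "BB"})

    def __post_init__(self) -> None:
        for name in ("tm_helix", "linker", "globular", "c_helix", "f_helix",
                     "i_helix", "fprime_gprime"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = int(rng[0]), int(rng[1])
            if hi < lo:
                raise ConfigurationError(f"empty residue range for {name}: {lo}-{hi}")
            setattr(self, name, (lo, hi))
        for name in ("tm_helix", "c_helix", "f_helix", "i_helix"):
            rng = getattr(self, name)
            if rng is not None and rng[1] - rng[0] + 1 < _MIN_AXIS_SPAN:
                raise ConfigurationError(
                    f"{name} range {rng[0]}-{rng[1]} spans fewer than "
                    f"{_MIN_AXIS_SPAN} residues; terminal four-residue centres "
                    "of mass would overlap"
                )
        if self.lipid_head & self.lipid_tail:
            raise ConfigurationError(
                "lipid head and tail particle name sets overlap: "
                f"{sorted(self.lipid_head & self.lipid_tail)}"
            )

    # -- configuration file round trip ------------------------------------

    def to_dict(self) -> dict:
        d: dict = {}
        for name in ("tm_helix", "linker", "globular", "c_helix", "f_helix",
                     "i_helix", "fprime_gprime"):
            rng = getattr(self, name)
            if rng is not None:
                d[name] = list(rng)
        if self.heme is not None:
            d["heme"] = {
                "residue_names": sorted(self.heme.residue_names),
                "atom_names": sorted(self.heme.atom_names),
            }
        d["lipid_residue_names"] = sorted(self.lipid_residue_names)
        d["lipid_head"] = sorted(self.lipid_head)
        d["lipid_tail"] = sorted(self.lipid_tail)
        d["backbone"] = sorted(self.backbone)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "SegmentMap":
        def rng(key):
            v = d.get(key)
            return None if v is None else (int(v[0]), int(v[1]))

        heme = None
        if "heme" in d and d["heme"] is not None:
            h = d["heme"]
            heme = HemeSelection(
                residue_names=frozenset(h.get("residue_names", {"HEM", "HEC"})),
                atom_names=frozenset(h.get("atom_names", {"NA", "NB", "NC", "ND"})),
            )
        kwargs = {}
        for key in ("lipid_residue_names", "lipid_head", "lipid_tail", "backbone"):
            if key in d:
                kwargs[key] = frozenset(d[key])
        return SegmentMap(
            tm_helix=rng("tm_helix"),
            linker=rng("linker"),
            globular=rng("globular"),
            c_helix=rng("c_helix"),
            f_helix=rng("f_helix"),
            i_helix=rng("i_helix"),
            fprime_gprime=rng("fprime_gprime"),
            heme=heme,
            **kwargs,
        )


@dataclass
class ResolvedSegments:
    """Index arrays into one particle ordering, one entry per configured segment."""

    segmap: SegmentMap
    ranges: dict  # segment name -> np.ndarray of particle indices (all particles)
    backbone_ranges: dict  # segment name -> indices restricted to backbone names
    heme: np.ndarray | None
    lipid_all: np.ndarray
    lipid_head: np.ndarray
    lipid_tail: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.ranges[name]


def resolve_segments(frame: Frame | Trajectory, segmap: SegmentMap) -> ResolvedSegments:
    """Match every configured segment to particle indices and validate.

    Raises :class:`ConfigurationError` when a range matches no particle or
    the heme selection does not match exactly four particles.
    """
    res_num = frame.residue_numbers
    res_name = frame.residue_names
    atom_name = frame.atom_names
    is_lipid = np.isin(res_name, list(segmap.lipid_residue_names))
    is_backbone = np.isin(atom_name, list(segmap.backbone))

    ranges: dict = {}
    backbone_ranges: dict = {}
    missing: list[str] = []
    for name in ("tm_helix", "linker", "globular", "c_helix", "f_helix",
                 "i_helix", "fprime_gprime"):
        rng = getattr(segmap, name)
        if rng is None:
            continue
        lo, hi = rng
        mask = (~is_lipid) & (res_num >= lo) & (res_num <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            missing.append(f"{name} ({lo}-{hi})")
            continue
        ranges[name] = idx
        backbone_ranges[name] = np.flatnonzero(mask & is_backbone)
    if missing:
        raise ConfigurationError(
            "segment ranges matched no particles: " + ", ".join(missing)
        )

    heme_idx = None
    if segmap.heme is not None:
        heme_mask = np.isin(res_name, list(segmap.heme.residue_names)) & np.isin(
            atom_name, list(segmap.heme.atom_names)
        )
        heme_idx = np.flatnonzero(heme_mask)
        if heme_idx.size != 4:
            raise ConfigurationError(
                f"heme selection must match exactly 4 particles, matched "
                f"{heme_idx.size}"
            )

    lipid_all = np.flatnonzero(is_lipid)
    lipid_head = np.flatnonzero(is_lipid & np.isin(atom_name, list(segmap.lipid_head)))
    lipid_tail = np.flatnonzero(is_lipid & np.isin(atom_name, list(segmap.lipid_tail)))
    return ResolvedSegments(
        segmap=segmap,
        ranges=ranges,
        backbone_ranges=backbone_ranges,
        heme=heme_idx,
        lipid_all=lipid_all,
        lipid_head=lipid_head,
        lipid_tail=lipid_tail,
    )
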