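"""Protein-lipid contact occupancy against a brute-force distance oracle."""

import numpy as np
import pytest

import membpos as mp
from membpos.core import ConfigurationError


def _probe_system(depths, n_frames=1, half=19.0, contact_frames=None):
    """Bilayer plus single-particle probe residues at given z depths.

    Probes sit directly above a head-group grid site so the in-plane offset
    is zero; ``contact_frames`` optionally maps probe index -> set of frames
    in which the probe is at its depth (it is moved far away otherwise).
    """
    spec = mp.SyntheticSpec(grid_n=4, half_thickness=half)
    bilayer = mp.build_bilayer(spec)
    site_xy = bilayer.positions[0, :2]  # a PO4 site
    n_probe = len(depths)
    probe_res = np.arange(50, 50 + n_probe)
    coords = np.empty((n_frames, bilayer.n_atoms + n_probe, 3))
    for f in range(n_frames):
        probes = np.column_stack(
            [np.tile(site_xy, (n_probe, 1)), np.asarray(depths, dtype=float)]
        )
        if contact_frames is not None:
            for i in range(n_probe):
                if f not in contact_frames.get(i, set(range(n_frames))):
                    probes[i, 2] = half + 100.0  # far from everything
        coords[f] = np.vstack([probes, bilayer.positions])
    traj = mp.Trajectory(
        atom_names=np.concatenate(
            [np.full(n_probe, "BB", dtype=object), bilayer.atom_names]
        ),
        residue_numbers=np.concatenate([probe_res, bilayer.residue_numbers]),
        residue_names=np.concatenate(
            [np.full(n_probe, "ALA", dtype=object), bilayer.residue_names]
        ),
        coordinates=coords,
        box=bilayer.box,
    )
    segmap = mp.SegmentMap(
        tm_helix=None, linker=None, globular=(50, 50 + n_probe - 1),
        c_helix=None, f_helix=None, i_helix=None, fprime_gprime=None,
        lipid_head=frozenset({"PO4"}),
        lipid_tail=frozenset({"C1A", "C2A"}),
    )
    return traj, segmap, probe_res


def _brute_force_occupancy(traj, segmap, cutoff):
    """O(N^2) per-frame oracle with minimal image in x and y."""
    head = set(segmap.lipid_head)
    tail = set(segmap.lipid_tail)
    lipid_names = set(segmap.lipid_residue_names)
    heme_names = set() if segmap.heme is None else set(segmap.heme.residue_names)
    box = traj.box
    n_frames = traj.n_frames
    is_lipid = np.array([rn in lipid_names for rn in traj.residue_names])
    head_idx = [i for i in range(traj.n_atoms)
                if is_lipid[i] and traj.atom_names[i] in head]
    tail_idx = [i for i in range(traj.n_atoms)
                if is_lipid[i] and traj.atom_names[i] in tail]
    protein_idx = [i for i in range(traj.n_atoms)
                   if not is_lipid[i] and traj.residue_names[i] not in heme_names]
    result = {}
    for f in range(n_frames):
        xyz = traj.coordinates[f]
        for i in protein_idx:
            res = int(traj.residue_numbers[i])
            rec = result.setdefault(res, {"head": set(), "tail": set()})
            for kind, idx in (("head", head_idx), ("tail", tail_idx)):
                for j in idx:
                    dx = xyz[i, 0] - xyz[j, 0]
                    dy = xyz[i, 1] - xyz[j, 1]
                    dz = xyz[i, 2] - xyz[j, 2]
                    if box is not None:
                        dx -= box[0] * round(dx / box[0])
                        dy -= box[1] * round(dy / box[1])
                    if dx * dx + dy * dy + dz * dz <= cutoff * cutoff:
                        rec[kind].add(f)
                        break
    rows = {}
    for res, rec in result.items():
        rows[res] = (
            100.0 * len(rec["head"]) / n_frames,
            100.0 * len(rec["tail"]) / n_frames,
        )
    return rows


class TestContactOccupancy:
    def test_always_in_contact_is_100(self):
        # probe 3 A above a head particle in all 10 frames
        traj, segmap, probes = _probe_system([19.0 + 3.0], n_frames=10)
        table = mp.contact_occupancy(traj, segmap)
        row = table[table.residue_number == probes[0]].iloc[0]
        assert row.head_pct == pytest.approx(100.0)

    def test_partial_contact_fraction(self):
        traj, segmap, probes = _probe_system(
            [19.0 + 3.0], n_frames=10, contact_frames={0: {0, 1, 2, 3}}
        )
        table = mp.contact_occupancy(traj, segmap)
        row = table[table.residue_number == probes[0]].iloc[0]
        assert row.head_pct == pytest.approx(40.0)

    def test_depth_thresholds_at_head_plane(self):
        # at the head plane: contact; 6 A above it: none at 5 A cutoff
        traj, segmap, probes = _probe_system([19.0, 19.0 + 6.0], n_frames=3)
        table = mp.contact_occupancy(traj, segmap)
        at_plane = table[table.residue_number == probes[0]].iloc[0]
        above = table[table.residue_number == probes[1]].iloc[0]
        assert at_plane.head_pct == pytest.approx(100.0)
        assert above.head_pct == pytest.approx(0.0)
        assert above.tail_pct == pytest.approx(0.0)

    def test_exact_agreement_with_brute_force_oracle(self, class_a_system):
        traj, _, segmap = class_a_system
        table = mp.contact_occupancy(traj, segmap)
        oracle = _brute_force_occupancy(traj, segmap, cutoff=5.0)
        got = {
            int(r.residue_number): (r.head_pct, r.tail_pct)
            for r in table.itertuples()
        }
        assert set(got) == set(oracle)
        for res in oracle:
            assert got[res] == pytest.approx(oracle[res], abs=0.0), res

    def test_occupancy_monotone_in_cutoff(self, class_a_system):
        traj, _, segmap = class_a_system
        small = mp.contact_occupancy(traj, segmap, cutoff=4.0)
        large = mp.contact_occupancy(traj, segmap, cutoff=7.0)
        merged = small.merge(large, on="residue_number", suffixes=("_s", "_l"))
        assert (merged.head_pct_l >= merged.head_pct_s).all()
        assert (merged.tail_pct_l >= merged.tail_pct_s).all()

    def test_minimal_image_in_plane(self):
        # head at x=44 in a 48 A box, probe at x=1: direct separation 43 A,
        # wrapped separation 5 A -> the contact exists only via minimal image
        box = np.array([48.0, 48.0, 120.0])
        coords = np.array(
            [[[1.0, 6.0, 19.0],     # probe residue 50
              [44.0, 6.0, 19.0],    # PO4 head
              [44.0, 30.0, 7.0]]]   # C1A tail, far from the probe
        )
        traj = mp.Trajectory(
            atom_names=np.array(["BB", "PO4", "C1A"], dtype=object),
            residue_numbers=np.array([50, 1001, 1001]),
            residue_names=np.array(["ALA", "POP", "POP"], dtype=object),
            coordinates=coords,
            box=box,
        )
        segmap = mp.SegmentMap(
            tm_helix=None, linker=None, globular=(50, 50),
            c_helix=None, f_helix=None, i_helix=None, fprime_gprime=None,
            lipid_head=frozenset({"PO4"}), lipid_tail=frozenset({"C1A"}),
        )
        table = mp.contact_occupancy(traj, segmap)
        row = table[table.residue_number == 50].iloc[0]
        assert row.head_pct == 100.0
        assert row.tail_pct == 0.0
        # without the box the direct distance exceeds the cutoff
        no_box = mp.Trajectory(
            atom_names=traj.atom_names, residue_numbers=traj.residue_numbers,
            residue_names=traj.residue_names, coordinates=coords, box=None,
        )
        table = mp.contact_occupancy(no_box, segmap)
        assert table[table.residue_number == 50].iloc[0].head_pct == 0.0

    def test_overlapping_sets_rejected_at_config(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            mp.SegmentMap(
                tm_helix=None, linker=None, globular=(50, 50),
                c_helix=None, f_helix=None, i_helix=None, fprime_gprime=None,
                lipid_head=frozenset({"PO4", "C1A"}),
                lipid_tail=frozenset({"C1A"}),
            )


class TestOccupancyReport:
    def test_annotation_attached_to_overlapping_range(self, class_a_system):
        traj, _, segmap = class_a_system
        table = mp.contact_occupancy(traj, segmap)
        report = mp.occupancy_report(table, annotations={"TM": (3, 21)})
        tm_rows = report[report.annotations == "TM"]
        assert (tm_rows.residue_number.between(3, 21)).all()
        assert len(tm_rows) > 0

    def test_zero_occupancy_rows_excluded(self, class_a_system):
        traj, _, segmap = class_a_system
        table = mp.contact_occupancy(traj, segmap)
        report = mp.occupancy_report(table)
        assert ((report.head_pct > 0) | (report.tail_pct > 0)).all()
        assert report.residue_number.is_monotonic_increasing

    def test_without_annotations_passes_through_unlabeled(self, class_a_system):
        traj, _, segmap = class_a_system
        report = mp.occupancy_report(mp.contact_occupancy(traj, segmap))
        assert (report.annotations == "").all()
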