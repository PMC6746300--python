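"""Idealized chemosensory-array lattice builder.

The cytoplasmic baseplate of the bacterial chemosensory array is modelled as a
honeycomb of receptor trimers-of-dimers (TODs) whose hexagon centers form a
triangular lattice with repeat ``lattice_constant`` (12 nm in vivo).  Each
hexagon center hosts a six-membered ring of coupling proteins: two thirds of
the rings alternate three CheA-P5 domains with three CheW monomers
("kinase-filled"), the remaining third contain six CheW ("CheW-only").  CheA
dimers bridge adjacent kinase-filled rings, one P5 domain in each.  The
resulting unit cell (a = lattice_constant * sqrt(3)) holds six TODs, three
CheA dimers and twelve CheW monomers, organized as three core-signaling units
(2 TOD + 1 CheA dimer + 4 CheW each).

Conventions: the array plane is XY, the receptor axis +Z, ring centers at
z = 0.  The hexagon face containing the origin is CheW-only; placements are
generated on a torus (periodic wrap) so per-cell counts are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, RangeError, ValidationError

__all__ = [
    "ComponentKind",
    "RingType",
    "Motif",
    "LatticeSpec",
    "SitePlacement",
    "RingMember",
    "RingAssignment",
    "BoxParameters",
    "Stoichiometry",
    "LatticeModel",
    "honeycomb_sites",
    "assign_rings_and_components",
    "build_lattice",
    "unit_cell_box",
    "motif_extract",
    "stoichiometry_report",
    "instantiate_coordinates",
    "CoordinateSet",
]


class ComponentKind(str, Enum):
    TOD = "TOD"
    CheA_dimer = "CheA_dimer"
    CheW = "CheW"
    P5_domain = "P5_domain"


class RingType(str, Enum):
    kinase_filled = "kinase_filled"
    chew_only = "chew_only"


class Motif(str, Enum):
    core_unit = "core_unit"
    trimer = "trimer"
    hexamer = "hexamer"
    unit_cell = "unit_cell"


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the idealized array.

    lattice_constant : hexagon-center (ring-center) repeat, Angstrom.
    n_cells          : supercell repeats along the two in-plane cell vectors.
    box_height       : c axis of the simulation box, Angstrom.
    tod_z_offset     : z offset of TOD sites relative to the ring plane.
    ring_radius      : radius at which ring members (P5/CheW) are placed.
    periodic         : wrap placements onto the supercell torus.
    """

    lattice_constant: float = 120.0
    n_cells: tuple[int, int] = (1, 1)
    box_height: float = 334.0
    tod_z_offset: float = 0.0
    ring_radius: float = 30.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if not self.lattice_constant > 0:
            raise ValidationError(
                f"lattice_constant must be positive, got {self.lattice_constant}"
            )
        n1, n2 = self.n_cells
        if n1 < 1 or n2 < 1:
            raise ValidationError(f"n_cells must be >= (1, 1), got {self.n_cells}")
        if not self.box_height > 0:
            raise ValidationError("box_height must be positive")


@dataclass
class SitePlacement:
    kind: ComponentKind
    position: np.ndarray  # (3,) Angstrom
    orientation: np.ndarray  # unit quaternion, scalar-last (x, y, z, w)
    cell_index: tuple[int, int]
    ring_id: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValidationError("orientation quaternion must have unit norm")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


@dataclass
class RingMember:
    slot: int  # 0..5 ordered by angle around the ring center
    kind: str  # "P5" or "CheW"
    source_index: int  # placement index of the CheA dimer or CheW monomer
    tod_index: int  # placement index of the TOD whose receptor dimer binds here
    receptor_dimer: int  # which of the TOD's three dimers (0..2)


@dataclass
class RingAssignment:
    ring_id: str
    center: np.ndarray
    ring_type: RingType
    members: list[RingMember]
    interface_labels: list[str]  # per adjacent slot pair (slot i, slot i+1 mod 6)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if len(self.members) != 6:
            raise ValidationError("a ring has exactly 6 members")


@dataclass(frozen=True)
class BoxParameters:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 120.0


@dataclass
class Stoichiometry:
    counts: dict[str, int]

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    def scaled(self, factor: int) -> "Stoichiometry":
        return Stoichiometry({k: v * factor for k, v in self.counts.items()})


CORE_UNIT_STOICHIOMETRY = Stoichiometry({"TOD": 2, "CheA_dimer": 1, "CheW": 4})


@dataclass
class LatticeModel:
    spec: LatticeSpec
    placements: list[SitePlacement]
    rings: list[RingAssignment]
    cell_vectors: np.ndarray  # (2, 3)
    # core_units: per CheA dimer placement index -> member placement indices
    core_units: dict[int, dict[str, list[int]]] = field(default_factory=dict)

    def placements_of(self, kind: ComponentKind) -> list[int]:
        return [i for i, p in enumerate(self.placements) if p.kind == kind]

    def to_json(self) -> str:
        obj = {
            "spec": {
                "lattice_constant": self.spec.lattice_constant,
                "n_cells": list(self.spec.n_cells),
                "box_height": self.spec.box_height,
            },
            "cell_vectors": self.cell_vectors.tolist(),
            "placements": [
                {
                    "kind": p.kind.value,
                    "position": p.position.tolist(),
                    "orientation": p.orientation.tolist(),
                    "cell_index": list(p.cell_index),
                    "ring_id": p.ring_id,
                    "label": p.label,
                }
                for p in self.placements
            ],
            "rings": [
                {
                    "ring_id": r.ring_id,
                    "center": r.center.tolist(),
                    "ring_type": r.ring_type.value,
                    "members": [
                        {
                            "slot": m.slot,
                            "kind": m.kind,
                            "source_index": m.source_index,
                            "tod_index": m.tod_index,
                            "receptor_dimer": m.receptor_dimer,
                        }
                        for m in r.members
                    ],
                    "interface_labels": r.interface_labels,
                }
                for r in self.rings
            ],
            "stoichiometry": stoichiometry_report(self).counts,
        }
        return json.dumps(obj, indent=2)

    def placement_table(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.placements):
            rows.append(
                {
                    "index": i,
                    "kind": p.kind.value,
                    "x": p.position[0],
                    "y": p.position[1],
                    "z": p.position[2],
                    "qx": p.orientation[0],
                    "qy": p.orientation[1],
                    "qz": p.orientation[2],
                    "qw": p.orientation[3],
                    "cell_i": p.cell_index[0],
                    "cell_j": p.cell_index[1],
                    "ring_id": p.ring_id or "",
                    "label": p.label,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal face/vertex topology
#
# Ring centers form a triangular lattice with primitive vectors
#   t1 = L (1, 0),  t2 = L (1/2, sqrt(3)/2).
# Face (i, j) = i t1 + j t2; its color (i - j) mod 3 three-colors the lattice
# (0 = CheW-only, 1/2 = the two kinase-filled sublattices).  The supercell
# vectors A1 = t1 + t2, A2 = -2 t1 + t2 have |A| = L sqrt(3), gamma = 120 deg,
# and hold three faces (one of each color) and six honeycomb vertices (TODs).
# Faces are keyed by (3u mod 3 n1, 3v mod 3 n2) with u = (i+2j)/3, v = (j-i)/3
# the supercell fractional coordinates; TODs by (face key, up/down triangle).
# ---------------------------------------------------------------------------

_W, _K1, _K2 = 0, 1, 2
# deltas from a K1 face to its three K2 neighbors
_K1_TO_K2 = ((1, 0), (0, -1), (-1, 1))
_NEIGHBOR_DELTAS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
# base faces of cell (0, 0): (i, j) and color
_BASE_FACES = (((0, 0), _W), ((0, 1), _K2), ((-1, 1), _K1))


class _Topology:
    def __init__(self, spec: LatticeSpec):
        self.spec = spec
        L = spec.lattice_constant
        self.t1 = np.array([L, 0.0, 0.0])
        self.t2 = np.array([L / 2.0, L * np.sqrt(3) / 2.0, 0.0])
        self.A1 = self.t1 + self.t2
        self.A2 = -2.0 * self.t1 + self.t2
        self.n1, self.n2 = spec.n_cells

    def face_key(self, ij: tuple[int, int]) -> tuple[int, int]:
        i, j = ij
        return ((i + 2 * j) % (3 * self.n1), (j - i) % (3 * self.n2))

    def color(self, ij: tuple[int, int]) -> int:
        return (ij[0] - ij[1]) % 3

    def faces(self):
        """Yield (ij, color, cell) for every face of the supercell."""
        for m in range(self.n1):
            for n in range(self.n2):
                for (bi, bj), color in _BASE_FACES:
                    ij = (bi + m - 2 * n, bj + m + n)
                    yield ij, color, (m, n)

    def face_position(self, ij: tuple[int, int]) -> np.ndarray:
        return ij[0] * self.t1 + ij[1] * self.t2

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap a position into the supercell parallelogram (XY only)."""
        M = np.array([self.A1[:2] * self.n1, self.A2[:2] * self.n2]).T
        frac = np.linalg.solve(M, pos[:2])
        frac -= np.floor(frac + 1e-9)
        out = pos.copy()
        out[:2] = M @ frac
        return out

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image in-plane displacement on the supercell torus."""
        best = d
        bn = np.dot(d[:2], d[:2])
        for s1 in (-1, 0, 1):
            for s2 in (-1, 0, 1):
                cand = d - s1 * self.A1 * self.n1 - s2 * self.A2 * self.n2
                n = np.dot(cand[:2], cand[:2])
                if n < bn - 1e-9:
                    best, bn = cand, n
        return best


def _quat_about_z(angle: float) -> np.ndarray:
    return Rotation.from_euler("z", angle).as_quat()


def honeycomb_sites(spec: LatticeSpec) -> list[SitePlacement]:
    """Place receptor TODs on the honeycomb vertices of the array.

    TODs sit at the centers of the up/down triangles of the ring-center
    lattice, i.e. the vertices of the hexagons; nearest-neighbor spacing is
    ``lattice_constant / sqrt(3)``, six TODs per unit cell.
    """
    topo = _Topology(spec)
    up = (topo.t1 + topo.t2) / 3.0
    placements: list[SitePlacement] = []
    for ij, _color, cell in topo.faces():
        base = topo.face_position(ij)
        for tag, offset in (("u", up), ("d", 2.0 * up)):
            pos = base + offset
            pos = pos + np.array([0.0, 0.0, spec.tod_z_offset])
            if spec.periodic:
                pos = topo.wrap(pos)
            # orientation: first incident-ring direction defines the x axis
            incident = _incident_faces(ij, tag)
            d = topo.min_image(topo.face_position(incident[0]) - pos)
            angle = float(np.arctan2(d[1], d[0]))
            k0, k1 = topo.face_key(ij)
            placements.append(
                SitePlacement(
                    kind=ComponentKind.TOD,
                    position=pos,
                    orientation=_quat_about_z(angle),
                    cell_index=cell,
                    label=f"TOD:{k0}_{k1}:{tag}",
                )
            )
    return placements


def _incident_faces(ij: tuple[int, int], tag: str) -> list[tuple[int, int]]:
    """The three ring faces touching a honeycomb vertex (one per color)."""
    i, j = ij
    if tag == "u":
        return [(i, j), (i + 1, j), (i, j + 1)]
    return [(i + 1, j), (i, j + 1), (i + 1, j + 1)]


def _edge_endpoints(f: tuple[int, int], delta: tuple[int, int]):
    """The two honeycomb vertices (TODs) flanking the face adjacency f, f+delta."""
    i, j = f
    if delta == (1, 0):
        return ((i, j), "u"), ((i, j - 1), "d")
    if delta == (0, -1):
        return ((i, j - 1), "u"), ((i - 1, j - 1), "d")
    if delta == (-1, 1):
        return ((i - 1, j), "u"), ((i - 1, j), "d")
    raise ValidationError(f"not a K1->K2 adjacency delta: {delta}")


def assign_rings_and_components(
    tod_sites: Sequence[SitePlacement], spec: LatticeSpec
) -> LatticeModel:
    """Three-color the ring faces, place CheA dimers and CheW, build rings.

    Faces are colored W / K1 / K2; the face containing the origin is CheW-only
    (W).  A CheA dimer is placed at the midpoint of every K1-K2 face
    adjacency with its two P5 domains assigned to the two flanking kinase
    rings; remaining ring slots are CheW.  Each TOD contributes one receptor
    dimer to each of its three incident rings.
    """
    topo = _Topology(spec)
    n_expected = 6 * spec.n_cells[0] * spec.n_cells[1]
    if len(tod_sites) != n_expected:
        raise ValidationError(
            f"expected {n_expected} TOD sites for {spec.n_cells}, got {len(tod_sites)}"
        )

    placements: list[SitePlacement] = list(tod_sites)
    tod_index: dict[tuple, int] = {}
    for idx, p in enumerate(tod_sites):
        try:
            _, key, tag = p.label.split(":")
            k0, k1 = (int(x) for x in key.split("_"))
        except ValueError as exc:
            raise ValidationError(
                "tod_sites must come from honeycomb_sites (bad label)"
            ) from exc
        tod_index[((k0, k1), tag)] = idx

    faces = {}  # key -> (ij, color, cell)
    for ij, color, cell in topo.faces():
        faces[topo.face_key(ij)] = (ij, color, cell)

    # --- CheA dimers on K1-K2 adjacencies -------------------------------
    dimer_index: dict[tuple, int] = {}  # (K1 key, delta) -> placement idx
    dimer_edges: dict[int, tuple] = {}  # placement idx -> (K1 key, K2 key, delta)
    vertex_dimer: dict[tuple, int] = {}  # (face key, tag) -> dimer placement idx
    for key, (ij, color, cell) in faces.items():
        if color != _K1:
            continue
        for delta in _K1_TO_K2:
            gij = (ij[0] + delta[0], ij[1] + delta[1])
            mid = topo.face_position(ij) + (
                topo.face_position(gij) - topo.face_position(ij)
            ) / 2.0
            if spec.periodic:
                mid = topo.wrap(mid)
            d = topo.min_image(topo.face_position(gij) - topo.face_position(ij))
            angle = float(np.arctan2(d[1], d[0]))
            idx = len(placements)
            placements.append(
                SitePlacement(
                    kind=ComponentKind.CheA_dimer,
                    position=mid,
                    orientation=_quat_about_z(angle),
                    cell_index=cell,
                    label=f"CheA:{key}:{delta}",
                )
            )
            dimer_index[(key, delta)] = idx
            dimer_edges[idx] = (key, topo.face_key(gij), delta)
            for vij, vtag in _edge_endpoints(ij, delta):
                vkey = (topo.face_key(vij), vtag)
                if vkey in vertex_dimer:
                    raise ValidationError("TOD assigned to two CheA dimers")
                vertex_dimer[vkey] = idx

    # --- rings -----------------------------------------------------------
    rings: list[RingAssignment] = []
    ring_of_face: dict[tuple, int] = {}
    chew_of_tod: dict[int, int] = {}  # TOD placement idx -> CheW-only-ring CheW idx
    kinase_chew_of_dimer: dict[int, list[int]] = {i: [] for i in dimer_edges}

    for key, (ij, color, cell) in sorted(faces.items()):
        center = topo.face_position(ij)
        if spec.periodic:
            center = topo.wrap(center)
        ring_type = RingType.chew_only if color == _W else RingType.kinase_filled
        ring_id = f"ring:{key[0]}:{key[1]}"

        # the six surrounding TODs, ordered by angle about the center
        surround = []
        for vij, vtag, dimer_slot in _surrounding_vertices(ij):
            t_idx = tod_index[(topo.face_key(vij), vtag)]
            disp = topo.min_image(placements[t_idx].position - center)
            ang = float(np.arctan2(disp[1], disp[0])) % (2 * np.pi)
            surround.append((ang, t_idx, dimer_slot))
        surround.sort()
        if len({t for _, t, _ in surround}) != 6 and min(spec.n_cells) >= 2:
            raise ValidationError("ring does not see six distinct TODs")

        members: list[RingMember] = []
        if ring_type == RingType.kinase_filled:
            # the three adjacent dimers (toward same-parity kinase neighbors)
            deltas = _K1_TO_K2 if color == _K1 else tuple(
                (-d[0], -d[1]) for d in _K1_TO_K2
            )
            dimer_dirs = []
            for delta in deltas:
                if color == _K1:
                    didx = dimer_index[(key, delta)]
                else:
                    nij = (ij[0] + delta[0], ij[1] + delta[1])
                    didx = dimer_index[(topo.face_key(nij), (-delta[0], -delta[1]))]
                d = topo.min_image(placements[didx].position - center)
                ang = float(np.arctan2(d[1], d[0])) % (2 * np.pi)
                dimer_dirs.append((ang, didx))
            dimer_dirs.sort()
            # P5 slot: the surrounding-TOD slot just counterclockwise of each
            # dimer direction; CheW fills the rest.
            p5_slots = {}
            for ang, didx in dimer_dirs:
                diffs = [(((ang - s[0]) % (2 * np.pi)), si) for si, s in enumerate(surround)]
                slot = min(diffs)[1]
                p5_slots[slot] = didx
            for slot, (ang, t_idx, dimer_slot) in enumerate(surround):
                if slot in p5_slots:
                    members.append(
                        RingMember(slot, "P5", p5_slots[slot], t_idx, dimer_slot)
                    )
                else:
                    w_idx = len(placements)
                    placements.append(
                        SitePlacement(
                            kind=ComponentKind.CheW,
                            position=center
                            + spec.ring_radius
                            * np.array([np.cos(ang), np.sin(ang), 0.0]),
                            orientation=_quat_about_z(ang),
                            cell_index=cell,
                            ring_id=ring_id,
                            label=f"CheW:{key}:{slot}",
                        )
                    )
                    members.append(RingMember(slot, "CheW", w_idx, t_idx, dimer_slot))
            if sorted(p5_slots) not in ([0, 2, 4], [1, 3, 5]):
                raise ValidationError("P5/CheW alternation failed")
        else:
            for slot, (ang, t_idx, dimer_slot) in enumerate(surround):
                w_idx = len(placements)
                placements.append(
                    SitePlacement(
                        kind=ComponentKind.CheW,
                        position=center
                        + spec.ring_radius * np.array([np.cos(ang), np.sin(ang), 0.0]),
                        orientation=_quat_about_z(ang),
                        cell_index=cell,
                        ring_id=ring_id,
                        label=f"CheW:{key}:{slot}",
                    )
                )
                members.append(RingMember(slot, "CheW", w_idx, t_idx, dimer_slot))
                chew_of_tod[t_idx] = w_idx

        interface_labels = [
            "interface_1" if s % 2 == 0 else "interface_2" for s in range(6)
        ]
        if ring_type == RingType.kinase_filled and 1 in {
            m.slot for m in members if m.kind == "P5"
        }:
            interface_labels = interface_labels[1:] + interface_labels[:1]
        rings.append(
            RingAssignment(ring_id, center, ring_type, members, interface_labels)
        )
        ring_of_face[key] = len(rings) - 1
        if ring_type == RingType.kinase_filled:
            for m in members:
                if m.kind == "CheW":
                    # CheW clockwise-adjacent to a P5 belongs to that dimer's core unit
                    prev = (m.slot - 1) % 6
                    p5 = next(x for x in members if x.slot == prev)
                    kinase_chew_of_dimer[p5.source_index].append(m.source_index)

    # --- core units ------------------------------------------------------
    core_units: dict[int, dict[str, list[int]]] = {}
    for didx, (k1key, k2key, delta) in dimer_edges.items():
        k1ij = faces[k1key][0]
        tods = [
            tod_index[(topo.face_key(vij), vtag)]
            for vij, vtag in _edge_endpoints(k1ij, delta)
        ]
        chews = list(kinase_chew_of_dimer[didx]) + [chew_of_tod[t] for t in tods]
        core_units[didx] = {"TOD": tods, "CheW": chews}

    model = LatticeModel(
        spec=spec,
        placements=placements,
        rings=rings,
        cell_vectors=np.array([topo.A1, topo.A2]),
        core_units=core_units,
    )
    return model


def _surrounding_vertices(ij: tuple[int, int]):
    """The six honeycomb vertices around face ij, with per-TOD dimer slot.

    The dimer slot is the index of face ij among the vertex's three incident
    faces: the TOD's receptor dimer pointing at this ring.
    """
    i, j = ij
    out = []
    # up/down triangle anchors whose triangles contain face ij
    for base, tag in (
        ((i, j), "u"),
        ((i - 1, j), "u"),
        ((i, j - 1), "u"),
        ((i, j - 1), "d"),
        ((i - 1, j - 1), "d"),
        ((i - 1, j), "d"),
    ):
        incident = _incident_faces(base, tag)
        slot = incident.index((i, j))
        out.append((base, tag, slot))
    return out


def build_lattice(spec: LatticeSpec) -> LatticeModel:
    """Convenience: honeycomb_sites + assign_rings_and_components."""
    return assign_rings_and_components(honeycomb_sites(spec), spec)


def unit_cell_box(spec: LatticeSpec) -> BoxParameters:
    """Hexagonal unit-cell box: a = b = lattice_constant * sqrt(3), c = height."""
    a = spec.lattice_constant * np.sqrt(3.0)
    return BoxParameters(a=a, b=a, c=spec.box_height)


def stoichiometry_report(model: LatticeModel) -> Stoichiometry:
    counts: dict[str, int] = {k.value: 0 for k in ComponentKind}
    for p in model.placements:
        counts[p.kind.value] += 1
    counts["P5_domain"] = 2 * counts["CheA_dimer"]
    counts["kinase_filled_rings"] = sum(
        1 for r in model.rings if r.ring_type == RingType.kinase_filled
    )
    counts["chew_only_rings"] = sum(
        1 for r in model.rings if r.ring_type == RingType.chew_only
    )
    return Stoichiometry(counts)


def _submodel(model: LatticeModel, placement_idx: list[int]) -> LatticeModel:
    idx = sorted(set(placement_idx))
    old2new = {o: n for n, o in enumerate(idx)}
    placements = [model.placements[i] for i in idx]
    keep = set(idx)
    rings = []
    for r in model.rings:
        if all(m.source_index in keep and m.tod_index in keep for m in r.members):
            rings.append(
                RingAssignment(
                    r.ring_id,
                    r.center,
                    r.ring_type,
                    [
                        RingMember(
                            m.slot,
                            m.kind,
                            old2new[m.source_index],
                            old2new[m.tod_index],
                            m.receptor_dimer,
                        )
                        for m in r.members
                    ],
                    list(r.interface_labels),
                )
            )
    core_units = {
        old2new[d]: {
            "TOD": [old2new[t] for t in cu["TOD"]],
            "CheW": [old2new[w] for w in cu["CheW"]],
        }
        for d, cu in model.core_units.items()
        if d in keep and all(t in keep for t in cu["TOD"] + cu["CheW"])
    }
    return LatticeModel(model.spec, placements, rings, model.cell_vectors, core_units)


def motif_extract(model: LatticeModel, motif: Motif | str) -> LatticeModel:
    """Extract the minimal sub-model for a motif.

    core_unit : one CheA dimer, its two flanking TODs and four CheW.
    trimer    : the three core units around one kinase-filled ring.
    hexamer   : the six core units around one CheW-only ring.
    unit_cell : three coupled core units (one unit cell's worth).
    """
    motif = Motif(motif)
    if not model.core_units:
        raise RangeError("model carries no core-unit topology")

    def unit_members(didx: int) -> list[int]:
        cu = model.core_units[didx]
        return [didx] + cu["TOD"] + cu["CheW"]

    if motif == Motif.core_unit:
        d0 = min(model.core_units)
        return _submodel(model, unit_members(d0))

    if motif in (Motif.trimer, Motif.unit_cell):
        ring = next(
            r for r in model.rings if r.ring_type == RingType.kinase_filled
        )
        dimers = sorted({m.source_index for m in ring.members if m.kind == "P5"})
        if len(dimers) != 3:
            raise RangeError("kinase ring does not trace to three distinct dimers")
        out: list[int] = []
        for d in dimers:
            out.extend(unit_members(d))
        if len(set(out)) != len(out):
            raise RangeError("motif not containable: core units overlap (wrapping)")
        return _submodel(model, out)

    # hexamer
    ring = next(r for r in model.rings if r.ring_type == RingType.chew_only)
    tod_dimer: dict[int, int] = {}
    for d, cu in model.core_units.items():
        for t in cu["TOD"]:
            tod_dimer[t] = d
    dimers = sorted({tod_dimer[m.tod_index] for m in ring.members})
    if len(dimers) != 6:
        raise RangeError(
            "hexamer not containable in this supercell (needs >= 2x2 cells)"
        )
    out = []
    for d in dimers:
        out.extend(unit_members(d))
    if len(set(out)) != len(out):
        raise RangeError("motif not containable: core units overlap (wrapping)")
    return _submodel(model, out)


# ---------------------------------------------------------------------------
# coordinate instantiation
# ---------------------------------------------------------------------------


@dataclass
class CoordinateSet:
    """Flat coordinate container writable as PDB (one chain per placement)."""

    coords: np.ndarray  # (N, 3)
    atoms: pd.DataFrame  # chain_id, res_id, atom_name, element, placement_index

    def write_pdb(self, path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = len(self.coords)
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(self.coords, dtype=np.float32)
        arr.chain_id = self.atoms["chain_id"].to_numpy(dtype="U4")
        arr.res_id = self.atoms["res_id"].to_numpy(dtype=int)
        arr.res_name = np.full(n, "GLY", dtype="U5")
        arr.atom_name = self.atoms["atom_name"].to_numpy(dtype="U6")
        arr.element = self.atoms["element"].to_numpy(dtype="U2")
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    @classmethod
    def read_pdb(cls, path) -> "CoordinateSet":
        import biotite.structure.io.pdb as pdb

        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        atoms = pd.DataFrame(
            {
                "chain_id": arr.chain_id,
                "res_id": arr.res_id,
                "atom_name": arr.atom_name,
                "element": arr.element,
            }
        )
        return cls(coords=np.asarray(arr.coord, dtype=float), atoms=atoms)


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def instantiate_coordinates(
    model: LatticeModel, templates: Mapping[ComponentKind | str, np.ndarray]
) -> CoordinateSet:
    """Rigidly place a coordinate template at every placement.

    Each template is centered on its centroid, rotated by the placement
    orientation and translated to the placement position.  Chain identifiers
    cycle through an alphanumeric alphabet; ``placement_index`` in the atom
    table traces every atom back to its placement.
    """
    tmpl = {ComponentKind(k): np.asarray(v, dtype=float) for k, v in templates.items()}
    needed = {p.kind for p in model.placements}
    missing = needed - set(tmpl)
    if missing:
        raise ConfigurationError(
            f"missing templates for: {sorted(k.value for k in missing)}"
        )
    coords_parts = []
    rows = []
    for idx, p in enumerate(model.placements):
        t = tmpl[p.kind]
        if t.ndim != 2 or t.shape[1] != 3 or len(t) == 0:
            raise ConfigurationError(f"template for {p.kind.value} must be (n, 3)")
        centered = t - t.mean(axis=0)
        placed = p.rotation.apply(centered) + p.position
        coords_parts.append(placed)
        chain = _CHAIN_ALPHABET[idx % len(_CHAIN_ALPHABET)]
        for a in range(len(t)):
            rows.append(
                {
                    "chain_id": chain,
                    "res_id": a + 1,
                    "atom_name": "CA",
                    "element": "C",
                    "placement_index": idx,
                }
            )
    return CoordinateSet(
        coords=np.vstack(coords_parts), atoms=pd.DataFrame(rows)
    )
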