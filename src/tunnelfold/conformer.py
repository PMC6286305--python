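"""Idealized peptide conformer construction from internal coordinates.

Builds coarse 3D models of peptides in a labelled conformational state
(``helical`` or ``extended``): full backbone (N, CA, C, O) propagated by
torsion-driven chain extension plus one pseudo side-chain sphere per residue,
sized from a residue volume table.  The representation is deliberately
minimal — just enough geometry for surface-area burial calculations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import load_defaults

__all__ = [
    "ResidueSpec",
    "PeptideSequence",
    "BackboneGeometry",
    "Conformer",
    "build_conformer",
    "place_next_atom",
    "measure_dihedral",
    "measure_rise",
    "hydrophobic_mask",
    "fit_chain_axis",
]

CANONICAL_CODES = "ACDEFGHIKLMNPQRSTVWY"

STATES = ("helical", "extended")

BACKBONE_ROLES = ("N", "CA", "C", "O", "CB")


class InputError(ValueError):
    """Invalid user input (unknown residue, bad state label, ...)."""


class GeometryError(ValueError):
    """Chain too short or a degenerate local frame."""


@dataclass(frozen=True)
class ResidueSpec:
    """One amino acid: code, hydrophobicity class, pseudo side-chain radius."""

    code: str
    hydrophobic: bool
    sidechain_radius: float  # Å
    mass: float  # Da

    def __post_init__(self):
        if self.code not in CANONICAL_CODES:
            raise InputError(f"unknown residue code {self.code!r}")
        if self.sidechain_radius <= 0:
            raise InputError("sidechain_radius must be positive")


def _residue_table() -> dict[str, ResidueSpec]:
    table = {}
    for code, row in load_defaults()["residues"].items():
        table[code] = ResidueSpec(
            code=code,
            hydrophobic=bool(row["hydrophobic"]),
            sidechain_radius=float(row["sidechain_radius"]),
            mass=float(row["mass"]),
        )
    return table


RESIDUE_TABLE = _residue_table()


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide with an annotated span that is helical in the native fold.

    ``helical_region`` is a 1-based inclusive ``(start, end)`` span; indexing
    is 1-based N→C throughout the package.
    """

    id: str
    residues: tuple[ResidueSpec, ...]
    helical_region: tuple[int, int]

    def __post_init__(self):
        n = len(self.residues)
        if n < 1:
            raise InputError("empty sequence")
        start, end = self.helical_region
        if not (1 <= start <= end <= n):
            raise InputError(
                f"helical_region {self.helical_region} out of range for length {n}"
            )

    @classmethod
    def from_string(
        cls,
        seq: str,
        id: str = "peptide",
        helical_region: tuple[int, int] | None = None,
    ) -> "PeptideSequence":
        seq = seq.strip().upper()
        try:
            residues = tuple(RESIDUE_TABLE[c] for c in seq)
        except KeyError as exc:
            raise InputError(f"unknown residue code {exc.args[0]!r} in sequence") from exc
        if helical_region is None:
            helical_region = (1, len(seq))
        return cls(id=id, residues=residues, helical_region=helical_region)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(r.code for r in self.residues)


@dataclass(frozen=True)
class BackboneGeometry:
    """Bond lengths (Å), bond angles (deg) and per-state dihedrals (deg)."""

    bond_lengths: dict[str, float]
    bond_angles: dict[str, float]
    dihedrals: dict[str, dict[str, float]]
    cb_offset: float = 2.0

    def __post_init__(self):
        for name, val in self.bond_lengths.items():
            if not (1.0 < val < 2.0):
                raise GeometryError(f"bond length {name}={val} outside (1, 2) Å")
        for state, dih in self.dihedrals.items():
            if abs(abs(dih.get("omega", 180.0)) - 180.0) > 1e-9:
                raise GeometryError(f"omega must be 180° (state {state})")

    @classmethod
    def default(cls) -> "BackboneGeometry":
        geo = load_defaults()["backbone_geometry"]
        return cls(
            bond_lengths=geo["bond_lengths"],
            bond_angles=geo["bond_angles"],
            dihedrals=geo["dihedrals"],
            cb_offset=geo["cb_offset"],
        )


@dataclass
class Conformer:
    """Coarse atomic model of a peptide in one conformational state."""

    peptide_id: str
    state: str
    residue_index: np.ndarray  # (n_atoms,), 1-based
    roles: np.ndarray  # (n_atoms,), unicode among BACKBONE_ROLES
    coords: np.ndarray  # (n_atoms, 3), Å
    radii: np.ndarray  # (n_atoms,), Å
    sequence: PeptideSequence | None = field(default=None, repr=False)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.roles == "CA"]

    def select(self, mask: np.ndarray) -> "Conformer":
        return Conformer(
            self.peptide_id, self.state, self.residue_index[mask],
            self.roles[mask], self.coords[mask], self.radii[mask], self.sequence,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        out = Conformer(
            self.peptide_id, self.state, self.residue_index.copy(), self.roles.copy(),
            self.coords @ rotation.T + translation, self.radii.copy(), self.sequence,
        )
        return out


def place_next_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Place atom D from frame atoms A-B-C given bond |CD|, angle B-C-D and
    torsion A-B-C-D (degrees).  Standard internal-coordinate (NeRF) step."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-12:
        raise GeometryError("coincident frame atoms")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear frame atoms: torsion undefined")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.cos(tor) * math.sin(ang),
        bond * math.sin(tor) * math.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees) defined by four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def build_conformer(
    seq: PeptideSequence,
    state: str,
    geom: BackboneGeometry | None = None,
) -> Conformer:
    """Build an idealized conformer of ``seq`` in the given state.

    In the ``helical`` state the annotated helical region gets ideal α-helix
    dihedrals and everything outside it is built extended; the ``extended``
    state is extended throughout.
    """
    if state not in STATES:
        raise InputError(f"state must be one of {STATES}, got {state!r}")
    if len(seq) < 2:
        raise GeometryError("need at least 2 residues to build a chain")
    geom = geom or BackboneGeometry.default()
    if state not in geom.dihedrals:
        raise GeometryError(f"geometry table lacks dihedrals for state {state!r}")

    bl, ba = geom.bond_lengths, geom.bond_angles
    start, end = seq.helical_region

    def dihedrals_for(res_i: int) -> tuple[float, float, float]:
        if state == "helical" and start <= res_i <= end:
            d = geom.dihedrals["helical"]
        else:
            d = geom.dihedrals["extended"]
        return d["phi"], d["psi"], d.get("omega", 180.0)

    # seed residue: N at origin, CA on x, C placed off an arbitrary y reference
    n_xyz = np.zeros(3)
    ca_xyz = np.array([bl["N_CA"], 0.0, 0.0])
    c_xyz = place_next_atom(
        np.array([0.0, 1.0, 0.0]), n_xyz, ca_xyz, bl["CA_C"], ba["N_CA_C"], 60.0
    )

    backbone = [(n_xyz, ca_xyz, c_xyz)]
    for i in range(2, len(seq) + 1):
        phi, _, omega = dihedrals_for(i)
        _, psi_prev, _ = dihedrals_for(i - 1)
        prev_n, prev_ca, prev_c = backbone[-1]
        n_i = place_next_atom(prev_n, prev_ca, prev_c, bl["C_N"], ba["CA_C_N"], psi_prev)
        ca_i = place_next_atom(prev_ca, prev_c, n_i, bl["N_CA"], ba["C_N_CA"], omega)
        c_i = place_next_atom(prev_c, n_i, ca_i, bl["CA_C"], ba["N_CA_C"], phi)
        backbone.append((n_i, ca_i, c_i))

    atom_radii = load_defaults()["atom_radii"]
    res_idx, roles, coords, radii = [], [], [], []
    for i, (res, (n_i, ca_i, c_i)) in enumerate(zip(seq.residues, backbone), start=1):
        _, psi_i, _ = dihedrals_for(i)
        o_i = place_next_atom(n_i, ca_i, c_i, bl["C_O"], ba["CA_C_O"], psi_i + 180.0)
        cb_i = _place_pseudo_sidechain(n_i, ca_i, c_i, geom.cb_offset)
        for role, xyz in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i), ("CB", cb_i)):
            res_idx.append(i)
            roles.append(role)
            coords.append(xyz)
            radii.append(res.sidechain_radius if role == "CB" else atom_radii[role])

    conf = Conformer(
        peptide_id=seq.id,
        state=state,
        residue_index=np.array(res_idx, dtype=int),
        roles=np.array(roles, dtype="U2"),
        coords=np.array(coords, dtype=float),
        radii=np.array(radii, dtype=float),
        sequence=seq,
    )
    _check_conformer(conf)
    return conf


def _place_pseudo_sidechain(n, ca, c, offset: float) -> np.ndarray:
    # along the tetrahedral direction opposite the N/C bisector, out of plane
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    direction = math.cos(math.radians(54.75)) * bisector + math.sin(math.radians(54.75)) * perp
    return ca + offset * direction


def _check_conformer(conf: Conformer) -> None:
    ca = conf.ca_coords()
    if len(ca) >= 2:
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        if d.min() < 3.6 or d.max() > 3.9:
            raise GeometryError(
                f"consecutive CA-CA distance outside [3.6, 3.9] Å: "
                f"[{d.min():.3f}, {d.max():.3f}]"
            )
    # pairwise coincidence check
    diff = conf.coords[:, None, :] - conf.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 1e-6:
        raise GeometryError("coincident atoms in conformer")


def fit_chain_axis(ca: np.ndarray) -> np.ndarray:
    """Unit vector of the best-fit (principal) axis through CA coordinates,
    oriented N→C."""
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis


def measure_rise(conf: Conformer) -> float:
    """Axial rise per residue (Å): end-to-end CA displacement projected on
    the best-fit chain axis, divided by (n − 1)."""
    ca = conf.ca_coords()
    if len(ca) < 4:
        raise GeometryError("need at least 4 residues to measure rise")
    axis = fit_chain_axis(ca)
    return float(abs(np.dot(ca[-1] - ca[0], axis)) / (len(ca) - 1))


def hydrophobic_mask(
    seq: PeptideSequence, hydrophobic_set: set[str] | None = None
) -> np.ndarray:
    """Boolean vector, one entry per residue, true iff the residue code is in
    the configured hydrophobic set (default from the packaged table)."""
    if hydrophobic_set is None:
        hydrophobic_set = set(load_defaults()["hydrophobic_set"])
    return np.array([r.code in hydrophobic_set for r in seq.residues], dtype=bool)
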