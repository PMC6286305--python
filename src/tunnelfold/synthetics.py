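"""Synthetic data generators.

Everything the analysis consumes can be generated here at desk scale:
reduced exit-tunnel geometries (wall pseudo-atoms around a smooth radius
profile with a single constriction), seeded conformational ensembles of a
peptide placed inside a tunnel, designed test sequences (TM-like, soluble,
half-TM, central mutant pairs), and replicate gel band-intensity datasets
following a logistic glycosylation-vs-distance law with multiplicative
lognormal noise.

All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformer import (
    Conformer,
    InputError,
    PeptideSequence,
    fit_chain_axis,
    hydrophobic_mask,
)
from .sasa import CONTEXT, PEPTIDE, SphereSet

__all__ = [
    "TunnelModel",
    "EnsembleSpec",
    "GelSimSpec",
    "GelDataset",
    "make_tunnel",
    "jitter_ensemble",
    "make_test_sequences",
    "simulate_gel",
    "logistic_law",
    "stream_rng",
]

# alphabets for designed sequences
TM_ALPHABET = "LIVFM"
SOLUBLE_ALPHABET = "EKQRSTNH"  # helix-favoring, polar
POLAR_FLANK_ALPHABET = "STNQ"
MUTANT_REPLACEMENTS = "LAKDGP"


class PlacementError(RuntimeError):
    """Conformer cannot be placed in the tunnel without clashes."""


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named independent random stream derived from a global seed."""
    import zlib

    return np.random.default_rng([seed & 0xFFFFFFFF, zlib.crc32(stream.encode())])


@dataclass
class TunnelModel:
    """Reduced exit-tunnel cartoon: wall pseudo-atoms on a surface of
    revolution around the z axis, P-site end at z = 0."""

    walls: SphereSet
    length: float
    d_max: float
    d_min: float
    constriction_at: float
    hydrophobic_fraction: float
    seed: int

    flare_at: float = 30.0
    waist_rise: float = 0.0  # Å gained along the waist past the constriction

    def radius_at(self, z) -> np.ndarray:
        """Analytic radius profile r(z).

        Cosine-smoothed descent from d_max/2 at the P-site end to the global
        minimum d_min/2 at the constriction, a gently rising narrow waist up
        to ``flare_at``, then a cosine flare back to d_max/2 at the exit.
        """
        z = np.asarray(z, dtype=float)
        r_max, r_min = self.d_max / 2.0, self.d_min / 2.0
        zc, zf = self.constriction_at, min(self.flare_at, self.length)
        r_waist_end = r_min + self.waist_rise

        entry = r_max + (r_min - r_max) * 0.5 * (
            1.0 - np.cos(math.pi * np.clip(z / zc, 0.0, 1.0))
        )
        waist = r_min + self.waist_rise * np.clip(
            (z - zc) / max(zf - zc, 1e-9), 0.0, 1.0
        )
        flare = r_waist_end + (r_max - r_waist_end) * 0.5 * (
            1.0 - np.cos(math.pi * np.clip((z - zf) / max(self.length - zf, 1e-9), 0.0, 1.0))
        )
        return np.where(z <= zc, entry, np.where(z <= zf, waist, flare))


@dataclass
class EnsembleSpec:
    n_frames: int = 50
    jitter_sigma: float = 0.3  # Å per-atom Gaussian jitter
    # C-terminal anchor z (Å).  The anchor stands in for the span of the
    # always-extended linker tethering the test region to the P-site, so in
    # the extended state the far end of a 22-mer reaches past the exit.
    axial_offset_range: tuple[float, float] = (38.0, 44.0)
    max_tilt: float = 5.0  # degrees
    azimuthal_spin: bool = True
    clash_distance: float = 1.0  # Å centre-to-centre peptide–wall
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InputError("n_frames must be ≥ 1")
        if self.jitter_sigma < 0:
            raise InputError("jitter_sigma must be ≥ 0")


@dataclass
class GelSimSpec:
    """Ground truth and noise model for a simulated glycosylation gel."""

    distances: tuple[int, ...]  # P-NST distances d (residues)
    replicates: int = 3
    d50: float = 64.0
    slope: float = 1.2
    g_min: float = 5.0  # %
    g_max: float = 95.0  # %
    total_intensity: float = 1000.0
    noise_sigma: float = 0.15  # lognormal σ on band intensities
    seed: int = 0
    construct: str = "construct"

    def __post_init__(self):
        if not (0.0 <= self.g_min < self.g_max <= 100.0):
            raise InputError("need 0 ≤ G_min < G_max ≤ 100")
        if self.slope <= 0:
            raise InputError("slope must be positive")
        if self.replicates < 3:
            raise InputError("need at least 3 replicates")


@dataclass
class GelDataset:
    """Tidy band-intensity table: construct, d, replicate, band, intensity."""

    table: pd.DataFrame
    spec: GelSimSpec | None = field(default=None, repr=False)

    COLUMNS = ("construct", "d", "replicate", "band", "intensity")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise InputError(f"gel table missing columns: {sorted(missing)}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GelDataset":
        return cls(pd.read_csv(path))


def make_tunnel(
    length: float = 100.0,
    d_max: float = 20.0,
    d_min: float = 10.0,
    constriction_at: float = 30.0,
    wall_spacing: float = 2.8,
    wall_radius: float = 1.7,
    wall_jitter: float = 0.25,
    hydrophobic_fraction: float = 0.3,
    patches: str = "random",
    flare_at: float = 30.0,
    waist_rise: float = 0.0,
    seed: int = 0,
) -> TunnelModel:
    """Generate a reduced tunnel: rings of wall pseudo-atoms along z with a
    smooth radius profile narrowing to ``d_min`` at the constriction.

    ``patches="random"`` assigns hydrophobic wall atoms by a Bernoulli draw
    at ``hydrophobic_fraction``; ``patches="rings"`` instead concentrates the
    same expected number of hydrophobic atoms into three localized rings (two
    flanking the constriction, one near the exit pore).
    """
    if d_min > d_max or d_min <= 0 or length <= 0:
        raise InputError("non-physical tunnel dimensions")
    if not (0.0 < constriction_at < length):
        raise InputError("constriction must lie strictly inside the tunnel")
    if patches not in ("random", "rings"):
        raise InputError(f"unknown patches mode {patches!r}")

    model = TunnelModel(
        walls=SphereSet(np.empty((0, 3)), np.empty(0), np.empty(0, dtype="U7"),
                        np.empty(0, dtype=bool), np.empty(0, dtype=int)),
        length=length, d_max=d_max, d_min=d_min,
        constriction_at=constriction_at,
        hydrophobic_fraction=hydrophobic_fraction, seed=seed,
        flare_at=flare_at, waist_rise=waist_rise,
    )

    rng = stream_rng(seed, "tunnel-walls")
    z_rings = np.arange(0.0, length + 1e-9, wall_spacing)
    coords = []
    for z in z_rings:
        r = float(model.radius_at(z))
        n_atoms = max(3, int(round(2.0 * math.pi * r / wall_spacing)))
        phase = rng.uniform(0.0, 2.0 * math.pi)
        ang = phase + 2.0 * math.pi * np.arange(n_atoms) / n_atoms
        ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(n_atoms, z)])
        ring += rng.normal(0.0, wall_jitter, ring.shape)
        coords.append(ring)
    coords = np.concatenate(coords)
    n = len(coords)

    if patches == "random":
        hydro = stream_rng(seed, "tunnel-hydro").random(n) < hydrophobic_fraction
    else:
        z = coords[:, 2]
        centers = (constriction_at - 5.0, constriction_at + 5.0, 0.9 * length)
        half_width = hydrophobic_fraction * length / (2.0 * len(centers))
        hydro = np.zeros(n, dtype=bool)
        for c in centers:
            hydro |= np.abs(z - c) <= half_width

    model.walls = SphereSet(
        coords=coords,
        radii=np.full(n, wall_radius),
        owner=np.full(n, CONTEXT),
        hydrophobic=hydro,
        residue_index=np.zeros(n, dtype=int),
    )
    return model


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _align_to_tunnel(conf: Conformer, anchor_z: float) -> Conformer:
    """Rigidly move the conformer so its chain axis lies on +z with the
    C-terminal CA at z = anchor_z (the P-site end) and the N-terminus toward
    the exit."""
    ca = conf.ca_coords()
    axis = fit_chain_axis(ca)
    target = np.array([0.0, 0.0, -1.0])  # C-terminus at low z, chain runs N→C downward
    v = np.cross(axis, target)
    s, c = np.linalg.norm(v), float(np.dot(axis, target))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        rot = _rotation_matrix(v / s, math.atan2(s, c))
    moved = conf.transformed(rot, np.zeros(3))
    ca_last = moved.ca_coords()[-1]
    centroid = moved.ca_coords().mean(axis=0)
    # put the axis through x=y=0 and the C-terminal CA at anchor_z
    shift = np.array([-centroid[0], -centroid[1], anchor_z - ca_last[2]])
    return moved.transformed(np.eye(3), shift)


def _has_clash(coords: np.ndarray, tunnel: TunnelModel, clash: float) -> bool:
    from scipy.spatial import cKDTree

    tree = cKDTree(tunnel.walls.coords)
    d, _ = tree.query(coords, k=1)
    return bool((d < clash).any())


def jitter_ensemble(
    conf: Conformer,
    tunnel: TunnelModel,
    spec: EnsembleSpec,
    hydrophobic_residues: np.ndarray | None = None,
) -> list[SphereSet]:
    """Seeded pseudo-ensemble of a conformer inside a tunnel.

    Each frame is an independent rigid placement draw (axial offset of the
    C-terminal anchor, small tilt, free azimuthal spin) plus per-atom
    Gaussian jitter, rejection-sampled until the frame has no peptide–wall
    clash.  Stands in for trajectory frames.
    """
    base = _align_to_tunnel(conf, anchor_z=sum(spec.axial_offset_range) / 2.0)
    if _has_clash(base.coords, tunnel, spec.clash_distance):
        raise PlacementError(
            f"conformer {conf.peptide_id!r} ({conf.state}) clashes with the tunnel "
            f"wall even at zero jitter; span may exceed the tunnel"
        )
    if hydrophobic_residues is None and conf.sequence is not None:
        hydrophobic_residues = hydrophobic_mask(conf.sequence)

    rng = stream_rng(spec.seed, f"ensemble-{conf.peptide_id}-{conf.state}")
    lo, hi = spec.axial_offset_range
    frames: list[SphereSet] = []
    max_tries = 200
    for _ in range(spec.n_frames):
        for attempt in range(max_tries):
            anchor = rng.uniform(lo, hi)
            placed = _align_to_tunnel(conf, anchor_z=anchor)
            spin_angle = rng.uniform(0, 2 * math.pi) if spec.azimuthal_spin else 0.0
            spin = _rotation_matrix(np.array([0.0, 0.0, 1.0]), spin_angle)
            tilt_ax = np.array([math.cos(a := rng.uniform(0, 2 * math.pi)), math.sin(a), 0.0])
            tilt = _rotation_matrix(tilt_ax, math.radians(rng.uniform(0, spec.max_tilt)))
            pivot = placed.ca_coords()[-1]
            coords = (placed.coords - pivot) @ (tilt @ spin).T + pivot
            coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
            if not _has_clash(coords, tunnel, spec.clash_distance):
                break
        else:
            raise PlacementError(
                f"no clash-free placement found in {max_tries} tries for "
                f"{conf.peptide_id!r} ({conf.state})"
            )
        frame = Conformer(
            conf.peptide_id, conf.state, conf.residue_index.copy(), conf.roles.copy(),
            coords, conf.radii.copy(), conf.sequence,
        )
        frames.append(SphereSet.from_conformer(frame, hydrophobic_residues, owner=PEPTIDE))
    return frames


def make_test_sequences(
    kind: str,
    length: int = 22,
    base: PeptideSequence | None = None,
    replacement: str | None = None,
    half: str = "N",
    seed: int = 0,
) -> PeptideSequence:
    """Designed test sequences.

    - ``tm``: 20–22 residues from a hydrophobic alphabet with a central
      Ile pair (the wild-type reference for the mutant series).
    - ``soluble``: helix-favoring polar alphabet, same length.
    - ``half_tm``: N- or C-terminal half (~length/2 residues) of a TM
      sequence, padded back to full length with polar flanks.
    - ``mutant_pair``: the central two residues of ``base`` replaced with
      ``replacement`` (one of L, A, K, D, G, P).
    """
    rng = stream_rng(seed, f"seq-{kind}")
    if kind == "tm":
        if not (20 <= length <= 22):
            raise InputError("tm length must be 20–22 residues")
        letters = list(rng.choice(list(TM_ALPHABET), size=length))
        mid = length // 2
        letters[mid - 1] = letters[mid] = "I"  # central Ile pair, wild-type analogue
        return PeptideSequence.from_string("".join(letters), id=f"tm-{seed}")
    if kind == "soluble":
        letters = rng.choice(list(SOLUBLE_ALPHABET), size=length)
        return PeptideSequence.from_string("".join(letters), id=f"soluble-{seed}")
    if kind == "half_tm":
        tm = base or make_test_sequences("tm", length=length, seed=seed)
        n = len(tm)
        k = n // 2
        core = str(tm)[:k] if half == "N" else str(tm)[-k:]
        pad = "".join(rng.choice(list(POLAR_FLANK_ALPHABET), size=n - k))
        seqstr = core + pad if half == "N" else pad + core
        return PeptideSequence.from_string(seqstr, id=f"half-tm-{half}-{seed}")
    if kind == "mutant_pair":
        if base is None:
            raise InputError("mutant_pair requires a base tm sequence")
        if replacement not in MUTANT_REPLACEMENTS:
            raise InputError(
                f"replacement must be one of {MUTANT_REPLACEMENTS!r}, got {replacement!r}"
            )
        s = list(str(base))
        mid = len(s) // 2
        s[mid - 1] = s[mid] = replacement
        return PeptideSequence.from_string(
            "".join(s), id=f"{base.id}-{replacement}{replacement}",
            helical_region=base.helical_region,
        )
    raise InputError(f"unknown sequence kind {kind!r}")


def logistic_law(d, d50: float, slope: float, g_min: float, g_max: float):
    """Percent glycosylation as a function of P-NST distance d."""
    d = np.asarray(d, dtype=float)
    return g_min + (g_max - g_min) / (1.0 + np.exp(-(d - d50) / slope))


def simulate_gel(spec: GelSimSpec) -> GelDataset:
    """Simulate replicate gel lanes.

    For each distance d and replicate, the glycosylated band intensity is
    total·G(d)/100 and the non-glycosylated band total·(1 − G(d)/100), each
    multiplied by independent lognormal(0, σ) noise.
    """
    rng = stream_rng(spec.seed, f"gel-{spec.construct}")
    rows = []
    for d in spec.distances:
        g = float(logistic_law(d, spec.d50, spec.slope, spec.g_min, spec.g_max))
        for rep in range(1, spec.replicates + 1):
            noise_g, noise_n = (
                (1.0, 1.0) if spec.noise_sigma == 0
                else np.exp(rng.normal(0.0, spec.noise_sigma, 2))
            )
            rows.append((spec.construct, d, rep, "glyc",
                         spec.total_intensity * g / 100.0 * noise_g))
            rows.append((spec.construct, d, rep, "nonglyc",
                         spec.total_intensity * (1.0 - g / 100.0) * noise_n))
    table = pd.DataFrame(rows, columns=list(GelDataset.COLUMNS))
    return GelDataset(table, spec=spec)
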