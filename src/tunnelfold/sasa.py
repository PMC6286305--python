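"""Shrake–Rupley solvent-accessible surface area and burial statistics.

Implements point-sampling SASA on a deterministic golden-section spiral
lattice, the in-context burial statistic ΔSASA (selection SASA in a
peptide+context complex minus the same selection alone), the ensemble
contrast ΔΔSASA between two conformational states, attribution of buried
area to occluder classes, and the linear buried-area → free-energy
conversion.

Sign conventions: ΔSASA ≤ 0 (burial removes area); ΔΔSASA < 0 means the
context buries the first (helical) state more than the second (extended).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .conformer import Conformer

__all__ = [
    "SphereSet",
    "SASAResult",
    "DeltaSASAResult",
    "DDSASAResult",
    "EnergyEstimate",
    "OccluderAttribution",
    "sasa",
    "delta_sasa",
    "dd_sasa",
    "burial_energy",
    "occluder_attribution",
    "sphere_lattice",
]

DEFAULT_PROBE = 1.4  # Å
DEFAULT_N_POINTS = 960

PEPTIDE = "peptide"
CONTEXT = "context"


class SasaInputError(ValueError):
    pass


class SasaConfigError(ValueError):
    pass


@dataclass
class SphereSet:
    """A set of spheres with ownership, hydrophobicity and residue labels."""

    coords: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    owner: np.ndarray  # (n,) unicode, "peptide" | "context"
    hydrophobic: np.ndarray  # (n,) bool
    residue_index: np.ndarray  # (n,) int, 0 for context atoms

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.owner = np.asarray(self.owner, dtype="U7").reshape(n)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool).reshape(n)
        self.residue_index = np.asarray(self.residue_index, dtype=int).reshape(n)
        if n and not np.all(np.isfinite(self.coords)):
            raise SasaInputError("non-finite coordinates")
        if n and np.any(self.radii <= 0):
            raise SasaInputError("radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_conformer(
        cls,
        conf: Conformer,
        hydrophobic_residues: np.ndarray | None = None,
        owner: str = PEPTIDE,
    ) -> "SphereSet":
        """Wrap a conformer; ``hydrophobic_residues`` is a per-residue boolean
        mask (1-based residue i → entry i-1)."""
        n = len(conf.coords)
        if hydrophobic_residues is None:
            hydro = np.zeros(n, dtype=bool)
        else:
            hydro = np.asarray(hydrophobic_residues, dtype=bool)[conf.residue_index - 1]
        return cls(
            coords=conf.coords.copy(),
            radii=conf.radii.copy(),
            owner=np.full(n, owner),
            hydrophobic=hydro,
            residue_index=conf.residue_index.copy(),
        )

    @classmethod
    def concat(cls, *sets: "SphereSet") -> "SphereSet":
        return cls(
            coords=np.concatenate([s.coords for s in sets]) if sets else np.empty((0, 3)),
            radii=np.concatenate([s.radii for s in sets]),
            owner=np.concatenate([s.owner for s in sets]),
            hydrophobic=np.concatenate([s.hydrophobic for s in sets]),
            residue_index=np.concatenate([s.residue_index for s in sets]),
        )

    def subset(self, mask: np.ndarray) -> "SphereSet":
        mask = np.asarray(mask, dtype=bool)
        return SphereSet(
            self.coords[mask], self.radii[mask], self.owner[mask],
            self.hydrophobic[mask], self.residue_index[mask],
        )


@dataclass
class SASAResult:
    per_atom: np.ndarray  # Å², full-length; NaN where not computed
    per_residue: dict[int, float]
    selection_total: float  # Å²
    probe: float
    n_points: int

    def __post_init__(self):
        computed = self.per_atom[~np.isnan(self.per_atom)]
        if np.any(computed < -1e-9):
            raise SasaInputError("negative per-atom area")


@dataclass
class DeltaSASAResult:
    delta_sasa: float  # Å², ≤ 0 up to quadrature tolerance
    sasa_complex: float
    sasa_alone: float
    probe: float
    n_points: int
    selection_size: int


@dataclass
class DDSASAResult:
    per_frame_first: np.ndarray  # ΔSASA series, first (helical) state
    per_frame_second: np.ndarray  # ΔSASA series, second (extended) state
    mean_first: float
    mean_second: float
    dd_sasa: float  # mean_first − mean_second
    sd_first: float
    sd_second: float
    se_dd: float  # quadrature standard error of the difference of means
    window: float | None = None  # fraction of trailing frames used for means


@dataclass
class EnergyEstimate:
    delta_g: float  # kcal/mol, negative = stabilizing
    coefficient: float  # kcal/mol/Å²


@dataclass
class OccluderAttribution:
    buried_by_hydrophobic_context: float  # Å²
    buried_by_polar_context: float  # Å²
    internal_occlusion: float  # Å² hidden by the peptide itself (both systems)

    @property
    def context_total(self) -> float:
        return self.buried_by_hydrophobic_context + self.buried_by_polar_context


_LATTICE_CACHE: dict[int, np.ndarray] = {}


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n_points`` unit vectors."""
    if n_points in _LATTICE_CACHE:
        return _LATTICE_CACHE[n_points]
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    _LATTICE_CACHE[n_points] = pts
    return pts


def _resolve_selection(spheres: SphereSet, selection) -> np.ndarray:
    """Selection may be None (all), a boolean mask, index array, or a
    predicate over (owner, hydrophobic, residue_index) arrays."""
    n = len(spheres)
    if selection is None:
        return np.ones(n, dtype=bool)
    if callable(selection):
        mask = np.asarray(selection(spheres), dtype=bool)
        if mask.shape != (n,):
            raise SasaInputError("selection predicate returned wrong-shape mask")
        return mask
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise SasaInputError("selection mask has wrong length")
        return sel
    mask = np.zeros(n, dtype=bool)
    mask[sel] = True
    return mask


def _accessible_fractions(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray,
    probe: float,
    n_points: int,
    return_point_masks: bool = False,
):
    """Accessible point fraction for each atom index in ``subset``.

    Neighbour candidates are limited to atoms within r_i + r_j + 2·probe.
    Optionally returns the per-point accessibility mask and, per occluded
    point, the index of the nearest occluding atom.
    """
    lattice = sphere_lattice(n_points)
    tree = cKDTree(coords)
    max_r = radii.max() if len(radii) else 0.0
    fractions = np.empty(len(subset))
    point_masks = []
    nearest_occluder = []
    for k, i in enumerate(subset):
        r_i = radii[i] + probe
        cutoff = radii[i] + max_r + 2.0 * probe
        nbrs = np.array(tree.query_ball_point(coords[i], cutoff))
        nbrs = nbrs[nbrs != i]
        if len(nbrs):
            d = np.linalg.norm(coords[nbrs] - coords[i], axis=1)
            keep = d < radii[i] + radii[nbrs] + 2.0 * probe
            nbrs = nbrs[keep]
        if len(nbrs) == 0:
            fractions[k] = 1.0
            if return_point_masks:
                point_masks.append(np.ones(n_points, dtype=bool))
                nearest_occluder.append(np.full(n_points, -1))
            continue
        pts = coords[i] + r_i * lattice  # (P, 3)
        diff = pts[:, None, :] - coords[nbrs][None, :, :]
        dist = np.linalg.norm(diff, axis=-1)  # (P, M)
        inside = dist < (radii[nbrs] + probe)[None, :]
        occluded = inside.any(axis=1)
        fractions[k] = 1.0 - occluded.mean()
        if return_point_masks:
            point_masks.append(~occluded)
            # nearest occluder by surface distance among occluding atoms
            surf = dist - (radii[nbrs] + probe)[None, :]
            surf_masked = np.where(inside, surf, np.inf)
            idx = np.where(occluded, nbrs[np.argmin(surf_masked, axis=1)], -1)
            nearest_occluder.append(idx)
    if return_point_masks:
        return fractions, point_masks, nearest_occluder
    return fractions


def sasa(
    spheres: SphereSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    selection=None,
) -> SASAResult:
    """Shrake–Rupley SASA of ``spheres``.

    Per-atom area = accessible lattice fraction × 4π(r + probe)².  Areas are
    computed for the selected atoms only; unselected entries are NaN.
    """
    if probe < 0:
        raise SasaInputError("probe radius must be non-negative")
    if n_points < 32:
        raise SasaInputError("n_points must be ≥ 32")
    mask = _resolve_selection(spheres, selection)
    per_atom = np.full(len(spheres), np.nan)
    subset = np.flatnonzero(mask)
    if len(subset) == 0:
        return SASAResult(per_atom, {}, 0.0, probe, n_points)
    fractions = _accessible_fractions(spheres.coords, spheres.radii, subset, probe, n_points)
    per_atom[subset] = fractions * 4.0 * math.pi * (spheres.radii[subset] + probe) ** 2
    per_residue: dict[int, float] = {}
    for i in subset:
        per_residue.setdefault(int(spheres.residue_index[i]), 0.0)
        per_residue[int(spheres.residue_index[i])] += per_atom[i]
    return SASAResult(per_atom, per_residue, float(np.nansum(per_atom[subset])), probe, n_points)


def delta_sasa(
    peptide: SphereSet,
    context: SphereSet,
    selection=None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> DeltaSASAResult:
    """ΔSASA of the selected peptide atoms: SASA in the peptide+context
    complex minus SASA of the peptide alone.  ≤ 0 up to quadrature noise."""
    mask = _resolve_selection(peptide, selection)
    if np.any(peptide.owner != PEPTIDE):
        raise SasaInputError("first argument must contain only peptide atoms")
    alone = sasa(peptide, probe=probe, n_points=n_points, selection=mask)
    complex_set = SphereSet.concat(peptide, context)
    complex_mask = np.concatenate([mask, np.zeros(len(context), dtype=bool)])
    in_complex = sasa(complex_set, probe=probe, n_points=n_points, selection=complex_mask)
    return DeltaSASAResult(
        delta_sasa=in_complex.selection_total - alone.selection_total,
        sasa_complex=in_complex.selection_total,
        sasa_alone=alone.selection_total,
        probe=probe,
        n_points=n_points,
        selection_size=int(mask.sum()),
    )


def dd_sasa(
    first_frames: list[SphereSet],
    second_frames: list[SphereSet],
    context: SphereSet,
    selection=None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    window: float | None = None,
) -> DDSASAResult:
    """Ensemble burial contrast between two states.

    Per-frame ΔSASA is computed with identical sampling parameters for both
    frame lists; the statistic is the difference of the (optionally
    window-restricted) frame means: mean(first) − mean(second).  By
    convention the first list is the helical state.
    """
    if not first_frames or not second_frames:
        raise SasaInputError("need at least one frame per state")
    if window is not None and not (0.0 < window <= 1.0):
        raise SasaConfigError("window must be a fraction in (0, 1]")

    def series(frames):
        return np.array([
            delta_sasa(f, context, selection=selection, probe=probe, n_points=n_points).delta_sasa
            for f in frames
        ])

    s1, s2 = series(first_frames), series(second_frames)

    def windowed(s):
        if window is None:
            return s
        k = max(1, int(math.ceil(len(s) * window)))
        return s[-k:]

    w1, w2 = windowed(s1), windowed(s2)
    m1, m2 = float(w1.mean()), float(w2.mean())
    sd1 = float(w1.std(ddof=1)) if len(w1) > 1 else 0.0
    sd2 = float(w2.std(ddof=1)) if len(w2) > 1 else 0.0
    se = math.sqrt(
        (sd1 ** 2 / len(w1) if len(w1) > 1 else 0.0)
        + (sd2 ** 2 / len(w2) if len(w2) > 1 else 0.0)
    )
    return DDSASAResult(
        per_frame_first=s1, per_frame_second=s2,
        mean_first=m1, mean_second=m2, dd_sasa=m1 - m2,
        sd_first=sd1, sd_second=sd2, se_dd=se, window=window,
    )


def burial_energy(
    dsasa: DeltaSASAResult | float, coefficient: float = 0.015
) -> EnergyEstimate:
    """Convert buried area to free energy: ΔG = coefficient × ΔSASA
    (kcal/mol per Å²; negative ΔSASA → stabilizing ΔG)."""
    if coefficient <= 0:
        raise SasaInputError("coefficient must be positive")
    value = dsasa.delta_sasa if isinstance(dsasa, DeltaSASAResult) else float(dsasa)
    return EnergyEstimate(delta_g=coefficient * value, coefficient=coefficient)


def occluder_attribution(
    peptide: SphereSet,
    context: SphereSet,
    selection=None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> OccluderAttribution:
    """Split the buried area of the selected peptide atoms by occluder class.

    Every lattice point accessible on the peptide alone but lost in the
    complex is attributed to its nearest occluding context atom; the
    hydrophobic/polar class totals then sum exactly to |ΔSASA| contributed by
    the context.  Area already hidden by the peptide itself is reported
    separately as internal occlusion.
    """
    mask = _resolve_selection(peptide, selection)
    subset = np.flatnonzero(mask)
    if len(subset) == 0 or len(context) == 0:
        return OccluderAttribution(0.0, 0.0, _internal_occlusion(peptide, subset, probe, n_points))

    complex_set = SphereSet.concat(peptide, context)
    n_pep = len(peptide)

    _, masks_alone, _ = _accessible_fractions(
        peptide.coords, peptide.radii, subset, probe, n_points, return_point_masks=True
    )
    _, masks_cplx, occluders = _accessible_fractions(
        complex_set.coords, complex_set.radii, subset, probe, n_points, return_point_masks=True
    )

    hydro_area = polar_area = internal = 0.0
    for k, i in enumerate(subset):
        w = 4.0 * math.pi * (peptide.radii[i] + probe) ** 2 / n_points
        internal += w * np.count_nonzero(~masks_alone[k])
        lost = masks_alone[k] & ~masks_cplx[k]
        occ = occluders[k][lost]
        # points lost in the complex are occluded by context atoms (index ≥ n_pep)
        ctx_occ = occ[occ >= n_pep] - n_pep
        hydro_area += w * np.count_nonzero(context.hydrophobic[ctx_occ])
        polar_area += w * np.count_nonzero(~context.hydrophobic[ctx_occ])
        # occ < n_pep cannot happen for lost points: peptide occlusion is
        # identical in both systems, so a point lost in the complex is
        # occluded exclusively by context atoms.
    return OccluderAttribution(hydro_area, polar_area, internal)


def _internal_occlusion(
    peptide: SphereSet, subset: np.ndarray, probe: float, n_points: int
) -> float:
    if len(subset) == 0:
        return 0.0
    fracs = _accessible_fractions(peptide.coords, peptide.radii, subset, probe, n_points)
    areas = 4.0 * math.pi * (peptide.radii[subset] + probe) ** 2
    return float(((1.0 - fracs) * areas).sum())
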