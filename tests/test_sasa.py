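import math

import numpy as np
import pytest

from tunnelfold.conformer import build_conformer, hydrophobic_mask
from tunnelfold.pipeline import selection_for
from tunnelfold.sasa import (
    CONTEXT,
    PEPTIDE,
    SasaInputError,
    SphereSet,
    burial_energy,
    dd_sasa,
    delta_sasa,
    occluder_attribution,
    sasa,
    sphere_lattice,
)
from tunnelfold.synthetics import EnsembleSpec, jitter_ensemble, make_tunnel


def spheres(coords, radii, owner=PEPTIDE, hydro=None, res=None):
    n = len(radii)
    return SphereSet(
        np.asarray(coords, dtype=float),
        np.asarray(radii, dtype=float),
        np.full(n, owner),
        np.zeros(n, dtype=bool) if hydro is None else np.asarray(hydro, dtype=bool),
        np.arange(1, n + 1) if res is None else np.asarray(res, dtype=int),
    )


def two_sphere_analytic(r1, r2, d, probe):
    """Independent oracle: accessible area of each of two intersecting
    spheres from the spherical-cap closed form on probe-expanded radii."""
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * math.pi * R1**2, 4 * math.pi * R2**2
    if d >= R1 + R2:
        return full1, full2
    # cap height hidden on sphere 1 by sphere 2 (and vice versa)
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return full1 - 2 * math.pi * R1 * h1, full2 - 2 * math.pi * R2 * h2


class TestLattice:
    def test_unit_norm(self):
        pts = sphere_lattice(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        assert np.array_equal(sphere_lattice(480), sphere_lattice(480))

    def test_centroid_near_origin(self):
        assert np.linalg.norm(sphere_lattice(960).mean(axis=0)) < 1e-2


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = spheres([[0, 0, 0]], [1.7])
        res = sasa(s, probe=1.4, n_points=960)
        exact = 4 * math.pi * 3.1**2
        assert res.selection_total == pytest.approx(exact, rel=0.01)

    def test_two_sphere_cap_oracle(self):
        r1, r2, d, probe = 1.7, 1.5, 2.0, 1.4
        s = spheres([[0, 0, 0], [d, 0, 0]], [r1, r2])
        res = sasa(s, probe=probe, n_points=1920)
        a1, a2 = two_sphere_analytic(r1, r2, d, probe)
        assert res.per_atom[0] == pytest.approx(a1, rel=0.01)
        assert res.per_atom[1] == pytest.approx(a2, rel=0.01)

    def test_distant_spheres_no_occlusion(self):
        s = spheres([[0, 0, 0], [20, 0, 0]], [1.7, 1.5])
        res = sasa(s, probe=1.4, n_points=480)
        exact = 4 * math.pi * (3.1**2 + 2.9**2)
        assert res.selection_total == pytest.approx(exact, rel=1e-9)

    def test_empty_selection_zero(self):
        s = spheres([[0, 0, 0]], [1.7])
        res = sasa(s, selection=np.zeros(1, dtype=bool))
        assert res.selection_total == 0.0

    def test_negative_probe_raises(self):
        s = spheres([[0, 0, 0]], [1.7])
        with pytest.raises(SasaInputError):
            sasa(s, probe=-0.1)

    def test_too_few_points_raises(self):
        s = spheres([[0, 0, 0]], [1.7])
        with pytest.raises(SasaInputError):
            sasa(s, n_points=16)

    def test_totals_sum_of_parts(self):
        rng = np.random.default_rng(0)
        s = spheres(rng.normal(scale=2.0, size=(8, 3)), np.full(8, 1.6))
        res = sasa(s, n_points=480)
        assert res.selection_total == pytest.approx(np.nansum(res.per_atom), abs=1e-6)
        assert sum(res.per_residue.values()) == pytest.approx(res.selection_total, abs=1e-6)

    def test_quadrature_convergence(self):
        # mean |error| vs the cap oracle shrinks as n_points doubles
        r1, r2, d, probe = 1.7, 1.5, 2.4, 1.4
        s = spheres([[0, 0, 0], [d, 0, 0]], [r1, r2])
        exact = sum(two_sphere_analytic(r1, r2, d, probe))
        errors = []
        for n in (120, 480, 1920, 7680):
            tot = sasa(s, probe=probe, n_points=n).selection_total
            errors.append(abs(tot - exact))
        assert errors[-1] < errors[0]
        assert errors[-1] / exact < 0.005

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=2.0, size=(6, 3))
        s1 = spheres(coords, np.full(6, 1.6))
        s2 = spheres(coords + np.array([123.4, -56.7, 89.0]), np.full(6, 1.6))
        a = sasa(s1, n_points=480).selection_total
        b = sasa(s2, n_points=480).selection_total
        assert a == pytest.approx(b, abs=1e-6)

    def test_rotation_quasi_invariance(self):
        # lattice is fixed in the global frame, so rotation changes totals
        # only at the quadrature-noise level
        rng = np.random.default_rng(4)
        coords = rng.normal(scale=2.0, size=(6, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s1 = spheres(coords, np.full(6, 1.6))
        s2 = spheres(coords @ q.T, np.full(6, 1.6))
        a = sasa(s1, n_points=960).selection_total
        b = sasa(s2, n_points=960).selection_total
        assert a == pytest.approx(b, rel=0.01)


class TestDeltaSasa:
    def test_empty_context_zero(self):
        pep = spheres([[0, 0, 0], [4, 0, 0]], [1.7, 1.7])
        ctx = spheres(np.empty((0, 3)), [], owner=CONTEXT, res=[])
        res = delta_sasa(pep, ctx, n_points=480)
        assert res.delta_sasa == pytest.approx(0.0, abs=1e-9)

    def test_far_context_zero(self):
        pep = spheres([[0, 0, 0]], [1.7])
        ctx = spheres([[50, 0, 0], [60, 0, 0]], [1.7, 1.7], owner=CONTEXT, res=[0, 0])
        res = delta_sasa(pep, ctx, n_points=480)
        assert res.delta_sasa == pytest.approx(0.0, abs=1e-9)

    def test_context_buries(self):
        pep = spheres([[0, 0, 0]], [1.7])
        ctx = spheres([[3.0, 0, 0]], [1.7], owner=CONTEXT, res=[0])
        res = delta_sasa(pep, ctx, n_points=960)
        assert res.delta_sasa < -10.0

    def test_peptide_owner_enforced(self):
        notpep = spheres([[0, 0, 0]], [1.7], owner=CONTEXT, res=[0])
        ctx = spheres([[3, 0, 0]], [1.7], owner=CONTEXT, res=[0])
        with pytest.raises(SasaInputError):
            delta_sasa(notpep, ctx)

    def test_narrow_tunnel_buries_more(self, tm_sequence):
        conf = build_conformer(tm_sequence, "helical")
        hydro = hydrophobic_mask(tm_sequence)
        sel = selection_for(tm_sequence)
        spec = EnsembleSpec(n_frames=1, jitter_sigma=0.0, seed=5)
        results = {}
        for label, d_min in (("narrow", 10.0), ("wide", 16.0)):
            tunnel = make_tunnel(d_min=d_min, d_max=20.0, seed=5)
            frames = jitter_ensemble(conf, tunnel, spec, hydrophobic_residues=hydro)
            results[label] = delta_sasa(
                frames[0], tunnel.walls, selection=sel, n_points=480
            ).delta_sasa
        assert results["narrow"] <= results["wide"]

    def test_delta_nonpositive_random_placements(self, tm_sequence, default_tunnel):
        conf = build_conformer(tm_sequence, "helical")
        hydro = hydrophobic_mask(tm_sequence)
        spec = EnsembleSpec(n_frames=10, seed=11)
        frames = jitter_ensemble(conf, default_tunnel, spec, hydrophobic_residues=hydro)
        sel = selection_for(tm_sequence)
        for f in frames:
            res = delta_sasa(f, default_tunnel.walls, selection=sel, n_points=240)
            assert res.delta_sasa <= 1e-6


class TestDDSasa:
    def _frames(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            spheres(rng.normal(scale=2.0, size=(4, 3)), np.full(4, 1.6))
            for _ in range(n)
        ]

    def _context(self):
        return spheres([[0.0, 0.0, 3.0]], [1.7], owner=CONTEXT, res=[0])

    def test_identical_frames_zero(self):
        frames = self._frames(3)
        res = dd_sasa(frames, frames, self._context(), n_points=240)
        assert res.dd_sasa == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        f1, f2 = self._frames(3, seed=1), self._frames(3, seed=2)
        ctx = self._context()
        a = dd_sasa(f1, f2, ctx, n_points=240)
        b = dd_sasa(f2, f1, ctx, n_points=240)
        assert a.dd_sasa == pytest.approx(-b.dd_sasa, abs=1e-9)

    def test_equals_mean_of_paired_differences(self):
        f1, f2 = self._frames(4, seed=3), self._frames(4, seed=4)
        ctx = self._context()
        res = dd_sasa(f1, f2, ctx, n_points=240)
        paired = np.mean(res.per_frame_first - res.per_frame_second)
        assert res.dd_sasa == pytest.approx(paired, abs=1e-9)

    def test_dd_equals_difference_of_means(self):
        f1, f2 = self._frames(3, seed=5), self._frames(5, seed=6)
        res = dd_sasa(f1, f2, self._context(), n_points=240)
        assert res.dd_sasa == pytest.approx(res.mean_first - res.mean_second, abs=1e-9)

    def test_empty_frames_raise(self):
        with pytest.raises(SasaInputError):
            dd_sasa([], self._frames(1), self._context())

    def test_window_restricts_mean(self):
        f1, f2 = self._frames(6, seed=7), self._frames(6, seed=8)
        ctx = self._context()
        full = dd_sasa(f1, f2, ctx, n_points=240)
        half = dd_sasa(f1, f2, ctx, n_points=240, window=0.5)
        assert half.mean_first == pytest.approx(
            np.mean(full.per_frame_first[-3:]), abs=1e-9
        )


class TestBurialEnergy:
    def test_paper_coefficient(self):
        est = burial_energy(-100.0)
        assert est.delta_g == pytest.approx(-1.5)

    def test_zero(self):
        assert burial_energy(0.0).delta_g == 0.0

    def test_linearity(self):
        assert burial_energy(-50.0, coefficient=0.030).delta_g == pytest.approx(-1.5)

    def test_bad_coefficient(self):
        with pytest.raises(SasaInputError):
            burial_energy(-1.0, coefficient=0.0)


class TestOccluderAttribution:
    def _pair(self, ctx_hydro):
        pep = spheres([[0, 0, 0]], [1.7], hydro=[True])
        n = len(ctx_hydro)
        ctx = SphereSet(
            np.array([[3.0, 0, 0], [-3.0, 0, 0]])[:n],
            np.full(n, 1.7), np.full(n, CONTEXT),
            np.asarray(ctx_hydro, dtype=bool), np.zeros(n, dtype=int),
        )
        return pep, ctx

    def test_all_hydrophobic_context(self):
        pep, ctx = self._pair([True, True])
        att = occluder_attribution(pep, ctx, n_points=480)
        assert att.buried_by_polar_context == 0.0
        assert att.buried_by_hydrophobic_context > 0.0

    def test_empty_context(self):
        pep = spheres([[0, 0, 0]], [1.7])
        ctx = spheres(np.empty((0, 3)), [], owner=CONTEXT, res=[])
        att = occluder_attribution(pep, ctx, n_points=480)
        assert att.buried_by_hydrophobic_context == 0.0
        assert att.buried_by_polar_context == 0.0

    def test_class_totals_match_delta_sasa(self):
        pep, ctx = self._pair([True, False])
        att = occluder_attribution(pep, ctx, n_points=960)
        dsa = delta_sasa(pep, ctx, n_points=960)
        assert att.context_total == pytest.approx(-dsa.delta_sasa, abs=1e-6)

    def test_brute_force_point_recount(self):
        # independent oracle: re-derive class totals point by point
        rng = np.random.default_rng(9)
        pep = spheres(rng.normal(scale=1.5, size=(3, 3)), np.full(3, 1.6),
                      hydro=[True] * 3)
        ctx_coords = rng.normal(scale=1.5, size=(4, 3)) + np.array([3.0, 0, 0])
        ctx_h = np.array([True, False, True, False])
        ctx = SphereSet(ctx_coords, np.full(4, 1.7), np.full(4, CONTEXT),
                        ctx_h, np.zeros(4, dtype=int))
        n_points = 480
        probe = 1.4
        att = occluder_attribution(pep, ctx, n_points=n_points, probe=probe)

        lattice = sphere_lattice(n_points)
        hydro = polar = 0.0
        for i in range(3):
            R = pep.radii[i] + probe
            pts = pep.coords[i] + R * lattice
            occ_pep = np.zeros(n_points, dtype=bool)
            for j in range(3):
                if j == i:
                    continue
                occ_pep |= np.linalg.norm(pts - pep.coords[j], axis=1) < pep.radii[j] + probe
            dist_ctx = np.linalg.norm(
                pts[:, None, :] - ctx.coords[None, :, :], axis=-1
            ) - (ctx.radii + probe)[None, :]
            occ_ctx = (dist_ctx < 0).any(axis=1)
            lost = ~occ_pep & occ_ctx
            nearest = np.argmin(dist_ctx, axis=1)
            w = 4 * math.pi * R**2 / n_points
            hydro += w * np.count_nonzero(lost & ctx_h[nearest])
            polar += w * np.count_nonzero(lost & ~ctx_h[nearest])
        assert att.buried_by_hydrophobic_context == pytest.approx(hydro, abs=1e-6)
        assert att.buried_by_polar_context == pytest.approx(polar, abs=1e-6)
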