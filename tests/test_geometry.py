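"""Voronoi cell volumes and spherical-harmonics descriptors.

Oracles: Monte-Carlo nearest-site point assignment for Voronoi volumes and
an explicit closed-form evaluation of the real spherical harmonics (written
out in Cartesian form, independent of scipy) for the power aggregate.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import graphbind as gb
from graphbind.errors import DegenerateSiteError
from graphbind.geometry import VoronoiSpec, SphericalHarmonicSpec


# ---------------------------------------------------------------- Voronoi

def mc_voronoi_volumes(coords, margin, n_samples, seed):
    """Monte-Carlo nearest-site oracle: fraction of box points per site."""
    rng = np.random.default_rng(seed)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    owner = d2.argmin(axis=1)
    counts = np.bincount(owner, minlength=len(coords))
    box_vol = float(np.prod(hi - lo))
    frac = counts / n_samples
    vol = frac * box_vol
    # binomial sampling error per site
    sigma = np.sqrt(frac * (1 - frac) / n_samples) * box_vol
    return vol, sigma


def test_cube_corner_cells_are_equal():
    pts = np.array([[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0)
                    for z in (0.0, 1.0)])
    v = gb.voronoi_descriptor(pts, VoronoiSpec(clip_margin=5.0))
    assert np.allclose(v, v[0])
    assert v.sum() == pytest.approx(11.0 ** 3, rel=1e-9)


def test_single_site_owns_whole_box():
    v = gb.voronoi_descriptor(np.array([[1.0, 2.0, 3.0]]),
                              VoronoiSpec(clip_margin=2.0))
    assert v[0] == pytest.approx(4.0 ** 3, rel=1e-12)


def test_two_sites_match_monte_carlo_oracle():
    coords = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    spec = VoronoiSpec(clip_margin=1.0)
    v = gb.voronoi_descriptor(coords, spec)
    mc, sigma = mc_voronoi_volumes(coords, 1.0, 1_000_000, seed=42)
    assert np.all(np.abs(v - mc) < 3 * sigma + 1e-9)
    # symmetry: the two half-boxes are equal
    assert v[0] == pytest.approx(v[1], rel=1e-9)


@pytest.mark.parametrize("seed,n", [(0, 5), (1, 12), (2, 40), (3, 120)])
def test_volume_conservation_random_sets(seed, n):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-4, 4, size=(n, 3))
    v = gb.voronoi_descriptor(coords, VoronoiSpec(clip_margin=5.0))
    lo, hi = coords.min(axis=0) - 5.0, coords.max(axis=0) + 5.0
    assert v.sum() == pytest.approx(float(np.prod(hi - lo)), rel=1e-6)
    assert np.all(v > 0)


def test_random_set_matches_monte_carlo_oracle():
    rng = np.random.default_rng(7)
    coords = rng.uniform(-3, 3, size=(15, 3))
    v = gb.voronoi_descriptor(coords, VoronoiSpec(clip_margin=4.0))
    mc, sigma = mc_voronoi_volumes(coords, 4.0, 1_000_000, seed=8)
    assert np.all(np.abs(v - mc) < 3 * sigma + 1e-9)


def test_coincident_sites_rejected():
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    with pytest.raises(DegenerateSiteError):
        gb.voronoi_descriptor(coords)


def test_degenerate_collinear_sites_still_conserve_volume():
    coords = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [2.8, 0.0, 0.0]])
    v = gb.voronoi_descriptor(coords, VoronoiSpec(clip_margin=3.0))
    assert v.sum() == pytest.approx((2.8 + 6.0) * 6.0 * 6.0, rel=1e-9)


# ---------------------------------------------- spherical harmonics oracle

SQRT = np.sqrt


def real_sh_cartesian(l, m, u):
    """Closed-form real spherical harmonics up to l = 2 from unit vectors."""
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    pi = np.pi
    if (l, m) == (0, 0):
        return np.full(len(u), 0.5 * SQRT(1 / pi))
    if (l, m) == (1, -1):
        return SQRT(3 / (4 * pi)) * y
    if (l, m) == (1, 0):
        return SQRT(3 / (4 * pi)) * z
    if (l, m) == (1, 1):
        return SQRT(3 / (4 * pi)) * x
    if (l, m) == (2, -2):
        return 0.5 * SQRT(15 / pi) * x * y
    if (l, m) == (2, -1):
        return 0.5 * SQRT(15 / pi) * y * z
    if (l, m) == (2, 0):
        return 0.25 * SQRT(5 / pi) * (3 * z ** 2 - 1)
    if (l, m) == (2, 1):
        return 0.5 * SQRT(15 / pi) * x * z
    if (l, m) == (2, 2):
        return 0.25 * SQRT(15 / pi) * (x ** 2 - y ** 2)
    raise ValueError((l, m))


def brute_force_descriptor(coords, l_max, cutoff):
    coords = np.asarray(coords, float)
    out = np.full(len(coords), 1.0 / (4 * np.pi))
    for i in range(len(coords)):
        diff = np.delete(coords, i, axis=0) - coords[i]
        dist = np.linalg.norm(diff, axis=1)
        sel = dist <= cutoff
        if not sel.any():
            continue
        u = diff[sel] / dist[sel][:, None]
        total = 0.0
        for l in range(l_max + 1):
            for m in range(-l, l + 1):
                total += float(np.mean(real_sh_cartesian(l, m, u))) ** 2
        out[i] = total
    return out


def test_lmax0_descriptor_is_constant():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(9, 3)) * 1.5
    d = gb.spherical_harmonics_descriptor(
        coords, SphericalHarmonicSpec(l_max=0, neighbor_cutoff=4.0))
    assert np.allclose(d, (1.0 / np.sqrt(4 * np.pi)) ** 2)


def test_isolated_atom_keeps_constant_term():
    coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    d = gb.spherical_harmonics_descriptor(
        coords, SphericalHarmonicSpec(l_max=2, neighbor_cutoff=4.0))
    assert np.allclose(d, 1.0 / (4 * np.pi))


def test_tetrahedral_matches_brute_force():
    center = np.zeros(3)
    tet = 1.5 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    coords = np.vstack([center, tet])
    spec = SphericalHarmonicSpec(l_max=2, neighbor_cutoff=4.0)
    d = gb.spherical_harmonics_descriptor(coords, spec)
    expect = brute_force_descriptor(coords, 2, 4.0)
    np.testing.assert_allclose(d, expect, rtol=1e-10, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_cloud_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(8, 3)) * 2.0
    spec = SphericalHarmonicSpec(l_max=2, neighbor_cutoff=4.0)
    np.testing.assert_allclose(gb.spherical_harmonics_descriptor(coords, spec),
                               brute_force_descriptor(coords, 2, 4.0),
                               rtol=1e-10, atol=1e-12)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_rotation_invariance(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(12, 3)) * 2.0
    R = Rotation.random(random_state=seed).as_matrix()
    spec = SphericalHarmonicSpec(l_max=2, neighbor_cutoff=4.0)
    d0 = gb.spherical_harmonics_descriptor(coords, spec)
    d1 = gb.spherical_harmonics_descriptor(coords @ R.T, spec)
    assert np.max(np.abs(d1 - d0) / np.abs(d0)) < 1e-8
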