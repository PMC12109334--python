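"""Geometric atomic descriptors: Voronoi cell volumes and spherical harmonics.

Two pose-describing per-atom scalars supplement the usual chemical node
features:

* **Voronoi volume** — space is partitioned into cells, each cell holding the
  points nearer its atom than any other atom, V(p_i) = {x : |x-p_i| <= |x-p_j|
  for all j != i}.  Infinite outer cells are bounded by clipping against the
  structure's axis-aligned bounding box expanded by ``clip_margin``; the
  reported scalar is the clipped cell volume in A^3.  The clipped cells tile
  the clip box exactly, so the volumes sum to the box volume — the key
  conservation invariant used in testing.

* **Spherical-harmonics power** — for each atom, unit direction vectors to
  all neighbours within ``neighbor_cutoff`` are expanded in real spherical
  harmonics Y_lm up to ``l_max``; the descriptor is the rotation-invariant
  power aggregate sum_l sum_m (mean_n Y_lm(theta_n, phi_n))^2.  Because a
  rotation mixes the Y_lm of fixed degree l by an orthogonal matrix, the
  aggregate is unchanged under rigid rotation of the structure.  An atom with
  no neighbours keeps only the constant l=0 term (1/sqrt(4 pi))^2.

Cell volumes are computed exactly: each cell is the intersection of the
bisector half-spaces against its (Delaunay-) neighbouring sites with the six
clip-box faces, evaluated with scipy's HalfspaceIntersection/ConvexHull.
This closed-form route also covers the degenerate cases (single site,
collinear or coplanar sites) that a tessellation-based route cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, HalfspaceIntersection, QhullError
from scipy.special import sph_harm_y

from .errors import DegenerateSiteError

__all__ = [
    "VoronoiSpec",
    "SphericalHarmonicSpec",
    "voronoi_descriptor",
    "spherical_harmonics_descriptor",
    "real_sph_harm",
]


@dataclass(frozen=True)
class VoronoiSpec:
    """Clip-box control for bounding infinite Voronoi cells.

    clip_margin : A added around the structure's axis-aligned bounding box.
    """

    clip_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.clip_margin <= 0:
            raise ValueError("clip_margin must be positive")


@dataclass(frozen=True)
class SphericalHarmonicSpec:
    """Degree limit and neighbourhood radius for the SH power descriptor."""

    l_max: int = 2
    neighbor_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.neighbor_cutoff <= 0:
            raise ValueError("neighbor_cutoff must be positive")


def _clip_box(coords: np.ndarray, margin: float) -> tuple[np.ndarray, np.ndarray]:
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    return lo, hi


def _box_halfspaces(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Six inequalities A x + b <= 0 describing [lo, hi]^3."""
    hs = []
    for axis in range(3):
        n = np.zeros(3)
        n[axis] = 1.0
        hs.append(np.append(n, -hi[axis]))    # x_axis <= hi
        hs.append(np.append(-n, lo[axis]))    # x_axis >= lo
    return np.array(hs)


def _neighbor_lists(coords: np.ndarray) -> list[set[int]]:
    """Candidate bisector partners per site.

    Delaunay vertex adjacency is a superset of Voronoi facet adjacency, so
    restricting each cell's bisectors to Delaunay neighbours is exact while
    avoiding the quadratic all-pairs set; degenerate inputs (few or
    coplanar sites) fall back to all pairs.
    """
    n = len(coords)
    all_pairs = [set(range(n)) - {i} for i in range(n)]
    if n < 5:
        return all_pairs
    try:
        tri = Delaunay(coords)
    except QhullError:
        return all_pairs
    indptr, indices = tri.vertex_neighbor_vertices
    neigh: list[set[int]] = []
    for i in range(n):
        s = set(indices[indptr[i]:indptr[i + 1]].tolist())
        neigh.append(s if s else all_pairs[i])
    return neigh


def voronoi_descriptor(coords: np.ndarray, spec: VoronoiSpec | None = None) -> np.ndarray:
    """Clipped Voronoi cell volume (A^3) for every atom site.

    Parameters
    ----------
    coords : (n, 3) array of atom positions; no two may coincide.
    spec : clip-box margin; defaults to 5 A.

    Returns
    -------
    (n,) array of positive volumes summing to the clip-box volume.
    """
    spec = spec or VoronoiSpec()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one site")
    if n > 1:
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 1e-12:
            i, j = np.unravel_index(int(d2.argmin()), d2.shape)
            raise DegenerateSiteError(f"sites {i} and {j} coincide")
    lo, hi = _clip_box(coords, spec.clip_margin)
    box_hs = _box_halfspaces(lo, hi)
    if n == 1:
        return np.array([float(np.prod(hi - lo))])
    neighbors = _neighbor_lists(coords)
    volumes = np.empty(n)
    for i in range(n):
        rows = [box_hs]
        for j in sorted(neighbors[i]):
            normal = coords[j] - coords[i]
            norm = np.linalg.norm(normal)
            normal = normal / norm
            mid = 0.5 * (coords[i] + coords[j])
            # points x with normal.(x - mid) <= 0 are on site i's side
            rows.append(np.append(normal, -float(normal @ mid)))
        hs = np.vstack(rows)
        inter = HalfspaceIntersection(hs, coords[i].copy())
        volumes[i] = ConvexHull(inter.intersections).volume
    return volumes


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-form spherical harmonic Y_lm(theta, phi).

    theta is the polar angle from +z, phi the azimuth.  Real forms follow the
    standard construction from the complex harmonics: for m > 0 the cosine
    combination, for m < 0 the sine combination, both carrying sqrt(2).
    """
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def spherical_harmonics_descriptor(coords: np.ndarray,
                                   spec: SphericalHarmonicSpec | None = None) -> np.ndarray:
    """Rotation-invariant SH power aggregate per atom.

    For atom i with neighbour directions {u_n} (|u_n - 0| = 1, neighbours are
    all atoms within ``spec.neighbor_cutoff``):

        D_i = sum_{l=0}^{l_max} sum_{m=-l}^{l} ( mean_n Y_lm(u_n) )^2

    Atoms with no neighbours in range get only the l = 0 constant term,
    (1 / sqrt(4 pi))^2.
    """
    spec = spec or SphericalHarmonicSpec()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    n = len(coords)
    l0_term = 1.0 / (4.0 * np.pi)  # (Y_00)^2 with Y_00 = 1/sqrt(4 pi)
    out = np.full(n, l0_term)
    if n == 1:
        return out
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n):
        mask = (dist[i] > 1e-9) & (dist[i] <= spec.neighbor_cutoff)
        if not mask.any():
            continue
        v = diff[i][mask]
        r = dist[i][mask]
        u = v / r[:, None]
        theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
        phi = np.arctan2(u[:, 1], u[:, 0])
        total = 0.0
        for l in range(spec.l_max + 1):
            for m in range(-l, l + 1):
                total += float(np.mean(real_sph_harm(l, m, theta, phi))) ** 2
        out[i] = total
    return out
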