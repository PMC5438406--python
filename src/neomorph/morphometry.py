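"""Morphometric descriptors from tissue label volumes.

From one 8-class label volume this module computes the image-derived part
of the 14-descriptor vector:

* eight relative tissue volumes (per-class voxel count x voxel volume,
  normalised by total intracranial volume) and the total intracranial
  volume itself (descriptor ``BV``);
* inner cortical surface area (``ISA``) — area of the cGM/cerebral-interior
  interface;
* gyrification index (``GI``) — ratio of the inner surface area to the
  area of its convex hull (1 for a convex brain, larger when folded);
* global mean curvature (``MC``) — area-weighted average of the magnitude
  of discrete mean curvature over the inner surface, units 1/mm;
* median cortical thickness (``MT``) — median distance from inner-surface
  vertices to the outer cortical surface.

Surface measures are computed on meshes extracted in physical mm
coordinates after nearest-neighbour resampling to an isotropic grid
(default 0.5 mm), so that thick-slice acquisitions (e.g. 2 mm) do not
bias the geometry.  Volumes are counted on the native grid, which is
unbiased regardless of anisotropy.

The iso-surface is taken at level 0.5 of the Gaussian-smoothed (sigma =
one voxel) binary mask rather than of the raw mask: marching cubes on a
raw binary mask yields a staircase surface whose area overestimates a
smooth anatomical boundary by several percent and does not converge
under grid refinement, while the smoothed-indicator level set recovers
smooth-surface areas to well under 1% at 0.5 mm resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .label_io import LabelVolume, TISSUE_CODES, TISSUE_NAMES

__all__ = [
    "TriangleSurface",
    "DescriptorVector",
    "tissue_volumes",
    "extract_inner_surface",
    "extract_outer_surface",
    "surface_area",
    "gyrification_index",
    "global_mean_curvature",
    "median_cortical_thickness",
    "compute_descriptors",
]

#: classes forming the cerebral interior (the region the inner cortical
#: surface encloses): white matter, deep grey and the ventricles; the
#: ventricles must be included so they do not puncture the surface.
INTERIOR_CLASSES = ("uWM", "mWM", "BGT", "vCSF")

#: documented mesh-discretization slack on the GI >= 1 invariant
EPS_MESH = 0.02

_DEFAULT_ISO = 0.5  # mm, isotropic resampling target for surface work


@dataclass
class TriangleSurface:
    """A closed, outward-oriented triangle mesh in physical mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) < 4:
            raise ValueError("vertices must be an (n>=4, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3 or len(self.faces) < 4:
            raise ValueError("faces must be an (m>=4, 3) array of vertex indices")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, validate: bool = True) -> "TriangleSurface":
        if validate:
            if not mesh.is_watertight:
                raise ValueError("surface is not watertight")
            if mesh.volume <= 0:
                raise ValueError("surface is not consistently outward-oriented")
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))

    @property
    def enclosed_volume(self) -> float:
        """Signed enclosed volume in mm^3 (positive for outward orientation)."""
        return float(self.as_trimesh().volume)

    def scaled(self, factor: float) -> "TriangleSurface":
        return TriangleSurface(vertices=self.vertices * factor, faces=self.faces)


@dataclass
class DescriptorVector:
    """The 14 descriptors of one subject at one timepoint.

    Relative volumes are dimensionless fractions summing to 1;
    ``brain_volume`` is the total intracranial volume in mm^3; ``isa`` in
    mm^2; ``gi`` dimensionless; ``mean_curvature`` in 1/mm;
    ``median_thickness`` in mm; ``ga_birth`` in weeks.
    """

    ga_birth: float
    rel_uWM: float
    rel_mWM: float
    rel_cGM: float
    rel_vCSF: float
    rel_eCSF: float
    rel_CB: float
    rel_BGT: float
    rel_BS: float
    brain_volume: float
    isa: float
    gi: float
    mean_curvature: float
    median_thickness: float

    def __post_init__(self) -> None:
        rel = [getattr(self, f"rel_{t}") for t in TISSUE_NAMES]
        if any(not 0.0 <= v <= 1.0 for v in rel):
            raise ValueError("relative volumes must lie in [0, 1]")
        if abs(sum(rel) - 1.0) > 1e-9:
            raise ValueError(f"relative volumes sum to {sum(rel)!r}, not 1")
        if self.gi < 1.0 - EPS_MESH:
            raise ValueError(f"gyrification index {self.gi} below 1 - eps_mesh")
        for name in ("isa", "brain_volume", "mean_curvature", "median_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict[str, float]:
        """Values keyed by the canonical descriptor names (Table order)."""
        return {
            "GA": self.ga_birth,
            "CB": self.rel_CB,
            "mWM": self.rel_mWM,
            "BGT": self.rel_BGT,
            "vCSF": self.rel_vCSF,
            "uWM": self.rel_uWM,
            "BS": self.rel_BS,
            "cGM": self.rel_cGM,
            "eCSF": self.rel_eCSF,
            "ISA": self.isa,
            "MC": self.mean_curvature,
            "GI": self.gi,
            "MT": self.median_thickness,
            "BV": self.brain_volume,
        }


def tissue_volumes(vol: LabelVolume) -> dict[str, float]:
    """Absolute per-class volumes (mm^3), intracranial total and fractions.

    Returns keys ``vol_<tissue>`` (mm^3), ``rel_<tissue>`` (fractions
    summing to 1) and ``intracranial_volume``.  Volumes are voxel counts
    on the native grid times the voxel volume.
    """
    counts = np.bincount(vol.grid.ravel(), minlength=9)
    if counts[1:].sum() == 0:
        raise ValueError("label volume has no non-background voxels")
    vv = vol.voxel_volume
    out: dict[str, float] = {}
    total = float(counts[1:].sum()) * vv
    for code, name in TISSUE_CODES.items():
        out[f"vol_{name}"] = float(counts[code]) * vv
        out[f"rel_{name}"] = float(counts[code]) / float(counts[1:].sum())
    out["intracranial_volume"] = total
    return out


def _resample_isotropic(mask: np.ndarray, spacing: tuple[float, float, float],
                        iso: float) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Nearest-neighbour resample a binary mask to ~iso mm voxels.

    Returns the mask and the *effective* spacing of the resampled grid
    (exact rational spacing, so downstream geometry stays unbiased).
    """
    if np.allclose(spacing, iso, rtol=1e-6):
        return mask, spacing
    factors = tuple(s / iso for s in spacing)
    res = ndimage.zoom(mask.astype(np.uint8), zoom=factors, order=0)
    eff = tuple(n_in * s / n_out for n_in, s, n_out in zip(mask.shape, spacing, res.shape))
    return res.astype(bool), eff


def _mesh_from_mask(mask: np.ndarray, spacing: tuple[float, float, float],
                    smooth_sigma_mm: float = 0.5) -> trimesh.Trimesh:
    """Extract the closed iso-surface of a binary mask in mm coordinates.

    The indicator is smoothed at a fixed *physical* scale (default
    0.5 mm) before taking the 0.5 level set, so the surface — and every
    measure on it — is defined in scale space rather than voxel space
    and converges under grid refinement.
    """
    if not mask.any():
        raise ValueError("empty mask: no surface to extract")
    padded = np.pad(mask.astype(np.float32), 1)
    if smooth_sigma_mm > 0:
        sigma_vox = tuple(smooth_sigma_mm / s for s in spacing)
        padded = ndimage.gaussian_filter(padded, sigma=sigma_vox)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts -= np.asarray(spacing)  # undo the 1-voxel pad offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if mesh.body_count > 1:  # keep the principal component only
        mesh = max(mesh.split(only_watertight=False), key=lambda m: len(m.faces))
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
    if not mesh.is_watertight:
        raise ValueError("extracted surface is not watertight after cleaning")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _interior_mask(vol: LabelVolume) -> np.ndarray:
    codes = [TISSUE_NAMES[t] for t in INTERIOR_CLASSES]
    mask = np.isin(vol.grid, codes)
    if not mask.any():
        raise ValueError("no cerebral interior voxels (uWM/mWM/BGT/vCSF)")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def extract_inner_surface(vol: LabelVolume, iso: float = _DEFAULT_ISO) -> TriangleSurface:
    """Inner cortical surface: closed boundary of the cerebral interior.

    The interior is the largest connected component of
    uWM + mWM + BGT + vCSF with holes filled (ventricles included so the
    surface is not punctured); the boundary is the 0.5 level set after
    isotropic resampling, in physical mm coordinates.
    """
    if not (vol.grid == TISSUE_NAMES["cGM"]).any():
        raise ValueError("volume contains no cortical grey matter")
    mask, spacing = _resample_isotropic(_interior_mask(vol), vol.spacing, iso)
    return TriangleSurface.from_trimesh(_mesh_from_mask(mask, spacing))


def extract_outer_surface(vol: LabelVolume, iso: float = _DEFAULT_ISO) -> TriangleSurface:
    """Outer cortical surface: boundary of (cerebral interior + cGM)."""
    inner = _interior_mask(vol)
    mask = ndimage.binary_fill_holes(inner | (vol.grid == TISSUE_NAMES["cGM"]))
    mask, spacing = _resample_isotropic(mask, vol.spacing, iso)
    return TriangleSurface.from_trimesh(_mesh_from_mask(mask, spacing))


def surface_area(surf: TriangleSurface) -> float:
    """Total mesh area in mm^2 (sum of triangle areas)."""
    return float(surf.as_trimesh().area)


def gyrification_index(surf: TriangleSurface) -> float:
    """Surface area divided by the area of the vertex convex hull."""
    mesh = surf.as_trimesh()
    try:
        hull_area = float(mesh.convex_hull.area)
    except Exception as exc:  # qhull failure on degenerate input
        raise ValueError(f"convex hull construction failed: {exc}") from exc
    return float(mesh.area) / hull_area


def _cotangent_mean_curvature(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex |H| (1/mm) from the cotangent Laplacian, with vertex areas.

    Uses the mean-curvature normal K_i = (1/2A_i) sum_j (cot a + cot b)
    (x_i - x_j) with barycentric vertex areas A_i; |H_i| = |K_i| / 2.
    """
    V, F = mesh.vertices, mesh.faces
    i0, i1, i2 = F[:, 0], F[:, 1], F[:, 2]
    e0 = V[i2] - V[i1]  # edge opposite corner 0, etc.
    e1 = V[i0] - V[i2]
    e2 = V[i1] - V[i0]

    def cot(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        return np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-12)

    cot0, cot1, cot2 = cot(-e1, e2), cot(-e2, e0), cot(-e0, e1)

    n = len(V)
    S = np.zeros((n, 3))
    # edge (i1,i2) opposite corner 0 carries weight cot0, etc.
    for (a, b), w in (((i1, i2), cot0), ((i2, i0), cot1), ((i0, i1), cot2)):
        contrib = w[:, None] * (V[a] - V[b])
        np.add.at(S, a, contrib)
        np.add.at(S, b, -contrib)

    areas = np.zeros(n)
    fa = mesh.area_faces / 3.0
    for idx in (i0, i1, i2):
        np.add.at(areas, idx, fa)
    areas = np.maximum(areas, 1e-12)
    K = S / (2.0 * areas[:, None])
    return np.linalg.norm(K, axis=1) / 2.0, areas


def global_mean_curvature(surf: TriangleSurface, smooth_iterations: int = 10,
                          smooth_lambda: float = 0.5) -> float:
    """Area-weighted average of |H| over the surface, in 1/mm.

    The mesh is Laplacian-smoothed (default 10 iterations, lambda 0.5,
    volume-preserving) before evaluating the discrete cotangent-Laplacian
    curvature, since the raw voxelized surface is noise-dominated; for a
    sphere of radius r the result approaches 1/r.
    """
    mesh = surf.as_trimesh().copy()
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            mesh, lamb=smooth_lambda, iterations=smooth_iterations
        )
    h, areas = _cotangent_mean_curvature(mesh)
    return float(np.average(h, weights=areas))


def _point_surface_distance(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Distance from points to the mesh surface.

    Nearest-vertex search (k-d tree) refined by exact point-to-triangle
    distance over the faces incident to each nearest vertex; exact
    whenever the true closest face touches the nearest vertex, which
    holds to well below mesh resolution on the dense meshes used here.
    """
    tree = cKDTree(mesh.vertices)
    d_vertex, idx = tree.query(points)
    vf = mesh.vertex_faces[idx]  # (n, max_degree), padded with -1
    n, deg = vf.shape
    flat = vf.ravel()
    valid = flat >= 0
    tri = mesh.triangles[flat[valid]]
    pts = np.repeat(points, deg, axis=0)[valid]
    closest = trimesh.triangles.closest_point(tri, pts)
    d = np.full(n * deg, np.inf)
    d[valid] = np.linalg.norm(closest - pts, axis=1)
    d_face = d.reshape(n, deg).min(axis=1)
    return np.minimum(d_vertex, d_face)


def median_cortical_thickness(inner: TriangleSurface, outer: TriangleSurface) -> float:
    """Median distance from inner-surface vertices to the outer surface.

    One-sided (inner -> outer) nearest-point distance; symmetric
    averaging can be obtained by calling this twice and averaging.
    """
    d = _point_surface_distance(outer.as_trimesh(), inner.vertices)
    return float(np.median(d))


def compute_descriptors(vol: LabelVolume, ga_birth: float,
                        iso: float = _DEFAULT_ISO) -> DescriptorVector:
    """Assemble the full 14-descriptor vector from one label volume."""
    vols = tissue_volumes(vol)
    inner = extract_inner_surface(vol, iso=iso)
    outer = extract_outer_surface(vol, iso=iso)
    return DescriptorVector(
        ga_birth=float(ga_birth),
        rel_uWM=vols["rel_uWM"], rel_mWM=vols["rel_mWM"], rel_cGM=vols["rel_cGM"],
        rel_vCSF=vols["rel_vCSF"], rel_eCSF=vols["rel_eCSF"], rel_CB=vols["rel_CB"],
        rel_BGT=vols["rel_BGT"], rel_BS=vols["rel_BS"],
        brain_volume=vols["intracranial_volume"],
        isa=surface_area(inner),
        gi=gyrification_index(inner),
        mean_curvature=global_mean_curvature(inner),
        median_thickness=median_cortical_thickness(inner, outer),
    )
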