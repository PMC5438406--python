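"""Morphometric operators against analytic and brute-force oracles."""

import numpy as np
import pytest
import trimesh

from neomorph import (
    LabelVolume,
    PhantomSpec,
    compute_descriptors,
    make_phantom,
    tissue_volumes,
)
from neomorph.morphometry import (
    TriangleSurface,
    extract_inner_surface,
    extract_outer_surface,
    global_mean_curvature,
    gyrification_index,
    median_cortical_thickness,
    surface_area,
)

TISSUES = ("uWM", "mWM", "cGM", "vCSF", "eCSF", "CB", "BGT", "BS")


# ---------------------------------------------------------------- volumes

def test_uniform_block_volume():
    vol = LabelVolume(grid=np.ones((10, 10, 10), dtype=np.int16), spacing=(1, 1, 1))
    tv = tissue_volumes(vol)
    assert tv["vol_uWM"] == pytest.approx(1000.0)
    assert tv["rel_uWM"] == 1.0
    assert all(tv[f"rel_{t}"] == 0.0 for t in TISSUES if t != "uWM")


def test_fractions_sum_to_one_and_match_naive_count(rng):
    grid = rng.integers(0, 9, size=(9, 11, 7), dtype=np.int16)
    grid[0, 0, 0] = 1  # guarantee non-empty foreground
    vol = LabelVolume(grid=grid, spacing=(0.7, 0.9, 1.3))
    tv = tissue_volumes(vol)
    assert sum(tv[f"rel_{t}"] for t in TISSUES) == pytest.approx(1.0, abs=1e-9)
    vv = 0.7 * 0.9 * 1.3
    for code, t in enumerate(TISSUES, start=1):
        naive = sum(
            1
            for i in range(9) for j in range(11) for k in range(7)
            if grid[i, j, k] == code
        )
        assert tv[f"vol_{t}"] == pytest.approx(naive * vv)


def test_empty_volume_rejected():
    vol = LabelVolume(grid=np.zeros((5, 5, 5), dtype=np.int16), spacing=(1, 1, 1))
    with pytest.raises(ValueError, match="non-background"):
        tissue_volumes(vol)


# --------------------------------------------------------------- surfaces

def test_unit_cube_area():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    surf = TriangleSurface(vertices=np.asarray(box.vertices), faces=np.asarray(box.faces))
    assert surface_area(surf) == pytest.approx(6.0)


def test_sphere_phantom_inner_surface_oracles(sphere_phantom, sphere_surfaces):
    _, truth = sphere_phantom
    inner, outer = sphere_surfaces
    assert surface_area(inner) == pytest.approx(truth["ISA"], rel=0.02)
    assert inner.enclosed_volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.02)
    assert gyrification_index(inner) == pytest.approx(1.0, abs=0.02)
    assert global_mean_curvature(inner) == pytest.approx(0.05, rel=0.10)
    assert median_cortical_thickness(inner, outer) == pytest.approx(3.0, rel=0.10)


def test_scaling_laws(sphere_surfaces):
    """Area ~ s^2, enclosed volume ~ s^3, curvature ~ 1/s, GI invariant."""
    inner, _ = sphere_surfaces
    doubled = inner.scaled(2.0)
    assert surface_area(doubled) == pytest.approx(4.0 * surface_area(inner), rel=1e-9)
    assert doubled.enclosed_volume == pytest.approx(8.0 * inner.enclosed_volume, rel=1e-9)
    assert global_mean_curvature(doubled) == pytest.approx(
        0.5 * global_mean_curvature(inner), rel=0.02
    )
    assert gyrification_index(doubled) == pytest.approx(
        gyrification_index(inner), rel=0.01
    )


def test_curvature_on_smooth_spheres_and_radius_ordering():
    """Cotangent-Laplacian |H| approaches 1/r on analytic sphere meshes."""
    estimates = {}
    for r in (10.0, 20.0):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=r)
        surf = TriangleSurface(np.asarray(ico.vertices), np.asarray(ico.faces))
        estimates[r] = global_mean_curvature(surf, smooth_iterations=0)
        assert estimates[r] == pytest.approx(1.0 / r, rel=0.10)
    assert estimates[10.0] > estimates[20.0]


def test_thickness_on_concentric_icospheres():
    inner = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    outer = trimesh.creation.icosphere(subdivisions=4, radius=23.0)
    si = TriangleSurface(np.asarray(inner.vertices), np.asarray(inner.faces))
    so = TriangleSurface(np.asarray(outer.vertices), np.asarray(outer.faces))
    assert median_cortical_thickness(si, so) == pytest.approx(3.0, rel=0.01)
    assert median_cortical_thickness(si, si) == pytest.approx(0.0, abs=1e-9)


def test_disconnected_island_excluded():
    """A far 1-voxel interior island must not break watertightness."""
    grid = np.zeros((40, 40, 40), dtype=np.int16)
    grid[5:20, 5:20, 5:20] = 1        # uWM block
    grid[20:22, 5:20, 5:20] = 3       # cGM cap so extraction precondition holds
    grid[35, 35, 35] = 1              # island
    vol = LabelVolume(grid=grid, spacing=(1.0, 1.0, 1.0))
    inner = extract_inner_surface(vol)
    mesh = inner.as_trimesh()
    assert mesh.is_watertight
    # enclosed volume is about the block only, nowhere near block + island corner
    assert inner.enclosed_volume == pytest.approx(15.0**3, rel=0.15)
    assert mesh.vertices[:, 0].max() < 25.0


def test_missing_cortex_is_an_error():
    grid = np.zeros((10, 10, 10), dtype=np.int16)
    grid[2:8, 2:8, 2:8] = 1
    vol = LabelVolume(grid=grid, spacing=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="cortical grey"):
        extract_inner_surface(vol)


def test_ventricles_do_not_puncture_inner_surface():
    """vCSF/BGT are interior classes: the surface encloses them."""
    grid = np.zeros((40, 40, 40), dtype=np.int16)
    grid[5:25, 5:25, 5:25] = 1
    grid[12:18, 12:18, 12:18] = 4     # ventricle inside the white matter
    grid[25:27, 5:25, 5:25] = 3
    vol = LabelVolume(grid=grid, spacing=(1.0, 1.0, 1.0))
    inner = extract_inner_surface(vol)
    assert inner.enclosed_volume == pytest.approx(20.0**3, rel=0.15)


# ------------------------------------------------------------ descriptors

def test_descriptor_vector_composition_and_determinism(coarse_phantom):
    vol, _ = coarse_phantom
    a = compute_descriptors(vol, ga_birth=26.5, iso=1.0)
    b = compute_descriptors(vol, ga_birth=26.5, iso=1.0)
    assert a == b
    assert a.ga_birth == 26.5
    d = a.as_dict()
    assert set(d) == {
        "GA", "CB", "mWM", "BGT", "vCSF", "uWM", "BS", "cGM", "eCSF",
        "ISA", "MC", "GI", "MT", "BV",
    }
    rel_sum = sum(d[k] for k in ("CB", "mWM", "BGT", "vCSF", "uWM", "BS", "cGM", "eCSF"))
    assert rel_sum == pytest.approx(1.0, abs=1e-9)


def test_descriptors_converge_under_grid_refinement(sphere_phantom):
    """Halving the voxel size changes each geometric descriptor by < 2%."""
    vol05, _ = sphere_phantom
    d05 = compute_descriptors(vol05, 26.5, iso=0.5)
    vol025, _ = make_phantom(PhantomSpec(spacing=(0.25,) * 3, shape=(360,) * 3))
    d025 = compute_descriptors(vol025, 26.5, iso=0.25)
    for name in ("isa", "gi", "mean_curvature", "median_thickness", "brain_volume"):
        lo, hi = getattr(d05, name), getattr(d025, name)
        assert abs(lo / hi - 1.0) < 0.02, name


def test_anisotropic_volume_is_resampled_not_rejected():
    """The 0.34 x 0.34 x 2.0 mm acquisition geometry runs end to end."""
    vol, truth = make_phantom(PhantomSpec.anisotropic_30wk())
    d = compute_descriptors(vol, 26.5)
    # thick slices leave a residual staircase bias; sanity bounds only
    assert d.isa == pytest.approx(truth["ISA"], rel=0.15)
    assert d.median_thickness == pytest.approx(3.0, rel=0.15)
    assert d.gi == pytest.approx(1.0, abs=0.10)
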