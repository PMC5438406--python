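"""Synthetic inputs with known ground truth.

Two generators:

* **Geometric brain phantoms** — concentric-sphere label volumes carrying
  all eight tissue classes, with closed-form volumes, inner cortical
  surface area (4*pi*r^2), gyrification index (1 for the convex case),
  global mean curvature (1/r) and cortical thickness.  A sinusoidal
  radial fold turns the cortex non-convex with a controllable
  gyrification increase.
* **Simulated cohorts** — two-class tables of the 14 descriptors drawn
  from class-conditional Gaussians with configurable standardized mean
  shifts, so the theoretical single-descriptor AUC is the closed form
  Phi(delta / sqrt(sigma0^2 + sigma1^2)).  Bayley composite scores are
  generated on the correct side of the 85 cut-off so that labeling the
  scores reproduces the drawn classes exactly, and positive counts can
  be fixed exactly to mirror printed cohort prevalences.

Default phantom geometry (mm, centred coordinates): basal ganglia and
thalami core r=6; ventricular CSF shell [6,8); unmyelinated white matter
shell [8,20) with an embedded myelinated-WM sphere r=3 at (0,0,14);
cortical grey matter shell [20,23); extracerebral CSF shell [23,26);
cerebellum sphere r=6 at (0,0,-36); brain stem sphere r=2.5 at
(0,0,-28.5).  Later structures overwrite earlier ones, so the brain stem
wins its small lens of overlap with the cerebellum; the closed-form
volumes include that correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .features import DESCRIPTORS, CohortTable, label_low_outcome
from .label_io import LabelVolume, TISSUE_NAMES

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "simulate_cohort",
    "theoretical_auc",
    "parametric_fold_mesh",
]

# fixed phantom geometry (mm)
_R_BGT = 6.0
_R_VCSF = 8.0
_R_INNER = 20.0  # uWM/cGM interface for a = 0
_R_OUTER = 23.0  # cGM/eCSF interface for a = 0
_R_ECSF = 26.0
_R_MWM, _C_MWM = 3.0, np.array([0.0, 0.0, 14.0])
_R_CB, _C_CB = 6.0, np.array([0.0, 0.0, -36.0])
_R_BS, _C_BS = 2.5, np.array([0.0, 0.0, -28.5])
_MAX_EXTENT = abs(_C_CB[2]) + _R_CB  # 42 mm: outermost structure reach

#: fixed sub-voxel lattice registration (fractions of one voxel).  The
#: phantom's structures all sit on the z axis; sampling them on a lattice
#: symmetric about that axis produces correlated ring-shaped
#: discretization errors that do not self-average, so the lattice is
#: deliberately offset by fixed irrational voxel fractions.
_LATTICE_OFFSET = (0.381966, 0.267949, 0.176471)


@dataclass
class PhantomSpec:
    """Parameters of the geometric brain phantom.

    ``fold_amplitude`` (mm) and ``fold_frequency`` modulate both cortical
    boundaries radially by ``a * sin(k*theta) * sin(k*phi)``, keeping the
    cortical ribbon at a constant 3 mm radial width; amplitude 0
    reproduces the concentric-sphere phantom exactly.
    """

    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    shape: tuple[int, int, int] = (180, 180, 180)
    fold_amplitude: float = 0.0
    fold_frequency: int = 6

    @classmethod
    def anisotropic_30wk(cls, fold_amplitude: float = 0.0) -> "PhantomSpec":
        """Preset emulating the 0.34 x 0.34 x 2.0 mm acquisition geometry."""
        return cls(spacing=(0.34, 0.34, 2.0), shape=(266, 266, 46),
                   fold_amplitude=fold_amplitude)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 2 for n in self.shape):
            raise ValueError("spacing must be positive and shape at least 2 voxels per axis")
        if self.fold_amplitude < 0:
            raise ValueError("fold amplitude must be non-negative")
        half = min(n * s for n, s in zip(self.shape, self.spacing)) / 2.0
        if half < _MAX_EXTENT + self.fold_amplitude:
            raise ValueError(
                f"field of view half-extent {half:.1f} mm cannot contain the "
                f"phantom structures (need >= {_MAX_EXTENT + self.fold_amplitude:.1f} mm)"
            )


def _sphere_vol(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


def _lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of intersection of two spheres via the two-cap formula."""
    if d >= r1 + r2:
        return 0.0
    x1 = (d * d - r2 * r2 + r1 * r1) / (2.0 * d)
    h1, h2 = r1 - x1, r2 - (d - x1)
    cap = lambda r, h: np.pi * h * h * (3.0 * r - h) / 3.0
    return float(cap(r1, h1) + cap(r2, h2))


def analytic_expectations() -> dict[str, float]:
    """Closed-form descriptor values for the unfolded (a = 0) phantom.

    Tissue volumes in mm^3 with the cerebellum/brain-stem overlap
    assigned to the brain stem (voxelization precedence); morphometric
    values from sphere geometry.
    """
    lens = _lens_volume(_R_CB, _R_BS, float(np.linalg.norm(_C_CB - _C_BS)))
    vols = {
        "BGT": _sphere_vol(_R_BGT),
        "vCSF": _sphere_vol(_R_VCSF) - _sphere_vol(_R_BGT),
        "mWM": _sphere_vol(_R_MWM),
        "uWM": _sphere_vol(_R_INNER) - _sphere_vol(_R_VCSF) - _sphere_vol(_R_MWM),
        "cGM": _sphere_vol(_R_OUTER) - _sphere_vol(_R_INNER),
        "eCSF": _sphere_vol(_R_ECSF) - _sphere_vol(_R_OUTER),
        "CB": _sphere_vol(_R_CB) - lens,
        "BS": _sphere_vol(_R_BS),
    }
    total = sum(vols.values())
    out = {f"vol_{k}": v for k, v in vols.items()}
    out.update({f"rel_{k}": v / total for k, v in vols.items()})
    out.update(
        intracranial_volume=total,
        ISA=4.0 * np.pi * _R_INNER**2,
        GI=1.0,
        MC=1.0 / _R_INNER,
        MT=_R_OUTER - _R_INNER,
    )
    return out


def _labels_at(X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
               spec: PhantomSpec) -> np.ndarray:
    """Continuous phantom label at arbitrary points (precedence order)."""
    r = np.sqrt(X * X + Y * Y + Z * Z)
    if spec.fold_amplitude > 0:
        theta = np.arccos(np.clip(Z / np.maximum(r, 1e-12), -1.0, 1.0))
        phi = np.arctan2(Y, X)
        f = spec.fold_amplitude * np.sin(spec.fold_frequency * theta) * np.sin(
            spec.fold_frequency * phi
        )
        f = np.where(r == 0, 0.0, f)
    else:
        f = 0.0
    r_inner = _R_INNER + f
    r_outer = _R_OUTER + f

    lbl = np.zeros(r.shape, dtype=np.int8)
    # structure-list order; later assignments overwrite earlier ones
    lbl[r < _R_BGT] = TISSUE_NAMES["BGT"]
    lbl[(r >= _R_BGT) & (r < _R_VCSF)] = TISSUE_NAMES["vCSF"]
    lbl[(r >= _R_VCSF) & (r < r_inner)] = TISSUE_NAMES["uWM"]
    d2 = (X - _C_MWM[0]) ** 2 + (Y - _C_MWM[1]) ** 2 + (Z - _C_MWM[2]) ** 2
    lbl[d2 < _R_MWM**2] = TISSUE_NAMES["mWM"]
    lbl[(r >= r_inner) & (r < r_outer)] = TISSUE_NAMES["cGM"]
    lbl[(r >= r_outer) & (r < _R_ECSF)] = TISSUE_NAMES["eCSF"]
    d2 = (X - _C_CB[0]) ** 2 + (Y - _C_CB[1]) ** 2 + (Z - _C_CB[2]) ** 2
    lbl[d2 < _R_CB**2] = TISSUE_NAMES["CB"]
    d2 = (X - _C_BS[0]) ** 2 + (Y - _C_BS[1]) ** 2 + (Z - _C_BS[2]) ** 2
    lbl[d2 < _R_BS**2] = TISSUE_NAMES["BS"]
    return lbl


def _boundary_distance(X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
                       spec: PhantomSpec) -> np.ndarray:
    """Lower bound-ish distance from points to the nearest label interface."""
    r = np.sqrt(X * X + Y * Y + Z * Z)
    d = np.full(r.shape, np.inf)
    for R in (_R_BGT, _R_VCSF, _R_INNER, _R_OUTER, _R_ECSF):
        d = np.minimum(d, np.abs(r - R) - spec.fold_amplitude)
    for c, R in ((_C_MWM, _R_MWM), (_C_CB, _R_CB), (_C_BS, _R_BS)):
        rc = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        d = np.minimum(d, np.abs(rc - R))
    return d


def make_phantom(spec: PhantomSpec | None = None) -> tuple[LabelVolume, dict[str, float]]:
    """Voxelize the phantom and return it with its analytic expectations.

    Voxels near a tissue interface are labelled by partial-volume
    majority: the continuous label is sampled on a 3x3x3 stratified
    sub-grid inside the voxel and the dominant label wins, which keeps
    per-class volume errors well below plain centre-point sampling.
    Interior voxels keep their (exact) centre label.

    The expectations dict is closed-form for ``fold_amplitude == 0``;
    for folded phantoms it is empty (use :func:`parametric_fold_mesh`
    as the surface oracle instead).
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) - (nx - 1) / 2.0 + _LATTICE_OFFSET[0]) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0 + _LATTICE_OFFSET[1]) * sy
    z = (np.arange(nz) - (nz - 1) / 2.0 + _LATTICE_OFFSET[2]) * sz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij", copy=False)

    lbl = _labels_at(X, Y, Z, spec).astype(np.int16)

    half_diag = 0.5 * float(np.sqrt(sx**2 + sy**2 + sz**2))
    near = _boundary_distance(X, Y, Z, spec) <= half_diag
    idx = np.nonzero(near)
    if idx[0].size:
        cx, cy, cz = X[idx], Y[idx], Z[idx]
        counts = np.zeros((idx[0].size, 9), dtype=np.int16)
        offs = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
        for ox in offs * sx:
            for oy in offs * sy:
                for oz in offs * sz:
                    sub = _labels_at(cx + ox, cy + oy, cz + oz, spec)
                    np.add.at(counts, (np.arange(idx[0].size), sub.astype(np.intp)), 1)
        lbl[idx] = np.argmax(counts, axis=1).astype(np.int16)

    vol = LabelVolume(grid=lbl, spacing=spec.spacing)
    truth = analytic_expectations() if spec.fold_amplitude == 0 else {}
    return vol, truth


def parametric_fold_mesh(
    fold_amplitude: float,
    fold_frequency: int = 6,
    radius: float = _R_INNER,
    n_theta: int = 400,
    n_phi: int = 800,
) -> tuple[np.ndarray, np.ndarray]:
    """High-resolution parametric triangulation of the folded surface
    r(theta, phi) = radius + a*sin(k*theta)*sin(k*phi).

    Serves as a brute-force oracle for surface area and gyrification of
    the folded phantom, independent of the voxel/marching-cubes path.
    Returns ``(vertices, faces)``.
    """
    th = np.linspace(0.0, np.pi, n_theta + 1)
    ph = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    R = radius + fold_amplitude * np.sin(fold_frequency * T) * np.sin(fold_frequency * P)
    V = np.stack(
        [R * np.sin(T) * np.cos(P), R * np.sin(T) * np.sin(P), R * np.cos(T)], axis=-1
    ).reshape(-1, 3)

    faces = []
    for i in range(n_theta):
        a, b = i * n_phi + np.arange(n_phi), i * n_phi + (np.arange(n_phi) + 1) % n_phi
        c, d = a + n_phi, b + n_phi
        faces.append(np.stack([a, c, b], axis=1))
        faces.append(np.stack([b, c, d], axis=1))
    return V, np.concatenate(faces, axis=0)


@dataclass
class CohortSpec:
    """Parameters of a simulated two-class descriptor cohort.

    ``delta`` gives per-descriptor standardized mean shifts of the
    positive (low-outcome) class; unlisted descriptors get shift 0.  With
    unit noise the theoretical single-descriptor AUC is
    ``Phi(delta/sqrt(2))``.  ``n_positive`` fixes the positive count
    exactly; alternatively ``prevalence`` draws it as round(n*prevalence).
    GA at birth is drawn from a truncated normal matching the study
    population (mean 26.5, SD 1.0, range 24-28 weeks); its class shift,
    if any, is applied to the location before truncation.
    """

    n: int
    n_positive: int | None = None
    prevalence: float | None = None
    delta: Mapping[str, float] = field(default_factory=dict)
    noise_scale: float = 1.0
    correlation: np.ndarray | None = None
    ga_mean: float = 26.5
    ga_sd: float = 1.0
    ga_range: tuple[float, float] = (24.0, 28.0)
    score_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_positive is None) == (self.prevalence is None):
            raise ValueError("specify exactly one of n_positive or prevalence")
        if self.n_positive is None:
            self.n_positive = int(round(self.n * self.prevalence))
        if not 2 <= self.n_positive <= self.n - 2:
            raise ValueError("need at least 2 subjects in each class")
        unknown = [k for k in self.delta if k not in DESCRIPTORS]
        if unknown:
            raise ValueError(f"delta names unknown descriptors: {unknown}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(DESCRIPTORS) - 1  # GA is drawn separately
            if R.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k} (image descriptors only)")
            if np.linalg.eigvalsh(R).min() <= 1e-10:
                raise ValueError("correlation matrix is not positive definite")
            self.correlation = R


def simulate_cohort(spec: CohortSpec, arm: str = "40wk") -> CohortTable:
    """Draw a cohort table with known class structure.

    Class labels are drawn first (exactly ``n_positive`` positives in a
    seeded random order), descriptors from class-conditional Gaussians,
    and Bayley cognitive/motor composites as ``85 -/+ (0.1 + |N(0, s)|)``
    conditioned on the label, so that thresholding the scores at 85
    recovers the drawn labels with zero mismatches.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 913]))
    n = spec.n
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[: spec.n_positive]] = 1

    image_cols = [d for d in DESCRIPTORS if d != "GA"]
    k = len(image_cols)
    if spec.correlation is None:
        Ximg = rng.standard_normal((n, k)) * spec.noise_scale
    else:
        L = np.linalg.cholesky(spec.correlation)
        Ximg = rng.standard_normal((n, k)) @ L.T * spec.noise_scale
    for j, col in enumerate(image_cols):
        Ximg[labels == 1, j] += spec.delta.get(col, 0.0)

    lo, hi = spec.ga_range
    ga = np.empty(n)
    for cls in (0, 1):
        mask = labels == cls
        loc = spec.ga_mean + (spec.delta.get("GA", 0.0) * spec.ga_sd if cls == 1 else 0.0)
        a, b = (lo - loc) / spec.ga_sd, (hi - loc) / spec.ga_sd
        ga[mask] = stats.truncnorm.rvs(
            a, b, loc=loc, scale=spec.ga_sd, size=int(mask.sum()), random_state=rng
        )

    offset_cog = 0.1 + np.abs(rng.normal(0.0, spec.score_sd, size=n))
    offset_mot = 0.1 + np.abs(rng.normal(0.0, spec.score_sd, size=n))
    sign = np.where(labels == 1, -1.0, 1.0)
    cognitive = 85.0 + sign * offset_cog
    motor = 85.0 + sign * offset_mot

    frame = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)], "GA": ga})
    for j, col in enumerate(image_cols):
        frame[col] = Ximg[:, j]
    frame = frame[["subject_id", *DESCRIPTORS]]
    frame["cognitive_score"] = cognitive
    frame["motor_score"] = motor
    frame["outcome_cognitive"] = [label_low_outcome(s) for s in cognitive]
    frame["outcome_motor"] = [label_low_outcome(s) for s in motor]
    assert (frame["outcome_cognitive"].to_numpy() == labels).all()
    assert (frame["outcome_motor"].to_numpy() == labels).all()
    return CohortTable(frame=frame, arm=arm)


def theoretical_auc(delta: float, sd0: float = 1.0, sd1: float = 1.0) -> float:
    """Closed-form AUC of a single Gaussian descriptor.

    For classes x0 ~ N(m, sd0^2) and x1 ~ N(m + delta, sd1^2) the
    probability that a random positive exceeds a random negative is
    ``Phi(delta / sqrt(sd0^2 + sd1^2))``.
    """
    if not np.isfinite(delta):
        return 1.0 if delta > 0 else 0.0
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf(delta / np.hypot(sd0, sd1)))
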