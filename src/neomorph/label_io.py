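"""Tissue label volume and subject metadata I/O.

The pipeline operates on 3-D integer label volumes using a fixed 8-class
neonatal tissue code scheme:

====  ======  =======================================
code  abbrev  tissue
====  ======  =======================================
0     --      background
1     uWM     unmyelinated white matter
2     mWM     myelinated white matter
3     cGM     cortical grey matter
4     vCSF    ventricular cerebrospinal fluid
5     eCSF    extracerebral cerebrospinal fluid
6     CB      cerebellum
7     BGT     basal ganglia and thalami
8     BS      brain stem
====  ======  =======================================

Upstream segmenters with other integer conventions are supported through a
``remap`` table at read time.  All geometry downstream is computed in
physical millimetres via the voxel spacing; anisotropic voxels (e.g.
0.34 x 0.34 x 2.0 mm) are explicitly supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_CODES",
    "TISSUE_NAMES",
    "LabelVolume",
    "SubjectRecord",
    "read_label_volume",
    "write_label_volume",
    "read_subject_table",
    "write_subject_table",
]

#: canonical label code -> tissue abbreviation (0 is background)
TISSUE_CODES: dict[int, str] = {
    1: "uWM",
    2: "mWM",
    3: "cGM",
    4: "vCSF",
    5: "eCSF",
    6: "CB",
    7: "BGT",
    8: "BS",
}
#: tissue abbreviation -> canonical code
TISSUE_NAMES: dict[str, int] = {v: k for k, v in TISSUE_CODES.items()}

_GA_PLAUSIBLE = (20.0, 32.0)


@dataclass
class LabelVolume:
    """A 3-D integer tissue segmentation with physical voxel spacing.

    Parameters
    ----------
    grid:
        3-D integer array of labels in ``{0..8}``.
    spacing:
        Voxel edge lengths in mm, one per axis, all positive.
    affine:
        Optional 4x4 voxel-to-world transform.  Defaults to a diagonal
        matrix built from ``spacing``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"label grid must be 3-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"label grid must be integer-typed, got {self.grid.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        bad = np.setdiff1d(np.unique(self.grid), np.arange(9))
        if bad.size:
            raise ValueError(f"labels outside the 8-class scheme {{0..8}}: {bad.tolist()}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def label_histogram(self) -> dict[int, int]:
        """Voxel count per label code, including background."""
        counts = np.bincount(self.grid.ravel(), minlength=9)
        return {c: int(counts[c]) for c in range(9)}


@dataclass
class SubjectRecord:
    """Per-subject metadata: gestational age, scan ages and Bayley scores.

    Absent values (missed scan, missed assessment) are ``None`` — never 0.
    """

    subject_id: str
    ga_birth: float
    pma_scan_30: float | None = None
    pma_scan_40: float | None = None
    cognitive_score: float | None = None
    motor_score: float | None = None

    def __post_init__(self) -> None:
        lo, hi = _GA_PLAUSIBLE
        if not lo <= self.ga_birth <= hi:
            import warnings

            warnings.warn(
                f"subject {self.subject_id}: ga_birth={self.ga_birth} weeks is outside "
                f"the plausible preterm range [{lo}, {hi}]",
                stacklevel=2,
            )


def read_label_volume(
    path: str | Path,
    remap: Mapping[int, int] | None = None,
) -> LabelVolume:
    """Read a tissue label volume from a NIfTI file.

    Parameters
    ----------
    path:
        ``.nii`` or ``.nii.gz`` file containing integer labels.
    remap:
        Optional mapping from the file's label codes to the canonical
        scheme, applied before validation.  Codes not in the mapping are
        kept as-is.

    Raises
    ------
    ValueError
        If voxel values are non-integer or (after remapping) outside
        ``{0..8}``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label image, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("voxel values are not integers; not a label volume")
        data = rounded.astype(np.int32)
    data = data.astype(np.int32, copy=False)
    if remap:
        out = data.copy()
        for src, dst in remap.items():
            out[data == src] = dst
        data = out
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(grid=data, spacing=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` to NIfTI, preserving labels and spacing."""
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine=vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


_REQUIRED_COLS = ("subject_id", "ga_birth")
_OPTIONAL_COLS = ("pma_scan_30", "pma_scan_40", "cognitive_score", "motor_score")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read per-subject metadata from a CSV file.

    The file must have a header row with at least ``subject_id`` and
    ``ga_birth``; empty cells in the optional columns become ``None``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing mandatory columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values: {sorted(dup.unique().tolist())}")

    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _OPTIONAL_COLS:
            val = row.get(col)
            kwargs[col] = None if val is None or pd.isna(val) else float(val)
        records.append(
            SubjectRecord(subject_id=str(row["subject_id"]), ga_birth=float(row["ga_birth"]), **kwargs)
        )
    return records


def write_subject_table(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to CSV (inverse of :func:`read_subject_table`)."""
    rows = [
        {
            "subject_id": r.subject_id,
            "ga_birth": r.ga_birth,
            "pma_scan_30": r.pma_scan_30,
            "pma_scan_40": r.pma_scan_40,
            "cognitive_score": r.cognitive_score,
            "motor_score": r.motor_score,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
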