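"""Shared image containers: scalar 3-D grids, gated series and volume curves."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

INTENSITY_KINDS = ("HU", "activity", "counts")


@dataclass
class ImageVolume:
    """A scalar 3-D grid with voxel spacing and a left-ventricular long axis.

    ``grid`` is indexed ``[x, y, z]`` with physical coordinates centred on the
    grid; ``spacing_mm`` gives the voxel pitch per axis and ``long_axis`` is a
    unit vector (in grid coordinates) along the LV long axis.
    """

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    intensity_kind: str = "HU"
    long_axis: np.ndarray = (0.0, 0.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"intensity_kind must be one of {INTENSITY_KINDS}")
        ax = np.asarray(self.long_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("long_axis must be non-zero")
        self.long_axis = ax / n

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def physical_coords(self):
        """Voxel-centre coordinates (mm), one 1-D array per axis, centred on 0."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.grid.shape, self.spacing_mm)
        )

    def save_nifti(self, path):
        affine = np.diag(list(self.spacing_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.grid, dtype=np.float32), affine)
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
        sidecar.write_text(json.dumps({
            "intensity_kind": self.intensity_kind,
            "long_axis": [float(v) for v in self.long_axis],
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }, indent=2))

    @classmethod
    def load_nifti(cls, path):
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        kind, axis, meta = "HU", (0.0, 0.0, 1.0), {}
        sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            kind = info.get("intensity_kind", kind)
            axis = info.get("long_axis", axis)
            meta = info.get("meta", {})
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, kind, axis, meta)


def _jsonable(v):
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class GatedImageSeries:
    """An ordered set of ImageVolumes over cardiac phases or gate bins."""

    bins: list
    bin_kind: str = "ct_phase"  # ct_phase | spect_gate
    phase_fractions: np.ndarray | None = None

    def __post_init__(self):
        if not self.bins:
            raise ValueError("series must contain at least one bin")
        shape0, sp0 = self.bins[0].shape, self.bins[0].spacing_mm
        for b in self.bins:
            if b.shape != shape0 or b.spacing_mm != sp0:
                raise ValueError("all bins must share grid shape and spacing")
        if self.phase_fractions is not None:
            self.phase_fractions = np.asarray(self.phase_fractions, dtype=float)
            if len(self.phase_fractions) != len(self.bins):
                raise ValueError("phase_fractions length must match bins")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def save_nifti_dir(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, b in enumerate(self.bins):
            b.save_nifti(out / f"bin_{i:03d}.nii.gz")


@dataclass
class VolumeCurve:
    """Per-phase LV volumes (ml) over one cardiac cycle.

    The curve is cyclic: phase 0 and phase 1 refer to the same time point.
    """

    phase_fractions: np.ndarray
    volumes_ml: np.ndarray

    def __post_init__(self):
        self.phase_fractions = np.asarray(self.phase_fractions, dtype=float)
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if self.phase_fractions.shape != self.volumes_ml.shape:
            raise ValueError("phase/volume length mismatch")
        if self.phase_fractions.ndim != 1 or len(self.phase_fractions) < 2:
            raise ValueError("curve needs at least two phases")
        if np.any((self.phase_fractions < 0) | (self.phase_fractions >= 1)):
            raise ValueError("phase fractions must lie in [0, 1)")

    @property
    def n_phases(self) -> int:
        return len(self.phase_fractions)

    @property
    def edv_ml(self) -> float:
        return float(np.max(self.volumes_ml))

    @property
    def esv_ml(self) -> float:
        return float(np.min(self.volumes_ml))

    def to_csv(self, path):
        pd.DataFrame({
            "phase_fraction": self.phase_fractions,
            "volume_ml": self.volumes_ml,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df["phase_fraction"].to_numpy(), df["volume_ml"].to_numpy())
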