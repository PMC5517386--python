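"""Digital twin of a dynamic two-membrane left-ventricle phantom.

The physical device this emulates pumps water in and out of an elastic
membrane chamber: the end-systolic volume (ESV) is fixed by the membrane at
rest, while the end-diastolic volume (EDV) is set by the stroke of the pump,
so the ejection fraction EF = (EDV - ESV)/EDV x 100% is dialled in through
the pumped volume.  The chamber sits in a water bath, and an outer "myocardial"
compartment surrounding the chamber is filled with a Tc-99m solution during
emission scans.

Model geometry
--------------
The LV chamber is a prolate ellipsoid (long/short semi-axis ratio
``axis_ratio``) whose enclosed volume - water plus the thin membrane wall,
exactly the region a CT segmentation delineates out to the membrane's outer
surface - follows a smooth cyclic volume curve with extrema exactly at
``esv_ml`` and ``edv_from_ef(esv_ml, ef_nominal)``.  The membrane occupies a
uniform thickness ``wall_thickness_mm`` inward from that outer surface; the
myocardial (activity) compartment coincides with the membrane shell.  Cavity
semi-axes scale isotropically with the cube root of the enclosed volume.

All randomness flows through explicitly seeded ``numpy.random.Generator``
instances; identical seeds give bit-identical volumes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grids import GatedImageSeries, ImageVolume, VolumeCurve

__all__ = [
    "PhantomConfig",
    "edv_from_ef",
    "cavity_volume_at_phase",
    "ground_truth_volumes",
    "phase_grid",
    "rasterize_ct",
    "rasterize_activity",
    "simulate_gated_ct",
    "semi_axes_mm",
    "shell_volume_ml",
    "water_volume_ml",
]


def edv_from_ef(esv_ml: float, ef: float) -> float:
    """End-diastolic volume implied by a fixed ESV and a nominal EF.

    Inverts EF = (EDV - ESV)/EDV x 100%:  EDV = ESV / (1 - EF/100).
    """
    if esv_ml <= 0:
        raise ValueError("esv_ml must be positive")
    if not (0 <= ef < 100):
        raise ValueError("ef must lie in [0, 100)")
    return esv_ml / (1.0 - ef / 100.0)


@dataclass
class PhantomConfig:
    """Nominal settings and geometry of the dynamic phantom.

    ``ef_nominal`` [%], ``bpm`` [1/min] and ``esv_ml`` [ml] define the pumping
    programme; ``wall_thickness_mm`` the membrane/myocardial shell;
    ``membrane_hu``/``water_hu``/``background_hu`` the CT compartment
    intensities (water bath, so background ~ water ~ 0 HU); ``ct_noise_sd``
    additive CT noise [HU]; ``activity_conc`` the emission-compartment
    concentration [counts/s/ml]; ``axis_ratio`` and ``long_axis`` the prolate
    shape and orientation; ``systolic_duty`` the fraction of the cycle spent
    contracting (end-systole occurs at this phase).
    """

    ef_nominal: float
    bpm: float = 60.0
    esv_ml: float = 33.0
    wall_thickness_mm: float = 1.8
    membrane_hu: float = 800.0
    water_hu: float = 0.0
    background_hu: float = 0.0
    ct_noise_sd: float = 15.0
    activity_conc: float = 2000.0
    axis_ratio: float = 1.8
    long_axis: tuple = (0.0, 0.0, 1.0)
    systolic_duty: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.ef_nominal < 100):
            raise ValueError("ef_nominal must lie in (0, 100)")
        if self.esv_ml <= 0:
            raise ValueError("esv_ml must be positive")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")
        if self.membrane_hu - self.water_hu <= 10 * self.ct_noise_sd:
            raise ValueError(
                "membrane and water CT numbers are not separable: require "
                "membrane_hu - water_hu > 10 * ct_noise_sd")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1 (prolate)")
        if not (0 < self.systolic_duty < 1):
            raise ValueError("systolic_duty must lie in (0, 1)")
        ax = np.asarray(self.long_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("long_axis must be non-zero")
        self.long_axis = tuple(ax / n)

    @property
    def edv_ml(self) -> float:
        return edv_from_ef(self.esv_ml, self.ef_nominal)

    def to_yaml(self, path):
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["long_axis"] = [float(v) for v in d["long_axis"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "long_axis" in d:
            d["long_axis"] = tuple(d["long_axis"])
        return cls(**d)


def _volume_fraction(phase, duty):
    """Raised-cosine cyclic waveform: 1 at end-diastole (phase 0), 0 at
    end-systole (phase ``duty``), C1-smooth across the cycle boundary."""
    p = np.asarray(phase, dtype=float) % 1.0
    sys_part = 0.5 * (1.0 + np.cos(np.pi * p / duty))
    dia_part = 0.5 * (1.0 - np.cos(np.pi * (p - duty) / (1.0 - duty)))
    return np.where(p < duty, sys_part, dia_part)


def cavity_volume_at_phase(config: PhantomConfig, phase) -> float:
    """LV chamber volume (water + inner membrane, ml) at a cardiac phase.

    Minimum over the cycle is exactly ``esv_ml`` (at phase ``systolic_duty``)
    and maximum exactly the EF-implied EDV (at phase 0).
    """
    edv = config.edv_ml
    w = _volume_fraction(phase, config.systolic_duty)
    out = config.esv_ml + (edv - config.esv_ml) * w
    return float(out) if np.isscalar(phase) else out


def phase_grid(config: PhantomConfig, n_phases: int) -> np.ndarray:
    """Near-uniform phase grid that contains both volume extrema.

    A uniform ``n_phases``-point grid over [0, 1) with the nonzero grid point
    nearest to the end-systolic phase replaced by the exact systolic phase, so
    the sampled curve attains ESV and EDV for every ``n_phases >= 2``.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    phases = np.arange(n_phases) / n_phases
    idx = int(np.argmin(np.abs(phases[1:] - config.systolic_duty))) + 1
    phases = phases.copy()
    phases[idx] = config.systolic_duty
    return phases


def ground_truth_volumes(config: PhantomConfig, n_phases: int = 21) -> VolumeCurve:
    """Analytic ground-truth LV volume curve (water + inner membrane)."""
    phases = phase_grid(config, n_phases)
    return VolumeCurve(phases, cavity_volume_at_phase(config, phases))


# ---------------------------------------------------------------------------
# geometry helpers

def semi_axes_mm(volume_ml: float, axis_ratio: float):
    """Prolate semi-axes (a, b, b) in mm for an ellipsoid of given volume."""
    v_mm3 = volume_ml * 1000.0
    b = (3.0 * v_mm3 / (4.0 * math.pi * axis_ratio)) ** (1.0 / 3.0)
    return axis_ratio * b, b, b


def _ellipsoid_volume_ml(a, b, c):
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def water_volume_ml(config: PhantomConfig, phase) -> float:
    """Volume of the water cavity proper (inside the inner membrane)."""
    a, b, _ = semi_axes_mm(cavity_volume_at_phase(config, phase), config.axis_ratio)
    t = config.wall_thickness_mm
    if b <= t:
        return 0.0
    return _ellipsoid_volume_ml(a - t, b - t, b - t)


def shell_volume_ml(config: PhantomConfig, phase) -> float:
    """Volume of the membrane (= myocardial/activity) shell at a phase."""
    enclosed = cavity_volume_at_phase(config, phase)
    return enclosed - water_volume_ml(config, phase)


def rotation_to_z(axis) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto +z (Rodrigues)."""
    v = np.asarray(axis, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(v, z), -1.0, 1.0))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    k = np.cross(v, z)
    s = np.linalg.norm(k)
    k = k / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


def _ellipsoid_signed_distance(px, py, pz, a, b, c):
    """Approximate signed distance (mm) to an axis-aligned ellipsoid surface,
    negative inside.  First-order estimate d = (g - 1)/|grad g| with
    g = sqrt((x/a)^2 + (y/b)^2 + (z/c)^2); exact for spheres, accurate to a
    small fraction of a voxel for moderate eccentricity."""
    g2 = (px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2
    g = np.sqrt(g2)
    grad = np.sqrt((px / a**2) ** 2 + (py / b**2) ** 2 + (pz / c**2) ** 2)
    rmin = min(a, b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (g - 1.0) * g / grad
    return np.where(grad > 1e-12, d, -rmin)


def _compartment_fractions(config, phase, shape, spacing_mm):
    """Per-voxel coverage fractions (cavity-water, membrane shell).

    Coverage is approximated by a linear ramp of one voxel width across each
    surface, which keeps integrated volumes accurate to O(h^2).
    """
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing_mm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    rot = rotation_to_z(config.long_axis)
    px = rot[0, 0] * gx + rot[0, 1] * gy + rot[0, 2] * gz
    py = rot[1, 0] * gx + rot[1, 1] * gy + rot[1, 2] * gz
    pz = rot[2, 0] * gx + rot[2, 1] * gy + rot[2, 2] * gz

    a, b, _ = semi_axes_mm(cavity_volume_at_phase(config, phase), config.axis_ratio)
    t = config.wall_thickness_mm
    h = float(np.prod(spacing_mm)) ** (1.0 / 3.0)

    # rotated frame puts long_axis on the third component
    d_out = _ellipsoid_signed_distance(px, py, pz, b, b, a)
    frac_out = np.clip(0.5 - d_out / h, 0.0, 1.0)
    if b > t:
        d_in = _ellipsoid_signed_distance(px, py, pz, b - t, b - t, a - t)
        frac_in = np.clip(0.5 - d_in / h, 0.0, 1.0)
    else:
        frac_in = np.zeros_like(frac_out)
    memb = np.clip(frac_out - frac_in, 0.0, 1.0)
    return frac_in, memb


def _phase_seed(seed: int, phase: float) -> list:
    return [int(seed) & 0x7FFFFFFF, int(round((phase % 1.0) * 1e9))]


def rasterize_ct(config: PhantomConfig, phase: float, fov_mm: float,
                 matrix: int, nz: int | None = None,
                 seed: int | None = None) -> ImageVolume:
    """Rasterize one cardiac phase as a CT (HU) volume.

    Voxels mix water/membrane/background HU by surface-coverage fraction and
    receive additive Gaussian noise of sd ``ct_noise_sd``; deterministic for a
    fixed (seed, phase).
    """
    spacing = fov_mm / matrix
    if spacing < 0.3:
        raise ValueError("fov_mm/matrix must be >= 0.3 mm")
    nz = matrix if nz is None else nz
    shape = (matrix, matrix, nz)
    sp = (spacing, spacing, spacing)
    frac_in, memb = _compartment_fractions(config, phase, shape, sp)
    frac_out = np.clip(frac_in + memb, 0.0, 1.0)
    hu = (config.background_hu * (1.0 - frac_out)
          + config.water_hu * frac_in
          + config.membrane_hu * memb)
    meta = {"phase": float(phase % 1.0)}
    if config.wall_thickness_mm < spacing:
        meta["warnings"] = ["wall thinner than one voxel; membrane is partial-volume only"]
    if config.ct_noise_sd > 0:
        rng = np.random.default_rng(
            _phase_seed(config.seed if seed is None else seed, phase))
        hu = hu + rng.normal(0.0, config.ct_noise_sd, size=hu.shape)
    return ImageVolume(hu, sp, "HU", config.long_axis, meta)


def rasterize_activity(config: PhantomConfig, phase: float, matrix: int,
                       spacing_mm: float, nz: int | None = None) -> ImageVolume:
    """Rasterize the emission source at one phase.

    The grid stores activity concentration (counts/s/ml) scaled by the local
    shell-coverage fraction: activity lives only in the myocardial (membrane)
    shell, and the grid integral (value x voxel volume) equals shell volume x
    ``activity_conc`` up to discretization.
    """
    if spacing_mm < 0.3:
        raise ValueError("spacing_mm must be >= 0.3 mm")
    nz = matrix if nz is None else nz
    shape = (matrix, matrix, nz)
    sp = (spacing_mm, spacing_mm, spacing_mm)
    _, memb = _compartment_fractions(config, phase, shape, sp)
    meta = {"phase": float(phase % 1.0)}
    if config.wall_thickness_mm < spacing_mm:
        meta["warnings"] = ["wall thinner than one voxel; membrane is partial-volume only"]
    return ImageVolume(config.activity_conc * memb, sp, "activity",
                       config.long_axis, meta)


def simulate_gated_ct(config: PhantomConfig, n_phases: int = 21,
                      fov_mm: float = 153.6, matrix: int = 128,
                      nz: int | None = None, seed: int | None = None):
    """Gated CT acquisition of the phantom.

    Returns (GatedImageSeries of HU volumes, analytic ground-truth VolumeCurve)
    over the same phase grid.
    """
    curve = ground_truth_volumes(config, n_phases)
    bins = [rasterize_ct(config, p, fov_mm, matrix, nz=nz, seed=seed)
            for p in curve.phase_fractions]
    series = GatedImageSeries(bins, "ct_phase", curve.phase_fractions)
    return series, curve
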