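"""Gated-CT LV volumetry.

Per cardiac phase: resample onto an isotropic grid aligned with the LV long
axis (cubic interpolation), fit a double-peaked Gaussian to the HU histogram
with a derivative-free simplex search, threshold midway between the water and
membrane peaks, clean the binary mask with 3-D morphology (closing, hole
filling, largest component), and report the segmented volume (water cavity
plus inner membrane).  The extrema of the resulting volume curve give EDV,
ESV and the reference ejection fraction EF_True.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .grids import GatedImageSeries, ImageVolume, VolumeCurve
from .phantom import rotation_to_z

__all__ = [
    "HistogramFit", "SegMask", "EFResult",
    "HistogramFitError", "SegmentationError",
    "resample_long_axis", "fit_double_gaussian", "segmentation_threshold",
    "segment_lv", "mask_volume_ml", "compute_ef", "ct_pipeline",
]


class HistogramFitError(RuntimeError):
    """Histogram is unimodal or the simplex search failed to converge."""


class SegmentationError(RuntimeError):
    """Thresholding plus clean-up produced an empty mask."""


@dataclass
class HistogramFit:
    """Six-parameter double-Gaussian fit to a CT volume histogram."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    amp1: float
    amp2: float
    residual: float

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if self.mu1 > self.mu2:
            raise ValueError("mu1 must be <= mu2")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class SegMask:
    grid: np.ndarray
    spacing_mm: tuple
    threshold_used: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)


@dataclass
class EFResult:
    edv_ml: float
    esv_ml: float
    ef_percent: float
    edv_phase_index: int
    esv_phase_index: int


def _edge_median(grid):
    faces = [grid[0], grid[-1], grid[:, 0], grid[:, -1], grid[:, :, 0], grid[:, :, -1]]
    return float(np.median(np.concatenate([f.ravel() for f in faces])))


def resample_long_axis(volume: ImageVolume, iso_mm: float) -> ImageVolume:
    """Resample onto an isotropic grid whose third axis is the LV long axis.

    Uses cubic spline interpolation; out-of-field values take the median edge
    intensity so a constant volume stays constant.  If the volume is already
    aligned and isotropic at ``iso_mm`` it is returned unchanged (copy).
    """
    axis = np.asarray(volume.long_axis, dtype=float)
    aligned = abs(axis @ [0, 0, 1]) > 1 - 1e-9
    iso_in = np.allclose(volume.spacing_mm, iso_mm, rtol=1e-9, atol=1e-9)
    if aligned and iso_in:
        out = ImageVolume(volume.grid.copy(), (iso_mm,) * 3, volume.intensity_kind,
                          (0, 0, 1), dict(volume.meta))
        return out
    if min(volume.spacing_mm) > 0 and iso_mm < min(volume.spacing_mm) / 2:
        volume.meta.setdefault("warnings", []).append(
            "output grid oversamples the source by more than 2x")

    rot = rotation_to_z(axis)  # maps long_axis -> z
    # Output basis vectors (world frame): columns of rot.T = e1, e2, long_axis.
    basis = rot.T
    extents = [s * (n - 1) for n, s in zip(volume.shape, volume.spacing_mm)]
    # Bounding half-extent of the rotated input box along each output axis.
    half = 0.5 * np.abs(basis.T) @ np.asarray(extents)
    shape_out = tuple(int(math.ceil(2 * h / iso_mm)) + 1 for h in half)

    spacing_in = np.asarray(volume.spacing_mm)
    c_in = (np.asarray(volume.shape) - 1) / 2.0
    c_out = (np.asarray(shape_out) - 1) / 2.0
    # input_index = diag(1/spacing_in) @ basis @ (iso * (out_index - c_out)) + c_in
    mat = (basis * iso_mm) / spacing_in[:, None]
    offset = c_in - mat @ c_out
    out = ndimage.affine_transform(
        np.asarray(volume.grid, dtype=float), mat, offset=offset,
        output_shape=shape_out, order=3, mode="constant",
        cval=_edge_median(volume.grid))
    return ImageVolume(out, (iso_mm,) * 3, volume.intensity_kind, (0, 0, 1),
                       dict(volume.meta))


def _fit_single_gaussian(xw, yw, m0, s0, a0):
    """3-parameter Nelder-Mead Gaussian fit on one window."""
    x0 = np.array([m0, s0, max(a0, 1.0)])
    scale = np.where(np.abs(x0) > 1e-9, np.abs(x0), 1.0)

    def ssr(p):
        m, s, a = p * scale
        r = a * np.exp(-0.5 * ((xw - m) / max(abs(s), 1e-12)) ** 2) - yw
        return float(r @ r)

    res = optimize.minimize(ssr, x0 / scale, method="Nelder-Mead",
                            options={"maxfev": 600, "xatol": 1e-8, "fatol": 1e-10})
    m, s, a = res.x * scale
    return float(m), float(abs(s)), float(a)


def _half_width(smooth, p):
    """Half-width at half maximum of a local mode, in bins (>= 2)."""
    half = 0.5 * smooth[p]
    lo = p
    while lo > 0 and smooth[lo - 1] > half:
        lo -= 1
    hi = p
    while hi < len(smooth) - 1 and smooth[hi + 1] > half:
        hi += 1
    return max(hi - lo, 2)


def _double_gaussian(x, p):
    m1, s1, a1, m2, s2, a2 = p
    return (a1 * np.exp(-0.5 * ((x - m1) / abs(s1)) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / abs(s2)) ** 2))


def fit_double_gaussian(histogram) -> HistogramFit:
    """Least-squares double-Gaussian fit via Nelder-Mead simplex search.

    ``histogram`` is a ``(bin_centers, counts)`` pair.  Initialisation places
    the means on the two most prominent histogram modes; failure to resolve
    two modes, or non-convergence within the evaluation budget, raises
    :class:`HistogramFitError`.
    """
    centers, counts = histogram
    centers = np.asarray(centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if centers.ndim != 1 or centers.shape != counts.shape or len(centers) < 8:
        raise ValueError("histogram must be (bin_centers, counts) 1-D arrays")

    # Locate the dominant mode, excise a band of +-5 half-widths around it,
    # and require a clearly non-empty second mode in the remainder.  The two
    # classes are wildly unbalanced (the water/background class can outnumber
    # the membrane voxels 500:1), so a global prominence cut cannot work.
    smooth = ndimage.gaussian_filter1d(counts, 2.0)
    p1 = int(np.argmax(smooth))
    hw1 = _half_width(smooth, p1)
    rest = smooth.copy()
    rest[max(0, p1 - 5 * hw1):p1 + 5 * hw1 + 1] = 0.0
    floor = max(5.0, 1e-6 * counts.sum())
    if rest.max() <= floor:
        raise HistogramFitError("histogram is unimodal at this binning")
    p2 = int(np.argmax(rest))
    hw2 = _half_width(smooth, p2)
    p1, p2 = sorted((p1, p2))

    # Fit only near the two modes: the partial-volume plateau between the
    # classes is not Gaussian and would otherwise bias the small peak.
    sel = np.zeros(len(centers), dtype=bool)
    sel[max(0, p1 - 8 * hw1):p1 + 8 * hw1 + 1] = True
    sel[max(0, p2 - 8 * hw2):p2 + 8 * hw2 + 1] = True
    xs, ys = centers[sel], counts[sel]

    # Stage 1: robust 3-parameter simplex fit per mode on its own window
    # (near-delta modes make a cold 6-parameter joint fit fall into local
    # minima where one component wanders off the data).
    binw = float(np.mean(np.diff(centers)))
    singles = []
    for p, hw in ((p1, hw1), (p2, hw2)):
        w0, w1 = max(0, p - 4 * hw), p + 4 * hw + 1
        xw, yw = centers[w0:w1], counts[w0:w1]
        tot = yw.sum()
        m0 = float((xw * yw).sum() / tot)
        s0 = max(float(np.sqrt((yw * (xw - m0) ** 2).sum() / tot)), 0.4 * binw)
        singles.append(_fit_single_gaussian(xw, yw, m0, s0, float(counts[p])))
    (m1, s1, a1), (m2, s2, a2) = singles

    # Stage 2: joint refinement of all six parameters on the union window.
    x0 = np.array([m1, s1, a1, m2, s2, a2])
    scale = np.where(np.abs(x0) > 1e-9, np.abs(x0), 1.0)

    def ssr(p):
        r = _double_gaussian(xs, p * scale) - ys
        return float(r @ r)

    ssr0 = ssr(x0 / scale)
    res = optimize.minimize(
        ssr, x0 / scale, method="Nelder-Mead",
        options={"maxfev": 2000, "xatol": 1e-8, "fatol": 1e-8 * (1 + ssr0)})
    if res.fun <= ssr0:
        m1, s1, a1, m2, s2, a2 = res.x * scale
    elif not res.success:
        raise HistogramFitError(
            f"simplex search did not converge: {res.message} (SSR {res.fun:.3g})")
    s1, s2 = abs(s1), abs(s2)
    if m1 > m2:
        m1, s1, a1, m2, s2, a2 = m2, s2, a2, m1, s1, a1
    return HistogramFit(m1, m2, max(s1, 1e-9), max(s2, 1e-9), a1, a2, float(res.fun))


def segmentation_threshold(fit: HistogramFit, rule: str = "midpoint") -> float:
    """Water/membrane decision threshold from the fitted peak locations.

    ``midpoint`` (default): (mu1 + mu2)/2 - the half-value of the two peak
    locations, which equals half the membrane CT number when water sits at
    ~0 HU.  ``half_upper``: literally mu2/2.
    """
    if rule == "midpoint":
        return (fit.mu1 + fit.mu2) / 2.0
    if rule == "half_upper":
        return fit.mu2 / 2.0
    raise ValueError("rule must be 'midpoint' or 'half_upper'")


_STRUCT = ndimage.generate_binary_structure(3, 1)


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological clean-up: closing (ball r=1), 3-D hole fill, largest
    connected component.  Idempotent."""
    m = ndimage.binary_closing(mask, structure=_STRUCT)
    m = ndimage.binary_fill_holes(m, structure=_STRUCT)
    labels, n = ndimage.label(m, structure=_STRUCT)
    if n == 0:
        raise SegmentationError("mask is empty after clean-up")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return m


def segment_lv(volume: ImageVolume, threshold: float) -> SegMask:
    """Segment the LV chamber (water cavity plus inner membrane).

    Voxels at or above the threshold define the membrane shell; hole filling
    recovers the enclosed cavity, and closing plus largest-component selection
    remove noise clutter while preserving the membrane boundary.
    """
    raw = np.asarray(volume.grid) >= threshold
    if not raw.any():
        raise SegmentationError("no voxels above threshold")
    return SegMask(clean_mask(raw), volume.spacing_mm, float(threshold))


def mask_volume_ml(mask: SegMask) -> float:
    """Voxel count x voxel volume, in ml."""
    return float(mask.grid.sum()) * float(np.prod(mask.spacing_mm)) / 1000.0


def compute_ef(curve: VolumeCurve) -> EFResult:
    """EDV/ESV/EF from a volume curve: EF = (EDV - ESV)/EDV x 100%."""
    v = np.asarray(curve.volumes_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("all volumes must be positive")
    i_edv = int(np.argmax(v))
    i_esv = int(np.argmin(v))
    edv, esv = float(v[i_edv]), float(v[i_esv])
    return EFResult(edv, esv, (edv - esv) / edv * 100.0, i_edv, i_esv)


def histogram_for_fit(grid: np.ndarray, n_bins: int = 256):
    """Histogram over the 0.1-99.9 intensity percentile range."""
    lo, hi = np.percentile(grid, [0.1, 99.9])
    # keep the (possibly tiny) upper class inside the range and pad both ends
    # so neither mode sits on an edge bin
    hi = max(hi, float(grid.max()))
    if hi <= lo:
        lo, hi = float(grid.min()), float(grid.max() + 1.0)
    pad = 0.02 * (hi - lo)
    lo, hi = lo - pad, hi + pad
    counts, edges = np.histogram(grid, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def analyze_phase(volume: ImageVolume, iso_mm: float | None = None,
                  threshold_rule: str = "midpoint"):
    """Resample -> histogram fit -> threshold -> segment one phase.

    Returns (volume_ml, SegMask, HistogramFit)."""
    iso = iso_mm if iso_mm is not None else min(volume.spacing_mm)
    res = resample_long_axis(volume, iso)
    fit = fit_double_gaussian(histogram_for_fit(res.grid))
    thr = segmentation_threshold(fit, threshold_rule)
    mask = segment_lv(res, thr)
    return mask_volume_ml(mask), mask, fit


def ct_pipeline(series: GatedImageSeries, iso_mm: float | None = None,
                threshold_rule: str = "midpoint", qc: bool = False):
    """Full gated-CT analysis: per-phase segmentation then EF from extrema.

    Thresholds are fitted independently per phase.  Returns
    ``(VolumeCurve, EFResult)`` or, with ``qc=True``,
    ``(VolumeCurve, EFResult, qc_dataframe)`` carrying per-phase thresholds,
    fitted peaks and an outlier flag (volume further than 3 median absolute
    deviations from the cyclic median).
    """
    if series.n_bins < 2:
        raise ValueError("need at least two phases")
    phases = (series.phase_fractions if series.phase_fractions is not None
              else np.arange(series.n_bins) / series.n_bins)
    vols, rows = [], []
    for i, vol in enumerate(series.bins):
        try:
            v, mask, fit = analyze_phase(vol, iso_mm, threshold_rule)
        except (HistogramFitError, SegmentationError) as exc:
            raise type(exc)(f"phase index {i}: {exc}") from exc
        vols.append(v)
        rows.append({"phase_index": i, "phase_fraction": float(phases[i]),
                     "volume_ml": v, "threshold_hu": mask.threshold_used,
                     "mu_water_hu": fit.mu1, "mu_membrane_hu": fit.mu2})
    curve = VolumeCurve(phases, np.asarray(vols))
    ef = compute_ef(curve)
    if not qc:
        return curve, ef
    df = pd.DataFrame(rows)
    med = df["volume_ml"].median()
    mad = float(np.median(np.abs(df["volume_ml"] - med))) or 1e-9
    df["outlier"] = np.abs(df["volume_ml"] - med) > 3 * 1.4826 * mad
    return curve, ef, df
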