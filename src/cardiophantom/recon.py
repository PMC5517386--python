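"""Ordered-subsets expectation-maximization (OSEM) reconstruction.

Reconstruction quality is parameterised by the equivalent number of
iterations EI = iterations x subsets, the effective number of multiplicative
updates each voxel receives.  With one subset the algorithm is exactly MLEM
and the Poisson log-likelihood is non-decreasing across iterations (the
projector and backprojector are exact transposes of each other).

No attenuation correction and no post-filter are applied; the collimator
PSF is part of the system model when ``psf_in_model`` is set (resolution
recovery).  Each gate bin is reconstructed independently.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import ImageVolume
from .spect import ProjectionSet, PSFModel, SystemModel, default_psf

__all__ = [
    "ReconParams", "ReconSeries", "equivalent_iterations",
    "osem_reconstruct", "osem_snapshots", "poisson_loglik", "run_mlem",
]


@dataclass
class ReconParams:
    n_iterations: int
    n_subsets: int = 1
    psf_in_model: bool = True
    nonneg_floor: float = 1e-12

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("n_iterations and n_subsets must be >= 1")
        if self.nonneg_floor <= 0:
            raise ValueError("nonneg_floor must be a small positive number")


@dataclass
class ReconSeries:
    gates: list
    params: ReconParams
    protocol_name: str
    ei: int
    loglik_trace: list = field(default_factory=list)

    @property
    def n_gates(self) -> int:
        return len(self.gates)


def equivalent_iterations(params: ReconParams) -> int:
    """EI = number of iterations x number of subsets."""
    return params.n_iterations * params.n_subsets


def _subset_views(n_views: int, n_subsets: int):
    """Interleaved subset partition: view i belongs to subset i mod S."""
    if n_views % n_subsets:
        raise ValueError(f"n_subsets={n_subsets} does not divide {n_views} views")
    return [list(range(s, n_views, n_subsets)) for s in range(n_subsets)]


def run_mlem(y, forward, back, n_iterations, sensitivity=None, x0=None,
             nonneg_floor=1e-12, callback=None):
    """Generic multiplicative EM loop for Poisson data y ~ Poisson(F x).

    ``forward``/``back`` are matched linear operators; ``sensitivity`` is
    back(ones) (computed if omitted).  Used both by the geometric
    reconstructions and by matrix-based reference problems.
    """
    y = np.asarray(y, dtype=float)
    if sensitivity is None:
        sensitivity = back(np.ones_like(y))
    live = sensitivity > 0
    x = np.ones_like(sensitivity) if x0 is None else np.asarray(x0, dtype=float).copy()
    x[~live] = 0.0
    for it in range(n_iterations):
        yhat = forward(x)
        ratio = y / np.maximum(yhat, nonneg_floor)
        upd = back(ratio)
        x = np.where(live, x * upd / np.maximum(sensitivity, nonneg_floor), 0.0)
        if callback is not None:
            callback(it, x)
    return x


def _fov_mask(n, nz):
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (ii - c) ** 2 + (jj - c) ** 2 <= c ** 2
    return np.repeat(disk[:, :, None], nz, axis=2)


def _subset_sensitivities(model, subsets, scale):
    return [model.back(np.ones((len(v), model.n, model.nz)), v) * scale
            for v in subsets]


def _osem_gate(y, model: SystemModel, params: ReconParams, scale: float,
               snapshot_iters=(), track_loglik=False, sens=None):
    """OSEM for one gate; returns (final estimate, {iter: snapshot}, trace)."""
    subsets = _subset_views(model.n_views, params.n_subsets)
    floor = params.nonneg_floor
    if sens is None:
        sens = _subset_sensitivities(model, subsets, scale)
    x = _fov_mask(model.n, model.nz).astype(float)
    snaps, trace = {}, []
    want = set(snapshot_iters)
    n_iter = max([params.n_iterations, *want]) if want else params.n_iterations
    for it in range(1, n_iter + 1):
        for v, s in zip(subsets, sens):
            yhat = model.forward(x, v) * scale
            ysub = y[v]
            if ysub.sum() == 0:
                warnings.warn("zero-count subset: update skipped", RuntimeWarning)
                continue
            ratio = ysub / np.maximum(yhat, floor)
            upd = model.back(ratio, v) * scale
            x = np.where(s > 0, x * upd / np.maximum(s, floor), 0.0)
        if track_loglik:
            yhat = model.forward(x) * scale
            trace.append(_loglik(y, yhat))
        if it in want:
            snaps[it] = x.copy()
    return x, snaps, trace


def _loglik(y, yhat):
    bad = (yhat <= 0) & (y > 0)
    if np.any(bad):
        return -np.inf
    pos = yhat > 0
    return float(np.sum(y[pos] * np.log(yhat[pos])) - yhat.sum())


def _model_for(projections: ProjectionSet, params: ReconParams,
               psf: PSFModel | None):
    if psf is None:
        psf = default_psf(projections.protocol.name)
    if not params.psf_in_model:
        psf = PSFModel(0.0, 0.0, psf.center_magnification)
    return SystemModel(projections.grid_shape, projections.protocol.pixel_mm,
                       projections.protocol, psf)


def osem_reconstruct(projections: ProjectionSet, params: ReconParams,
                     psf: PSFModel | None = None) -> ReconSeries:
    """OSEM reconstruction of every gate bin.

    Uniform positive initialisation inside the cylindrical field of view, no
    post-filter.  With ``n_subsets == 1`` the per-iteration Poisson
    log-likelihood is recorded in ``loglik_trace`` (one list per gate).
    """
    model = _model_for(projections, params, psf)
    track = params.n_subsets == 1
    sens = _subset_sensitivities(
        model, _subset_views(model.n_views, params.n_subsets),
        projections.count_scale)
    gates, traces = [], []
    for g in range(projections.n_gates):
        x, _, trace = _osem_gate(
            np.asarray(projections.counts[g], dtype=float), model, params,
            projections.count_scale, track_loglik=track, sens=sens)
        gates.append(_as_volume(x, projections))
        traces.append(trace)
    return ReconSeries(gates, params, projections.protocol.name,
                       equivalent_iterations(params), traces)


def osem_snapshots(projections: ProjectionSet, ei_values, n_subsets: int = 2,
                   psf: PSFModel | None = None, psf_in_model: bool = True):
    """Reconstructions at several EI values from a single OSEM run.

    Every requested EI must be a multiple of ``n_subsets``; snapshots are
    taken after the corresponding full iteration, so the EI sweep costs one
    reconstruction at max(EI).  Returns {ei: ReconSeries}.
    """
    ei_values = sorted(int(e) for e in ei_values)
    if any(e % n_subsets for e in ei_values):
        raise ValueError(f"every EI must be a multiple of n_subsets={n_subsets}")
    iters = [e // n_subsets for e in ei_values]
    params = ReconParams(max(iters), n_subsets, psf_in_model)
    model = _model_for(projections, params, psf)
    sens = _subset_sensitivities(
        model, _subset_views(model.n_views, n_subsets), projections.count_scale)
    per_gate = []
    for g in range(projections.n_gates):
        _, snaps, _ = _osem_gate(
            np.asarray(projections.counts[g], dtype=float), model, params,
            projections.count_scale, snapshot_iters=iters, sens=sens)
        per_gate.append(snaps)
    out = {}
    for e, it in zip(ei_values, iters):
        gates = [_as_volume(per_gate[g][it], projections)
                 for g in range(projections.n_gates)]
        out[e] = ReconSeries(gates, ReconParams(it, n_subsets, psf_in_model),
                             projections.protocol.name, e)
    return out


def _as_volume(x, projections: ProjectionSet) -> ImageVolume:
    p = projections.protocol.pixel_mm
    return ImageVolume(x, (p, p, p), "activity", (0, 0, 1),
                       {"protocol": projections.protocol.name})


def poisson_loglik(projections: ProjectionSet, estimate: ImageVolume,
                   psf: PSFModel | None = None, gate: int = 0) -> float:
    """Poisson log-likelihood sum(y log yhat - yhat) of one gate's data under
    an activity estimate; -inf if the model assigns zero mean where counts
    were observed."""
    grid = np.asarray(estimate.grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("estimate must be non-negative")
    y = np.asarray(projections.counts[gate], dtype=float)
    if y.size == 0:
        return 0.0
    if psf is None:
        psf = default_psf(projections.protocol.name)
    model = SystemModel(projections.grid_shape, projections.protocol.pixel_mm,
                        projections.protocol, psf)
    yhat = model.forward(grid) * projections.count_scale
    return _loglik(y, yhat)
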