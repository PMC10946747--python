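"""Multi-coil non-uniform Fourier encoding F_n S_c and helpers.

The encoding operator maps the per-echo image series through the coil
sensitivities and the non-uniform Fourier transform evaluated at the
(possibly delay-shifted) radial sample locations.  The adjoint is exact, so
conjugate-gradient solvers built on the normal equations behave as expected.
Density-compensated gridding provides the reconstruction's initial guess, and
coil sensitivities are estimated from per-coil gridded images with the
adaptive (Walsh) combination method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import ndimage

from .nufft import nufft2, nufft2_adjoint
from .trajectory import RadialTrajectory

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import CoilSensitivities


@dataclass
class EchoImageSeries:
    """Complex images x_n, one per echo time TE_n; shape (n_echoes, N, N)."""

    images: np.ndarray
    echo_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_echoes(self) -> int:
        return self.images.shape[0]

    @property
    def grid_size(self) -> int:
        return self.images.shape[-1]


@dataclass
class KSpaceData:
    """Complex radial samples y_{n,c}: (n_echoes, n_coils, n_spokes, n_readout)."""

    samples: np.ndarray
    echo_times_ms: np.ndarray

    @property
    def n_echoes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]


def forward_echo(
    image: np.ndarray, k_echo: np.ndarray, sens_maps: np.ndarray
) -> np.ndarray:
    """Encode one echo image into all coils: (coil, spoke, readout)."""
    out = np.empty((sens_maps.shape[0],) + k_echo.shape[:-1], dtype=complex)
    for c, s in enumerate(sens_maps):
        out[c] = nufft2(s * image, k_echo)
    return out


def adjoint_echo(
    samples: np.ndarray, k_echo: np.ndarray, sens_maps: np.ndarray
) -> np.ndarray:
    """Adjoint of :func:`forward_echo` for one echo: coil-combined image."""
    n = sens_maps.shape[-1]
    img = np.zeros((n, n), dtype=complex)
    for c, s in enumerate(sens_maps):
        img += np.conj(s) * nufft2_adjoint(samples[c], k_echo, n)
    return img


def forward(
    x: EchoImageSeries, traj: RadialTrajectory, sens: "CoilSensitivities"
) -> KSpaceData:
    """Apply F_n(dk_n) S_c to every echo and coil."""
    if x.grid_size != sens.maps.shape[-1]:
        raise ValueError("image and sensitivity grids disagree")
    out = np.empty(
        (x.n_echoes, sens.n_coils) + traj.k.shape[1:3], dtype=complex
    )
    for n in range(x.n_echoes):
        out[n] = forward_echo(x.images[n], traj.k[n], sens.maps)
    return KSpaceData(samples=out, echo_times_ms=np.asarray(x.echo_times_ms))


def adjoint(
    y: KSpaceData, traj: RadialTrajectory, sens: "CoilSensitivities"
) -> EchoImageSeries:
    """Exact adjoint of :func:`forward` under the Euclidean inner products."""
    n = sens.maps.shape[-1]
    imgs = np.empty((y.n_echoes, n, n), dtype=complex)
    for e in range(y.n_echoes):
        imgs[e] = adjoint_echo(y.samples[e], traj.k[e], sens.maps)
    return EchoImageSeries(images=imgs, echo_times_ms=y.echo_times_ms)


def _ramp_weights(traj: RadialTrajectory) -> np.ndarray:
    """Analytic radial ramp |k|: annular-sector area per sample.

    The DC sample, whose |k| vanishes, is weighted as half the first k-step.
    Used to initialize the iterative density estimate.
    """
    m = np.arange(traj.n_readout)
    radii = np.abs(m - traj.n_readout // 2) * traj.dk_sample
    radii = np.maximum(radii, traj.dk_sample / 2)
    w = radii * traj.dk_sample * np.pi / traj.n_spokes
    return np.broadcast_to(w, traj.k.shape[:-1]).copy()


def density_weights(traj: RadialTrajectory, n_iters: int = 15) -> np.ndarray:
    """Sampling-density compensation, per echo/spoke/sample (k-area units).

    Ramp-initialized Pipe-Menon iteration: each weight is repeatedly divided
    by the local kernel-smoothed sampling density, so that the compensated
    samples approximate a unit-density covering of the sampled k-space
    region.  This removes the few-percent amplitude bias of the plain
    analytic ramp and adapts to echo-dependent spoke subsets.
    """
    from . import nufft as nf

    w = _ramp_weights(traj)
    n = traj.grid_size
    ng = int(round(nf.OVERSAMPLING * n))
    # unit 1-D kernel integral; the 2-D spread of unit-density weights then
    # smooths to ~1 everywhere inside the sampled region
    phi0 = (nf.KERNEL_WIDTH / nf._i0(nf.KB_BETA)) * np.sinh(nf.KB_BETA) / nf.KB_BETA
    cell = 1.0 / nf.OVERSAMPLING**2  # k-area of one oversampled grid cell
    # spread followed by interpolation smooths with the kernel's
    # self-convolution, whose 2-D integral is phi0^4
    norm = phi0**4
    for e in range(traj.k.shape[0]):
        pts = nf._grid_positions(traj.k[e], n, ng)
        we = w[e].reshape(-1) / cell  # to grid-cell units
        for _ in range(n_iters):
            dens = nf._interp2(nf._spread2(pts, we.astype(complex), ng), pts).real
            dens /= norm
            we = we / np.maximum(dens, 1e-12)
        w[e] = (we * cell).reshape(w[e].shape)
    return w


def gridding_recon_coils(y: KSpaceData, traj: RadialTrajectory) -> np.ndarray:
    """Density-compensated adjoint per coil: (echo, coil, N, N) images."""
    n = traj.grid_size
    w = density_weights(traj)
    out = np.empty((y.n_echoes, y.n_coils, n, n), dtype=complex)
    for e in range(y.n_echoes):
        for c in range(y.n_coils):
            out[e, c] = nufft2_adjoint(w[e] * y.samples[e, c], traj.k[e], n)
    # the 1/N^2-normalized adjoint needs an N^2 factor to approximate the
    # continuous inverse transform
    return out * n * n


def gridding_recon(
    y: KSpaceData, traj: RadialTrajectory, sens: "CoilSensitivities | None" = None
) -> EchoImageSeries:
    """Gridded (regridding) reconstruction used as the solver's initial guess.

    With sensitivities, coils are combined as sum(conj(S_c) x_c) / sum|S_c|^2;
    without, the root-sum-of-squares magnitude is returned.
    """
    if y.samples.size == 0:
        raise ValueError("empty k-space data")
    coils = gridding_recon_coils(y, traj)
    if sens is None:
        imgs = np.sqrt(np.sum(np.abs(coils) ** 2, axis=1))
    else:
        rss = np.sum(np.abs(sens.maps) ** 2, axis=0)
        rss = np.maximum(rss, 1e-12)
        imgs = np.sum(np.conj(sens.maps)[None] * coils, axis=1) / rss
    return EchoImageSeries(images=imgs.astype(complex), echo_times_ms=y.echo_times_ms)


def estimate_sensitivities(
    coil_images: np.ndarray, smooth_px: int = 9, support_quantile: float = 0.05
):
    """Adaptive-combination (Walsh) sensitivity estimate from coil images.

    The per-pixel coil covariance is smoothed over a ``smooth_px`` box and its
    dominant eigenvector, phase-referenced to the first coil and normalized to
    unit root-sum-of-squares, is taken as the sensitivity.  The estimate is
    invariant to a global scaling of the data.

    Parameters
    ----------
    coil_images : (n_coils, N, N) complex (e.g. first-echo gridded images),
        or (n_echoes, n_coils, N, N), in which case echoes are averaged into
        the covariance.
    """
    ci = np.asarray(coil_images, dtype=complex)
    if ci.ndim == 4:
        cov = np.einsum("ecxy,edxy->xycd", ci, np.conj(ci))
    elif ci.ndim == 3:
        cov = np.einsum("cxy,dxy->xycd", ci, np.conj(ci))
    else:
        raise ValueError("expected (C, N, N) or (E, C, N, N) coil images")
    if not np.any(cov):
        raise ValueError("all-zero coil images: cannot estimate sensitivities")
    for a in range(cov.shape[2]):
        for b in range(cov.shape[3]):
            cov[:, :, a, b] = ndimage.uniform_filter(
                cov[:, :, a, b].real, smooth_px
            ) + 1j * ndimage.uniform_filter(cov[:, :, a, b].imag, smooth_px)
    vals, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    dom = vecs[..., -1]  # (N, N, C)
    # phase-reference to coil 0 so the maps are smooth, then unit-RSS
    phase = np.exp(-1j * np.angle(dom[..., :1]))
    dom = dom * phase
    maps = np.moveaxis(dom, -1, 0)
    from .phantom import CoilSensitivities

    return CoilSensitivities(maps=maps)
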