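"""Numerical brain phantom: anatomy, tissue parameters, coils, k-space.

The phantom emulates a 2-D labeled brain slice with four compartments --
grey matter (GM), white matter (WM), cerebrospinal fluid (CSF) and skull --
each carrying a tissue-constant effective transverse relaxation time T2* and
proton density M0.  The default anatomy is procedural (seeded smooth closed
contours: skull annulus, cortical GM ribbon, WM interior, a connected CSF
ventricle), so the package builds and tests without any external download; a
user-supplied labeled image can be passed instead for studies that require a
specific anatomy.

Multi-echo images follow the mono-exponential decay x_n = M0 exp(-TE_n/T2*),
and raw data are generated by the package's own encoding operator with
optional gradient-delay corruption and complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import encoding
from .encoding import EchoImageSeries, KSpaceData
from .trajectory import DelaySet, RadialTrajectory, apply_gradient_delay

LABEL_BACKGROUND = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_CSF = 3
LABEL_SKULL = 4

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_GM: "GM",
    LABEL_WM: "WM",
    LABEL_CSF: "CSF",
    LABEL_SKULL: "skull",
}

#: Tissue-constant T2* in ms.  Skull is not part of the evaluated region and
#: its short T2* is a configurable package default.
T2STAR_MS = {LABEL_GM: 84.0, LABEL_WM: 66.0, LABEL_CSF: 2000.0, LABEL_SKULL: 10.0}

#: Proton density on every tissue pixel (arbitrary units).
M0_TISSUE = 100.0

DEFAULT_ECHO_TIMES_MS = tuple(5.0 * (i + 1) for i in range(8))


@dataclass
class TissuePhantom:
    """Labeled anatomy plus tissue-constant parameter maps."""

    labels: np.ndarray
    t2star_ms: np.ndarray | None = None
    m0: np.ndarray | None = None

    @property
    def grid_size(self) -> int:
        return self.labels.shape[0]

    def tissue_mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.labels, labels)


@dataclass
class CoilSensitivities:
    """Complex receive-sensitivity maps, shape (n_coils, N, N)."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class PhantomConfig:
    """Simulation conditions for one phantom acquisition."""

    noise_level: float = 0.0
    seed: int = 0
    echo_times_ms: tuple = DEFAULT_ECHO_TIMES_MS
    delay_dwell: tuple[float, float] = (0.0, 0.0)
    grid_size: int = 256
    n_coils: int = 8
    skull_t2star_ms: float = T2STAR_MS[LABEL_SKULL]

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")


def _smooth_blob(phi: np.ndarray, rng: np.random.Generator, amp: float = 0.02):
    """Gentle seeded angular modulation of a closed contour radius."""
    r = np.ones_like(phi)
    for harmonic in range(2, 6):
        a = rng.uniform(0.2, 1.0) * amp
        p = rng.uniform(0, 2 * np.pi)
        r += a * np.cos(harmonic * phi + p)
    return r


def make_anatomy(grid_size: int = 256, seed: int = 0) -> TissuePhantom:
    """Procedural brain-like label map (labels only; parameters unassigned).

    Nested smooth closed regions: a skull annulus, a cortical GM ribbon, the
    WM interior and a single connected butterfly-shaped CSF ventricle.  The
    head covers well over 20% of the grid and the output is deterministic
    given the seed.
    """
    if grid_size < 32:
        raise ValueError("grid_size must be at least 32")
    rng = np.random.default_rng(seed)
    n = grid_size
    c = np.arange(n) - n // 2
    # normalized coordinates, head slightly taller than wide
    x, y = np.meshgrid(c / (0.80 * n / 2), c / (0.95 * n / 2), indexing="ij")
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)

    head = _smooth_blob(phi, rng)
    brain = head * _smooth_blob(phi, rng, amp=0.015)
    wm = brain * _smooth_blob(phi, rng, amp=0.025)

    labels = np.zeros((n, n), dtype=np.int16)
    labels[r < 0.95 * head] = LABEL_SKULL
    labels[r < 0.82 * brain] = LABEL_GM
    labels[r < 0.64 * wm] = LABEL_WM

    # connected two-lobed ventricle: local polar contour around mid-brain
    vx = x - rng.uniform(-0.03, 0.03)
    vy = y - rng.uniform(-0.05, 0.02)
    vr = np.hypot(vx, vy)
    vphi = np.arctan2(vy, vx)
    ventricle = vr < 0.17 * (1 + 0.55 * np.cos(2 * vphi))
    labels[ventricle & (labels == LABEL_WM)] = LABEL_CSF
    return TissuePhantom(labels=labels)


def assign_tissue_params(
    phantom: TissuePhantom, skull_t2star_ms: float = T2STAR_MS[LABEL_SKULL]
) -> TissuePhantom:
    """Attach tissue-constant T2* (ms) and M0 maps to a labeled anatomy."""
    known = set(LABEL_NAMES)
    present = set(np.unique(phantom.labels).tolist())
    if not present <= known:
        raise ValueError(f"unknown label values: {sorted(present - known)}")
    t2s = np.zeros(phantom.labels.shape)
    table = {**T2STAR_MS, LABEL_SKULL: skull_t2star_ms}
    for label, value in table.items():
        t2s[phantom.labels == label] = value
    m0 = np.where(phantom.labels > 0, M0_TISSUE, 0.0)
    return TissuePhantom(labels=phantom.labels, t2star_ms=t2s, m0=m0)


def simulate_coils(
    n_coils: int = 8, grid_size: int = 256, uniform: bool = False
) -> CoilSensitivities:
    """Smooth complex sensitivities of circularly arranged receive elements.

    Each virtual element sits on a circle of radius 1.25 (normalized FOV/2
    units) and contributes a Gaussian magnitude profile with a mild linear
    phase along its viewing direction; ``uniform=True`` returns all-ones maps
    (a single ideal body coil).  Deterministic by construction.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = grid_size
    if uniform:
        return CoilSensitivities(maps=np.ones((n_coils, n, n), dtype=complex))
    c = (np.arange(n) - n // 2) / (n / 2)
    x, y = np.meshgrid(c, c, indexing="ij")
    maps = np.empty((n_coils, n, n), dtype=complex)
    for i in range(n_coils):
        alpha = 2 * np.pi * i / n_coils
        cx, cy = 1.25 * np.cos(alpha), 1.25 * np.sin(alpha)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.85**2))
        phase = np.pi * 0.4 * (x * np.cos(alpha) + y * np.sin(alpha)) + alpha / 3
        maps[i] = mag * np.exp(1j * phase)
    return CoilSensitivities(maps=maps)


def simulate_multiecho_images(
    phantom: TissuePhantom, echo_times_ms
) -> EchoImageSeries:
    """Mono-exponential echo images x_n = M0 exp(-TE_n / T2*), zero phase."""
    if phantom.t2star_ms is None or phantom.m0 is None:
        raise ValueError("phantom parameter maps not assigned")
    te = np.asarray(echo_times_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(
            -te[:, None, None] / np.where(phantom.t2star_ms > 0, phantom.t2star_ms, np.inf)
        )
    imgs = phantom.m0[None] * decay
    return EchoImageSeries(images=imgs.astype(complex), echo_times_ms=te)


def add_noise(kspace: KSpaceData, noise_level: float, seed: int) -> KSpaceData:
    """Add i.i.d. complex Gaussian noise scaled to the first-echo signal.

    The per-component standard deviation is
    ``noise_level * mean(|noiseless first-echo samples|) / M0_TISSUE``, tying
    the stated noise levels (0, 0.1, 0.5, 1) to the proton-density scale of
    100 regardless of grid size or coil count.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    if noise_level == 0:
        return KSpaceData(
            samples=kspace.samples.copy(), echo_times_ms=kspace.echo_times_ms
        )
    rng = np.random.default_rng(seed)
    sigma = noise_level * np.mean(np.abs(kspace.samples[0])) / M0_TISSUE
    noise = rng.normal(scale=sigma, size=kspace.samples.shape + (2,))
    return KSpaceData(
        samples=kspace.samples + noise[..., 0] + 1j * noise[..., 1],
        echo_times_ms=kspace.echo_times_ms,
    )


def simulate_acquisition(
    config: PhantomConfig,
    traj: RadialTrajectory,
    phantom: TissuePhantom | None = None,
    sens: CoilSensitivities | None = None,
):
    """Full simulation: anatomy -> echo images -> corrupted noisy k-space.

    Returns ``(kspace, phantom, sens, images)``.  The k-space samples are
    evaluated on the delay-corrupted trajectory, but the caller keeps only the
    nominal one -- the reconstruction is never told the simulated delays.
    """
    if phantom is None:
        phantom = make_anatomy(config.grid_size, config.seed)
    if phantom.t2star_ms is None:
        phantom = assign_tissue_params(phantom, config.skull_t2star_ms)
    if sens is None:
        sens = simulate_coils(config.n_coils, config.grid_size)
    images = simulate_multiecho_images(phantom, config.echo_times_ms)
    true_delays = DelaySet.uniform(*config.delay_dwell)
    corrupted = apply_gradient_delay(traj, true_delays)
    kspace = encoding.forward(images, corrupted, sens)
    kspace = add_noise(kspace, config.noise_level, config.seed)
    return kspace, phantom, sens, images
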