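"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import radstar.evaluate as ev
import radstar.phantom as ph
import radstar.trajectory as tj


def ndft2(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Direct-summation non-uniform DFT oracle (O(M N^2), tiny inputs only).

    Mirrors the package convention: s(k) = (1/N^2) sum_r x[r] e^{-2i pi k.r/N}
    with centered pixel coordinates.
    """
    n = x.shape[0]
    c = np.arange(n) - n // 2
    rx, ry = np.meshgrid(c, c, indexing="ij")
    k = np.asarray(k, dtype=float).reshape(-1, 2)
    out = np.empty(k.shape[0], dtype=complex)
    for j, (kx, ky) in enumerate(k):
        out[j] = np.sum(x * np.exp(-2j * np.pi * (kx * rx + ky * ry) / n))
    return out / n**2


def ndft2_adjoint(y: np.ndarray, k: np.ndarray, n: int) -> np.ndarray:
    """Adjoint of :func:`ndft2` by direct summation."""
    c = np.arange(n) - n // 2
    rx, ry = np.meshgrid(c, c, indexing="ij")
    k = np.asarray(k, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=complex).reshape(-1)
    img = np.zeros((n, n), dtype=complex)
    for j, (kx, ky) in enumerate(k):
        img += y[j] * np.exp(2j * np.pi * (kx * rx + ky * ry) / n)
    return img / n**2


@pytest.fixture(scope="session")
def quick_profile() -> ev.StudyProfile:
    return ev.StudyProfile.quick()


@pytest.fixture(scope="session")
def quick_phantom(quick_profile):
    """Noiseless, zero-delay, fully sampled quick-profile acquisition."""
    cfg = ph.PhantomConfig(
        noise_level=0.0,
        seed=0,
        echo_times_ms=quick_profile.echo_times_ms,
        delay_dwell=(0.0, 0.0),
        grid_size=quick_profile.grid_size,
        n_coils=quick_profile.n_coils,
    )
    traj = tj.golden_angle_spokes(
        quick_profile.n_spokes,
        quick_profile.n_readout,
        quick_profile.grid_size,
        len(quick_profile.echo_times_ms),
    )
    kspace, truth, sens, images = ph.simulate_acquisition(cfg, traj)
    return {
        "config": cfg,
        "traj": traj,
        "kspace": kspace,
        "truth": truth,
        "sens": sens,
        "images": images,
    }


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 4-connected components of a boolean mask (BFS flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    n_comp = 0
    idx = np.argwhere(mask)
    for start in map(tuple, idx):
        if seen[start]:
            continue
        n_comp += 1
        stack = [start]
        seen[start] = True
        while stack:
            i, j = stack.pop()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < mask.shape[0] and 0 <= b < mask.shape[1]:
                    if mask[a, b] and not seen[a, b]:
                        seen[a, b] = True
                        stack.append((a, b))
    return n_comp
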