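"""Golden-angle radial trajectories, gradient-delay corruption, undersampling.

A multi-echo radial acquisition reads one spoke per excitation; all echoes of
an excitation share the spoke angle, but successive echoes of a bipolar
multi-gradient-echo readout traverse the line in alternating directions
(polarity +1 for odd echoes, -1 for even echoes, 1-based).

A gradient timing delay on a physical gradient axis shifts every sample of a
spoke rigidly along that axis' projection of the readout direction.  With
delays ``(tau_x, tau_y)`` in dwell-time units, a spoke at angle ``theta`` with
polarity ``p`` is shifted by

    delta_k = -p * dk * (tau_x * cos(theta), tau_y * sin(theta))

where ``dk`` is the k-space step between adjacent readout samples.  The sign
convention (positive delay shifts samples opposite to the readout direction)
is internal; only consistency between corruption and estimation matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GOLDEN_ANGLE_DEG = 111.246

#: Largest delay magnitude (dwell units) accepted by the corruption model.
MAX_DELAY_DWELL = 5.0


@dataclass
class DelaySet:
    """Per-axis gradient delays in dwell-time units, one pair per polarity.

    ``odd`` applies to positive-polarity (odd, 1-based) echoes and ``even`` to
    negative-polarity echoes.  The simulated corruptions of the study use the
    same pair for both polarities.
    """

    odd: tuple[float, float] = (0.0, 0.0)
    even: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def uniform(cls, tau_x: float, tau_y: float) -> "DelaySet":
        """Same delay pair for both readout polarities."""
        return cls(odd=(tau_x, tau_y), even=(tau_x, tau_y))

    def as_array(self) -> np.ndarray:
        return np.array([*self.odd, *self.even], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "DelaySet":
        v = np.asarray(v, dtype=float)
        return cls(odd=(v[0], v[1]), even=(v[2], v[3]))

    def validate(self, limit: float = MAX_DELAY_DWELL) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError("delays must be finite")
        if np.max(np.abs(v)) > limit:
            raise ValueError(f"delay magnitude exceeds {limit} dwell")


@dataclass
class RadialTrajectory:
    """Sample coordinates of a multi-echo radial acquisition.

    Attributes
    ----------
    angles_deg : (n_echoes, n_spokes) nominal spoke angles in degrees.
    k : (n_echoes, n_spokes, n_readout, 2) sample coordinates in cycles/FOV,
        ordered (kx, ky).
    polarity : (n_echoes,) readout polarity, +1 odd echoes / -1 even echoes.
    dk_sample : k-space step between adjacent readout samples (grid/readout).
    grid_size : nominal reconstruction matrix size N.
    """

    angles_deg: np.ndarray
    k: np.ndarray
    polarity: np.ndarray
    dk_sample: float
    grid_size: int
    delays: DelaySet = field(default_factory=DelaySet)

    @property
    def n_echoes(self) -> int:
        return self.k.shape[0]

    @property
    def n_spokes(self) -> int:
        return self.k.shape[1]

    @property
    def n_readout(self) -> int:
        return self.k.shape[2]


def golden_angle_spokes(
    n_spokes: int = 402,
    n_readout: int = 512,
    grid_size: int = 256,
    n_echoes: int = 8,
    golden_angle_deg: float = GOLDEN_ANGLE_DEG,
) -> RadialTrajectory:
    """Nominal golden-angle trajectory shared by all echoes of an acquisition.

    Spoke ``i`` lies at ``mod(i * 111.246, 360)`` degrees; sample ``m`` of a
    positive-polarity spoke sits at ``(m - n_readout/2) * dk`` along the spoke
    direction with ``dk = grid_size / n_readout`` cycles/FOV.  Even echoes
    traverse the same line with the sample order reversed (bipolar readout).
    """
    if min(n_spokes, n_readout, grid_size, n_echoes) <= 0:
        raise ValueError("all trajectory dimensions must be positive")
    angles = np.mod(np.arange(n_spokes) * golden_angle_deg, 360.0)
    dk = grid_size / n_readout
    radii = (np.arange(n_readout) - n_readout // 2) * dk
    theta = np.deg2rad(angles)
    direction = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (spoke, 2)
    base = radii[None, :, None] * direction[:, None, :]  # (spoke, readout, 2)
    polarity = np.where(np.arange(n_echoes) % 2 == 0, 1.0, -1.0)  # 1-based odd
    k = polarity[:, None, None, None] * base[None]
    return RadialTrajectory(
        angles_deg=np.broadcast_to(angles, (n_echoes, n_spokes)).copy(),
        k=k,
        polarity=polarity,
        dk_sample=dk,
        grid_size=grid_size,
    )


def delay_shifts(traj: RadialTrajectory, delays: DelaySet) -> np.ndarray:
    """Per-spoke rigid k-space shifts, shape (n_echoes, n_spokes, 2)."""
    theta = np.deg2rad(traj.angles_deg)
    tau = np.where(
        (traj.polarity > 0)[:, None],
        np.asarray(delays.odd),
        np.asarray(delays.even),
    )  # (n_echoes, 2)
    shift = np.empty(traj.angles_deg.shape + (2,))
    shift[..., 0] = tau[:, None, 0] * np.cos(theta)
    shift[..., 1] = tau[:, None, 1] * np.sin(theta)
    return -traj.polarity[:, None, None] * traj.dk_sample * shift


def apply_gradient_delay(
    traj: RadialTrajectory, delays: DelaySet, limit: float = MAX_DELAY_DWELL
) -> RadialTrajectory:
    """Shift every spoke rigidly according to per-axis gradient delays.

    The shift composes additively: applying ``-tau`` afterwards restores the
    nominal trajectory exactly.
    """
    delays.validate(limit)
    k = traj.k + delay_shifts(traj, delays)[:, :, None, :]
    total = DelaySet(
        odd=tuple(np.add(traj.delays.odd, delays.odd)),
        even=tuple(np.add(traj.delays.even, delays.even)),
    )
    return replace(traj, k=k, delays=total)


def _subset(traj: RadialTrajectory, idx_per_echo: np.ndarray) -> RadialTrajectory:
    e = np.arange(traj.n_echoes)[:, None]
    return replace(
        traj,
        angles_deg=traj.angles_deg[e, idx_per_echo],
        k=traj.k[e, idx_per_echo],
    )


def undersample_uniform(samples, traj: RadialTrajectory, keep_fraction: float):
    """Keep the last ``keep_fraction`` of acquired spokes, same for all echoes.

    Removing spokes from the beginning of the acquisition emulates a shortened
    scan while avoiding transient non-steady-state spokes.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = traj.n_spokes
    m = int(np.ceil(keep_fraction * n))
    keep = np.arange(n - m, n)
    idx = np.broadcast_to(keep, (traj.n_echoes, m))
    return samples[:, :, keep, :], _subset(traj, idx)


def undersample_alternate(samples, traj: RadialTrajectory, keep_fraction: float):
    """Odd echoes keep the first spokes, even echoes the last spokes.

    At ``keep_fraction = 0.5`` the two spoke sets are disjoint and their union
    is the full acquisition; each echo's retained angles remain consecutive
    golden-angle increments, so every echo keeps near-uniform angular coverage.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = traj.n_spokes
    m = int(np.ceil(keep_fraction * n))
    first = np.arange(m)
    last = np.arange(n - m, n)
    idx = np.where((traj.polarity > 0)[:, None], first, last)
    return _take_samples(samples, idx), _subset(traj, idx)


def _take_samples(samples: np.ndarray, idx_per_echo: np.ndarray) -> np.ndarray:
    # samples: (echo, coil, spoke, readout); idx_per_echo: (echo, m)
    e = np.arange(samples.shape[0])[:, None, None]
    c = np.arange(samples.shape[1])[None, :, None]
    return samples[e, c, idx_per_echo[:, None, :]]
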