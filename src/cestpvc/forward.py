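"""Continuous-wave multi-pool Bloch-McConnell forward model for CEST z-spectra.

A z-spectrum is the water longitudinal magnetization, normalized to the
unsaturated signal S0, measured after a long off-resonance saturation pulse as
a function of the saturation frequency offset.  Each exchanging proton
compartment (water, amide, semisolid MT, NOE) is a :class:`Pool`; the coupled
magnetization dynamics under continuous-wave (CW) irradiation form a linear
ODE ``dM/dt = A M + b`` over the stacked (x, y, z) components of every pool,
solved exactly by eigendecomposition / matrix exponential.

Pulsed saturation protocols are mapped onto this CW model through their
power-equivalent amplitude (:func:`cw_equivalent_b1`).

Conventions
-----------
* Positive ppm offsets are downfield of water; amide resonates at +3.5 ppm.
* ppm -> rad/s conversion is ``2*pi * larmor_MHz * ppm``.
* The first pool is always water and carries the absolute equilibrium signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAMMA_H",
    "Pool",
    "SaturationProtocol",
    "PulseTrain",
    "ZSpectrum",
    "assemble_generator",
    "simulate_zspectrum",
    "cw_equivalent_b1",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8


class ConfigurationError(ValueError):
    """Raised for inconsistent model or protocol configuration."""


@dataclass(frozen=True)
class Pool:
    """One exchanging magnetization compartment.

    Parameters
    ----------
    name:
        Label, e.g. ``"water"``, ``"amide"``, ``"mt"``, ``"noe"``.
    m0:
        Equilibrium magnetization.  For the water pool this is the absolute
        (dimensionless-scale) signal; for solute pools it is the concentration
        relative to the water pool.
    kex:
        Exchange rate pool -> water, s^-1.  Ignored for the water pool.
    t1, t2:
        Longitudinal / transverse relaxation times, s.
    dw:
        Chemical shift relative to water, ppm.  Water has ``dw = 0``.
    """

    name: str
    m0: float
    kex: float
    t1: float
    t2: float
    dw: float

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError(f"pool {self.name!r}: m0 must be >= 0, got {self.m0}")
        if self.kex < 0:
            raise ValueError(f"pool {self.name!r}: kex must be >= 0, got {self.kex}")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(
                f"pool {self.name!r}: relaxation times must be positive "
                f"(t1={self.t1}, t2={self.t2})"
            )
        if self.t2 > self.t1 * (1 + 1e-12):
            raise ValueError(f"pool {self.name!r}: t2 must not exceed t1")

    def with_m0(self, m0: float) -> "Pool":
        return replace(self, m0=m0)


@dataclass(frozen=True)
class SaturationProtocol:
    """CW-equivalent saturation protocol.

    ``b1`` is the CW-equivalent amplitude in uT, ``t_sat`` the total
    saturation duration in s, ``offsets`` the sampled frequencies in ppm and
    ``larmor`` the water Larmor frequency in MHz (sets the ppm -> rad/s
    conversion; 127.74 MHz corresponds to 3 T).  ``reference_offset`` marks
    the offset treated as the unsaturated reference.
    """

    b1: float
    t_sat: float
    offsets: tuple[float, ...]
    larmor: float = 127.74
    reference_offset: float = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if self.t_sat <= 0:
            raise ValueError("t_sat must be positive")
        if len(self.offsets) == 0:
            raise ValueError("offsets must be non-empty")
        if self.larmor <= 0:
            raise ValueError("larmor must be positive")

    def with_offsets(self, offsets: Sequence[float]) -> "SaturationProtocol":
        return replace(self, offsets=tuple(offsets))


@dataclass(frozen=True)
class PulseTrain:
    """A pulsed saturation train, kept to document protocol provenance.

    The flip angle fixes the pulse area (``integral of gamma*B1 dt``); for a
    Gaussian shape, ``gaussian_truncation`` is the fraction of the peak
    amplitude at the pulse edges.
    """

    n_pulses: int
    flip_angle: float
    pulse_duration: float
    inter_pulse_delay: float
    shape: str = "rectangular"
    gaussian_truncation: float | None = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.flip_angle < 0:
            raise ValueError("flip_angle must be >= 0")
        if self.pulse_duration < 0 or self.inter_pulse_delay < 0:
            raise ValueError("durations must be >= 0")
        if self.shape not in ("rectangular", "gaussian"):
            raise ConfigurationError(f"unknown pulse shape {self.shape!r}")

    @property
    def total_duration(self) -> float:
        """Total train duration n_pulses * (pulse + delay), s."""
        return self.n_pulses * (self.pulse_duration + self.inter_pulse_delay)


@dataclass
class ZSpectrum:
    """Normalized saturation-transfer spectrum.

    ``signal`` holds the water z-magnetization at each ppm offset divided by
    the unsaturated signal ``s0``; ``s0 * signal`` recovers the absolute
    signal.
    """

    offsets: np.ndarray
    signal: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.offsets.shape != self.signal.shape:
            raise ValueError("offsets and signal must have the same length")

    @property
    def absolute(self) -> np.ndarray:
        return self.signal * self.s0


def _validate_pools(pools: Sequence[Pool]) -> None:
    if len(pools) == 0:
        raise ValueError("at least one pool (water) is required")
    if abs(pools[0].dw) > 1e-12:
        raise ConfigurationError(
            f"first pool must be water with dw=0, got dw={pools[0].dw} ppm"
        )
    if pools[0].m0 <= 0:
        raise ValueError("water pool m0 must be positive")


def _assemble_batch(
    pools: Sequence[Pool],
    b1: float,
    offsets: np.ndarray,
    b0_shift: float,
    larmor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (n_offsets, 3n, 3n) generator matrices and the shared (3n,) b."""
    n = len(pools)
    dim = 3 * n
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    n_off = offsets.shape[0]

    m0 = np.array([p.m0 for p in pools])
    # solute m0 is a concentration relative to the water pool; water m0 sets
    # the absolute scale, so the normalized spectrum is scale-invariant
    m0[1:] *= m0[0]
    r1 = np.array([1.0 / p.t1 for p in pools])
    r2 = np.array([1.0 / p.t2 for p in pools])
    kex = np.array([p.kex for p in pools])
    kex[0] = 0.0
    dw = np.array([p.dw for p in pools])
    # detailed balance: water -> pool rate scaled by relative concentration
    kback = kex * m0 / m0[0]

    w1 = GAMMA_H * b1 * 1e-6  # rad/s
    # per-pool off-resonance in the rotating frame, rad/s
    delta = 2.0 * math.pi * larmor * (offsets[:, None] - dw[None, :] - b0_shift)

    A = np.zeros((n_off, dim, dim))
    ix = 3 * np.arange(n)
    iy = ix + 1
    iz = ix + 2

    out_rate = kex.copy()
    out_rate[0] = kback.sum()

    for c, idx in enumerate((ix, iy, iz)):
        rel = r2 if c < 2 else r1
        A[:, idx, idx] = -(rel + out_rate)[None, :]
        # exchange coupling with water, identical for all three components
        A[:, idx[0], idx[1:]] = kex[None, 1:]
        A[:, idx[1:], idx[0]] = kback[None, 1:]
    # off-resonance precession
    A[:, ix, iy] = -delta
    A[:, iy, ix] = delta
    # saturation nutation about x
    A[:, iy, iz] = w1
    A[:, iz, iy] = -w1

    b = np.zeros(dim)
    b[iz] = r1 * m0
    return A, b


def assemble_generator(
    pools: Sequence[Pool],
    b1: float,
    offset: float,
    b0_shift: float = 0.0,
    larmor: float = 127.74,
) -> tuple[np.ndarray, np.ndarray]:
    """Generator ``(A, b)`` of the CW Bloch-McConnell ODE ``dM/dt = A M + b``.

    ``M`` stacks (x, y, z) components pool by pool, water first, so the
    system dimension is ``3 * n_pools``.  Exchange terms obey detailed
    balance (water->pool rate ``kex * m0_pool / m0_water``), the saturation
    coupling is ``gamma * B1`` and off-resonance terms derive from
    ``offset - dw - b0_shift`` converted to rad/s via the Larmor frequency.
    """
    _validate_pools(pools)
    A, b = _assemble_batch(pools, b1, np.array([offset]), b0_shift, larmor)
    return A[0], b


def _propagate(A: np.ndarray, b: np.ndarray, m_init: np.ndarray, t: float) -> np.ndarray:
    """Exact solution M(t) of dM/dt = A M + b from M(0), batched over axis 0.

    Uses eigendecomposition of each generator; falls back to the matrix
    exponential of the affine-augmented system when a generator is close to
    defective or singular.
    """
    n_off, dim, _ = A.shape
    out = np.empty((n_off, dim))
    try:
        m_ss = np.linalg.solve(A, np.broadcast_to(-b, (n_off, dim))[:, :, None])[:, :, 0]
        w, v = np.linalg.eig(A)
        c = np.linalg.solve(v, (m_init[None, :] - m_ss)[:, :, None])[:, :, 0]
        out = np.real(np.einsum("oij,oj->oi", v, np.exp(w * t) * c)) + m_ss
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    # robust fallback: exp of the augmented homogeneous system
    aug = np.zeros((dim + 1, dim + 1))
    m_aug = np.concatenate([m_init, [1.0]])
    for i in range(n_off):
        aug[:dim, :dim] = A[i]
        aug[:dim, dim] = b
        out[i] = (expm(aug * t) @ m_aug)[:dim]
    return out


def simulate_zspectrum(
    pools: Sequence[Pool],
    protocol: SaturationProtocol,
    b0_shift: float = 0.0,
) -> ZSpectrum:
    """Simulate the z-spectrum of a pool system under CW saturation.

    Magnetization starts at thermal equilibrium and is propagated over
    ``t_sat`` with the exact matrix-exponential solution of the linear BM
    system; the returned signal is the water z-component normalized by the
    water equilibrium signal ``s0``.  At ``b1 = 0`` equilibrium is a fixed
    point of the free relaxation dynamics, so the signal is identically 1.
    """
    _validate_pools(pools)
    offsets = np.asarray(protocol.offsets, dtype=float)
    s0 = pools[0].m0
    if protocol.b1 == 0.0:
        return ZSpectrum(offsets, np.ones_like(offsets), s0)

    A, b = _assemble_batch(pools, protocol.b1, offsets, b0_shift, protocol.larmor)
    m_init = np.zeros(3 * len(pools))
    m_init[2::3] = [p.m0 for p in pools]
    m_init[5::3] *= pools[0].m0  # solute concentrations are relative to water
    m_final = _propagate(A, b, m_init, protocol.t_sat)
    if not np.all(np.isfinite(m_final)):
        bad = offsets[~np.isfinite(m_final).all(axis=1)]
        raise FloatingPointError(
            f"numerical overflow while propagating magnetization at offsets {bad} ppm"
        )
    return ZSpectrum(offsets, m_final[:, 2] / s0, s0)


def cw_equivalent_b1(train: PulseTrain, average_over: str = "cycle") -> float:
    """Power-equivalent CW amplitude of a pulsed saturation train, uT.

    The peak amplitude is fixed by the flip angle through the pulse area
    ``integral gamma B1(t) dt = flip``; the CW equivalent is the RMS of
    ``B1(t)`` over the full pulse+delay cycle (``average_over="cycle"``,
    default) or over the pulse alone (``average_over="pulse"``).
    """
    if average_over not in ("cycle", "pulse"):
        raise ConfigurationError(f"average_over must be 'cycle' or 'pulse', got {average_over!r}")
    if train.flip_angle == 0:
        return 0.0
    if train.pulse_duration == 0:
        raise ConfigurationError("pulse_duration must be positive for a nonzero flip angle")
    flip = math.radians(train.flip_angle)
    tp = train.pulse_duration
    cycle = tp + train.inter_pulse_delay

    if train.shape == "rectangular":
        peak = flip / (GAMMA_H * tp)  # Tesla
        sq_integral = peak**2 * tp
    else:
        trunc = train.gaussian_truncation
        if trunc is None:
            raise ConfigurationError(
                "gaussian pulse shape requires the gaussian_truncation parameter"
            )
        if not 0 < trunc < 1:
            raise ConfigurationError("gaussian_truncation must lie in (0, 1)")
        # B1(t) = peak * exp(-t^2 / (2 sigma^2)) on t in [-tp/2, tp/2], with
        # truncation fraction trunc at the edges
        sigma = (tp / 2.0) / math.sqrt(2.0 * math.log(1.0 / trunc))
        area_factor = sigma * math.sqrt(2.0 * math.pi) * math.erf(tp / (2.0 * math.sqrt(2.0) * sigma))
        peak = flip / (GAMMA_H * area_factor)
        sq_integral = peak**2 * sigma * math.sqrt(math.pi) * math.erf(tp / (2.0 * sigma))

    window = cycle if average_over == "cycle" else tp
    return math.sqrt(sq_integral / window) * 1e6
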