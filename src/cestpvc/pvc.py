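"""Partial-volume mixture of a 1-pool CSF spectrum and a 4-pool tissue spectrum.

A voxel at a tissue-CSF boundary contains a tissue fraction ``[tissue]`` (the
partial volume estimate, PVE) and a CSF fraction ``1 - [tissue]``.  Its
z-spectrum is modelled as the tissue-fraction-weighted sum

    S_total(w) = (1 - [tissue]) * S_CSF(w) + [tissue] * S_tissue(w)

where both component spectra share the voxel's B0 shift and are expressed on
one common scale: the CSF equilibrium signal is pinned to the tissue water
signal through the CSF/tissue concentration ratio, and the mixture is
normalized by the combined unsaturated signal
``s0 = (1 - [tissue]) * m0_CSF + [tissue] * m0_water``.  With the component
spectra normalized by that same ``s0``, the weighted-sum identity above holds
at machine precision.

Because CSF carries no amide pool, the apparent APT effect in the raw mixed
spectrum is diluted as the tissue fraction falls; the partial-volume-corrected
fit undoes that dilution by fitting the mixture with the voxel's known PVE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cestpvc.forward import Pool, SaturationProtocol, ZSpectrum, simulate_zspectrum
from cestpvc.params import CSF_TISSUE_RATIO, default_csf_pool, default_tissue_pools

__all__ = [
    "CompartmentModel",
    "TissueFraction",
    "pvc_spectrum",
    "mixture_components",
    "constrain_csf_m0",
    "estimate_csf_tissue_ratio",
    "RatioEstimationError",
]


class RatioEstimationError(ValueError):
    """The CSF/tissue concentration ratio is not identifiable from the data."""


@dataclass(frozen=True)
class TissueFraction:
    """Tissue partial volume estimate in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"tissue PVE must lie in [0, 1], got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass
class CompartmentModel:
    """Two-compartment description of a voxel: 4-pool tissue + 1-pool CSF.

    ``csf_tissue_ratio`` links the CSF equilibrium signal to the tissue water
    signal; the CSF pool's m0 is always derived through
    :func:`constrain_csf_m0` and is not a free quantity.
    """

    tissue_pools: list[Pool] = field(default_factory=default_tissue_pools)
    csf_pool: Pool = field(default_factory=default_csf_pool)
    csf_tissue_ratio: float = CSF_TISSUE_RATIO

    def __post_init__(self) -> None:
        if self.csf_tissue_ratio <= 0:
            raise ValueError("csf_tissue_ratio must be positive")
        if abs(self.csf_pool.dw) > 1e-12:
            raise ValueError("CSF pool must resonate at the water frequency (dw=0)")

    @property
    def tissue_water_m0(self) -> float:
        return self.tissue_pools[0].m0

    def constrained_csf_pool(self) -> Pool:
        """CSF pool with m0 pinned to ratio * tissue water m0."""
        return self.csf_pool.with_m0(
            constrain_csf_m0(self.tissue_water_m0, self.csf_tissue_ratio)
        )


def constrain_csf_m0(tissue_water_m0: float, ratio: float) -> float:
    """CSF equilibrium signal implied by the tissue water signal.

    The CSF concentration is never fitted freely — left free, the tissue
    compartment alone can absorb the whole signal and the mixture degenerates
    to the tissue model — so it is fixed at ``ratio * tissue_water_m0``.
    """
    if tissue_water_m0 <= 0:
        raise ValueError(f"tissue water m0 must be positive, got {tissue_water_m0}")
    if ratio <= 0:
        raise ValueError(f"csf/tissue ratio must be positive, got {ratio}")
    return ratio * tissue_water_m0


def mixture_components(
    model: CompartmentModel,
    pve: TissueFraction | float,
    protocol: SaturationProtocol,
    b0_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Absolute CSF and tissue spectra plus the combined unsaturated signal.

    Returns ``(csf_abs, tissue_abs, s0_total)`` where the mixture's absolute
    signal is ``(1-p) * csf_abs + p * tissue_abs`` and
    ``s0_total = (1-p) * m0_csf + p * m0_water``.
    """
    p = float(pve)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"tissue PVE must lie in [0, 1], got {p}")
    csf = model.constrained_csf_pool()
    tissue_abs = simulate_zspectrum(model.tissue_pools, protocol, b0_shift).absolute
    csf_abs = simulate_zspectrum([csf], protocol, b0_shift).absolute
    s0_total = (1.0 - p) * csf.m0 + p * model.tissue_water_m0
    return csf_abs, tissue_abs, s0_total


def pvc_spectrum(
    model: CompartmentModel,
    pve: TissueFraction | float,
    protocol: SaturationProtocol,
    b0_shift: float = 0.0,
) -> ZSpectrum:
    """Mixed-voxel z-spectrum: tissue-fraction-weighted CSF + tissue sum.

    Both compartments share ``b0_shift`` and the normalization by the
    combined unsaturated signal.  At ``pve = 1`` this is exactly the 4-pool
    tissue spectrum, at ``pve = 0`` exactly the CSF spectrum.
    """
    p = float(pve)
    csf_abs, tissue_abs, s0_total = mixture_components(model, p, protocol, b0_shift)
    total = ((1.0 - p) * csf_abs + p * tissue_abs) / s0_total
    return ZSpectrum(np.asarray(protocol.offsets), total, s0_total)


def estimate_csf_tissue_ratio(
    s0_volume: np.ndarray,
    tissue_pve_map: np.ndarray,
    csf_pve_map: np.ndarray,
    mask: np.ndarray,
    n_bootstrap: int = 500,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Estimate the CSF/tissue concentration ratio from unsaturated images.

    Fits the per-voxel unsaturated signal as a two-regressor linear model
    ``S0_v ~ a * tissue_pve_v + c * csf_pve_v`` over the masked voxels and
    returns ``(c / a, bootstrap sd)``, the bootstrap resampling voxels.  The
    ratio is a proton-density ratio modulated by T1 saturation of the
    readout, so it is below 1 even though CSF is nearly pure water.

    Raises
    ------
    RatioEstimationError
        If fewer than 10 masked voxels are available or the design has no
        CSF-containing voxels (the ratio is then unidentifiable).
    """
    s0_volume = np.asarray(s0_volume, dtype=float)
    if s0_volume.shape != np.shape(tissue_pve_map) or s0_volume.shape != np.shape(csf_pve_map):
        raise ValueError("s0 volume and PVE maps must share a grid")
    mask = np.asarray(mask, dtype=bool)
    y = s0_volume[mask]
    x = np.column_stack([np.asarray(tissue_pve_map)[mask], np.asarray(csf_pve_map)[mask]])
    if y.size < 10:
        raise RatioEstimationError(f"only {y.size} masked voxels; need at least 10")
    if np.linalg.matrix_rank(x) < 2 or np.allclose(x[:, 1], 0.0):
        raise RatioEstimationError(
            "no CSF-containing voxels in the mask: ratio is unidentifiable"
        )

    def _ratio(xx: np.ndarray, yy: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(xx, yy, rcond=None)
        a, c = coef
        if a == 0:
            raise RatioEstimationError("tissue coefficient estimated as zero")
        return c / a

    ratio = _ratio(x, y)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    boot = []
    n = y.size
    for _ in range(n_bootstrap):
        idx = gen.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.linalg.matrix_rank(xb) < 2:
            continue
        boot.append(_ratio(xb, yb))
    sd = float(np.std(boot, ddof=1)) if len(boot) > 1 else float("nan")
    return float(ratio), sd
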