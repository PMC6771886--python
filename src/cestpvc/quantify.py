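"""APTR* quantification and PVE-threshold analysis masks.

APTR* is a model-based amide proton transfer metric: the difference between
the fitted spectrum of the water-only system (water + MT + NOE, amide pool
removed, ``Sw``) and the full 4-pool spectrum (``Sw+a``), evaluated at the
amide resonance (+3.5 ppm) and normalized by the unsaturated water signal:

    APTR* = (Sw - Sw+a) / S0

For a partial-volume-corrected fit only the tissue compartment's spectra
enter, so the metric reflects tissue amide exchange undiluted by CSF.  The
evaluation defaults to the B0-corrected frame: the fitted water shift defines
the voxel's own frequency axis, and +3.5 ppm means the amide resonance in
that frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cestpvc.forward import SaturationProtocol, simulate_zspectrum
from cestpvc.inference import ImageFitResult, VoxelFit, _apply_params
from cestpvc.pvc import CompartmentModel

__all__ = ["AptrMap", "MaskSet", "aptr_star", "aptr_map", "make_pve_masks", "AptrUndefinedError"]

AMIDE_OFFSET_PPM = 3.5


class AptrUndefinedError(ValueError):
    """APTR* requested for a fit without a tissue compartment."""


@dataclass
class AptrMap:
    """Voxelwise APTR* values, defined only where ``eligible_mask`` is true."""

    values: np.ndarray
    model_tag: str
    eligible_mask: np.ndarray


@dataclass
class MaskSet:
    """Partition of interpretable voxels by tissue PVE band.

    ``whole_slice`` covers PVE in [0.50, 1.00]; ``low_pve`` its bottom half
    [0.50, 0.75) and ``high_pve`` its top half [0.75, 1.00].  The two bands
    are disjoint and their union is the whole-slice mask.
    """

    whole_slice: np.ndarray
    low_pve: np.ndarray
    high_pve: np.ndarray


def aptr_star(
    fit: VoxelFit,
    protocol: SaturationProtocol,
    compartments: CompartmentModel | None = None,
    corrected_frame: bool = True,
) -> float:
    """APTR* of one fitted voxel.

    Re-simulates the fitted tissue system twice — without and with the amide
    pool — at +3.5 ppm and returns the normalized difference.  With
    ``corrected_frame=True`` (default) the spectra are evaluated at the amide
    resonance of the B0-corrected frame; otherwise at the nominal acquisition
    offset of +3.5 ppm with the fitted shift applied.

    Non-converged fits still yield a value; flag handling is the caller's
    responsibility (``fit.converged``).
    """
    if fit.model_tag == "csf_only":
        raise AptrUndefinedError("CSF-only voxels carry no amide (APT) information")
    compartments = compartments or CompartmentModel()
    pools = _apply_params(compartments.tissue_pools, fit.estimates)
    # an amide pool of zero concentration is no pool at all; dropping it makes
    # the with/without spectra the same computation and APTR* exactly zero
    pools = [p for p in pools if p.name == "water" or p.m0 > 0]
    b0 = 0.0 if corrected_frame else fit.b0_shift
    probe = protocol.with_offsets([AMIDE_OFFSET_PPM])
    # normalized by the fitted water m0, i.e. the tissue-compartment S0
    s_with = simulate_zspectrum(pools, probe, b0).signal[0]
    s_without = simulate_zspectrum(
        [p for p in pools if p.name != "amide"], probe, b0
    ).signal[0]
    return float(s_without - s_with)


def aptr_map(
    image_fit: ImageFitResult,
    protocol: SaturationProtocol,
    compartments: CompartmentModel | None = None,
    corrected_frame: bool = True,
) -> AptrMap:
    """APTR* over all APT-eligible voxels of an image fit."""
    eligible = image_fit.maps["eligible"] > 0
    values = np.full(eligible.shape, np.nan)
    for idx, fit in image_fit.fits.items():
        if fit.model_tag == "csf_only":
            continue
        values[idx] = aptr_star(fit, protocol, compartments, corrected_frame)
    return AptrMap(values=values, model_tag=image_fit.requested_model, eligible_mask=eligible)


def make_pve_masks(tissue_pve_map: np.ndarray) -> MaskSet:
    """Threshold a tissue PVE map into whole-slice / low-PVE / high-PVE masks.

    Voxels below 0.50 belong to no mask; 0.75 sits on the boundary of both
    printed bands and is assigned to the high-PVE mask so that the two bands
    partition the whole-slice mask.
    """
    pve = np.asarray(tissue_pve_map, dtype=float)
    if np.nanmin(pve) < 0 or np.nanmax(pve) > 1:
        raise ValueError("tissue PVE values must lie in [0, 1]")
    whole = (pve >= 0.50) & (pve <= 1.00)
    low = (pve >= 0.50) & (pve < 0.75)
    high = (pve >= 0.75) & (pve <= 1.00)
    return MaskSet(whole_slice=whole, low_pve=low, high_pve=high)
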