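"""Digital stroke phantom: synthetic CEST data with known ground truth.

The phantom emulates the structure of a single-slice clinical APT acquisition
at 3 T: a tissue slab bordered by a CSF band with mixed boundary voxels
(tissue PVE rising from 0 to 1), an ischemic-core lesion with reduced amide
concentration, a mirrored contralateral ROI in clean tissue, a smooth
per-voxel B0 offset field, and Gaussian noise in the signal domain.  Every
voxel's spectrum is built with the same tissue/CSF mixture forward model the
fitting stage uses, so fits can be validated against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from cestpvc.forward import SaturationProtocol
from cestpvc.params import default_protocol
from cestpvc.pvc import CompartmentModel, pvc_spectrum

__all__ = ["PhantomSpec", "PhantomDataset", "generate_phantom", "add_noise", "pve_ramp_spec"]


def _default_column_pve() -> tuple[float, ...]:
    # CSF band -> mixed boundary -> pure tissue, per x column of a 16-wide grid
    return (0.0, 0.0, 0.2, 0.4, 0.6, 0.8) + (1.0,) * 10


@dataclass
class PhantomSpec:
    """Geometry, true parameters and noise of a synthetic CEST dataset.

    The tissue PVE varies by x column (``column_pve``); the lesion and its
    mirrored contralateral ROI are axis-aligned boxes
    ``(x0, x1, y0, y1)`` (half-open) placed in pure tissue, the contralateral
    box mirroring the lesion across the y midline.  ``lesion_amide_factor``
    multiplies the amide concentration inside the lesion (0.7 = the 30%
    reduction typical of ischemic core).  ``b0_coeffs`` are polynomial
    coefficients ``(c0, cx, cy, cxy, cx2)`` on unit-scaled coordinates, ppm.
    ``noise_sd`` is the Gaussian noise sd as a fraction of the tissue water
    unsaturated signal.
    """

    shape: tuple[int, int, int] = (16, 16, 1)
    column_pve: tuple[float, ...] = field(default_factory=_default_column_pve)
    lesion_box: tuple[int, int, int, int] = (8, 12, 3, 7)
    lesion_amide_factor: float = 0.7
    b0_coeffs: tuple[float, float, float, float, float] = (0.0, 0.02, -0.015, 0.01, 0.02)
    noise_sd: float = 0.01
    protocol: SaturationProtocol = field(default_factory=default_protocol)
    compartments: CompartmentModel = field(default_factory=CompartmentModel)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.lesion_amide_factor <= 1.0:
            raise ValueError("lesion_amide_factor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.column_pve) != self.shape[0]:
            raise ValueError("column_pve must provide one tissue PVE per x column")

    @property
    def contralateral_box(self) -> tuple[int, int, int, int]:
        x0, x1, y0, y1 = self.lesion_box
        ny = self.shape[1]
        return (x0, x1, ny - y1, ny - y0)

    def b0_field(self) -> np.ndarray:
        nx, ny, nz = self.shape
        u = (np.arange(nx) / max(nx - 1, 1) - 0.5) * 2.0
        v = (np.arange(ny) / max(ny - 1, 1) - 0.5) * 2.0
        uu, vv = np.meshgrid(u, v, indexing="ij")
        c0, cx, cy, cxy, cx2 = self.b0_coeffs
        plane = c0 + cx * uu + cy * vv + cxy * uu * vv + cx2 * uu**2
        return np.repeat(plane[:, :, None], nz, axis=2)


@dataclass
class PhantomDataset:
    """Synthetic 4D CEST data with its ground truth.

    ``truth`` is a per-voxel table (i, j, k, region, tissue_pve, csf_pve,
    b0_shift, amide_m0); ``tissue_pve_map + csf_pve_map == 1`` everywhere.
    """

    data_4d: np.ndarray
    s0_volume: np.ndarray
    tissue_pve_map: np.ndarray
    csf_pve_map: np.ndarray
    roi_masks: dict[str, np.ndarray]
    truth: pd.DataFrame
    protocol: SaturationProtocol
    compartments: CompartmentModel
    spec: PhantomSpec


def add_noise(
    data: np.ndarray, sd: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Add independent Gaussian noise in the signal domain (seeded)."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    data = np.asarray(data, dtype=float)
    if sd == 0:
        return data.copy()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return data + gen.normal(0.0, sd, size=data.shape)


def _box_mask(shape: tuple[int, int, int], box: tuple[int, int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    x0, x1, y0, y1 = box
    m[x0:x1, y0:y1, :] = True
    return m


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the synthetic dataset described by ``spec``.

    Each voxel's clean spectrum is the tissue-fraction-weighted CSF/tissue
    mixture at the voxel's true PVE, B0 shift and regional pool parameters
    (lesion voxels carry the reduced amide concentration), on the absolute
    signal scale; seeded Gaussian noise is then added to the 4D data and the
    unsaturated reference volume.  Identical specs (including seed) produce
    bit-identical datasets.
    """
    nx, ny, nz = spec.shape
    protocol = spec.protocol
    n_off = len(protocol.offsets)

    tissue_pve = np.zeros(spec.shape)
    for i, p in enumerate(spec.column_pve):
        if not 0.0 <= p <= 1.0:
            raise ValueError("column_pve values must lie in [0, 1]")
        tissue_pve[i, :, :] = p
    csf_pve = 1.0 - tissue_pve

    core = _box_mask(spec.shape, spec.lesion_box)
    contra = _box_mask(spec.shape, spec.contralateral_box)
    if np.any(tissue_pve[core] < 0.5):
        raise ValueError("lesion box extends outside the tissue region (PVE < 0.5)")
    if np.any(core & contra):
        raise ValueError("lesion and contralateral boxes overlap")

    b0 = spec.b0_field()
    base = spec.compartments
    amide_idx = next(i for i, p in enumerate(base.tissue_pools) if p.name == "amide")
    lesion_pools = list(base.tissue_pools)
    lesion_pools[amide_idx] = lesion_pools[amide_idx].with_m0(
        lesion_pools[amide_idx].m0 * spec.lesion_amide_factor
    )
    lesion_model = replace(base, tissue_pools=lesion_pools)

    clean = np.zeros((nx, ny, nz, n_off))
    s0 = np.zeros(spec.shape)
    rows = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                in_core = core[i, j, k]
                model = lesion_model if in_core else base
                z = pvc_spectrum(model, tissue_pve[i, j, k], protocol, b0[i, j, k])
                clean[i, j, k, :] = z.absolute
                s0[i, j, k] = z.s0
                region = (
                    "core"
                    if in_core
                    else "contralateral"
                    if contra[i, j, k]
                    else "csf"
                    if tissue_pve[i, j, k] < 0.5
                    else "tissue"
                )
                rows.append(
                    {
                        "i": i,
                        "j": j,
                        "k": k,
                        "region": region,
                        "tissue_pve": tissue_pve[i, j, k],
                        "csf_pve": csf_pve[i, j, k],
                        "b0_shift": b0[i, j, k],
                        "amide_m0": model.tissue_pools[amide_idx].m0,
                    }
                )

    sd_abs = spec.noise_sd * base.tissue_water_m0
    rng = np.random.default_rng(spec.seed)
    data_4d = add_noise(clean, sd_abs, rng)
    s0_volume = add_noise(s0, sd_abs, rng)

    return PhantomDataset(
        data_4d=data_4d,
        s0_volume=s0_volume,
        tissue_pve_map=tissue_pve,
        csf_pve_map=csf_pve,
        roi_masks={"core": core, "contralateral": contra},
        truth=pd.DataFrame(rows),
        protocol=protocol,
        compartments=base,
        spec=spec,
    )


def pve_ramp_spec(
    n_steps: int = 6,
    n_rows: int = 2,
    pve_min: float = 0.5,
    pve_max: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocol: SaturationProtocol | None = None,
    compartments: CompartmentModel | None = None,
) -> PhantomSpec:
    """Spec for the PVE-ramp phantom: constant tissue, tissue fraction rising
    column by column from ``pve_min`` to ``pve_max``, no lesion contrast.

    This is the geometry that isolates the CSF dilution artifact: apparent
    (uncorrected) APT contrast varies along the ramp although the underlying
    tissue never changes.
    """
    cols = tuple(float(p) for p in np.linspace(pve_min, pve_max, n_steps))
    kwargs: dict = {}
    if protocol is not None:
        kwargs["protocol"] = protocol
    if compartments is not None:
        kwargs["compartments"] = compartments
    return PhantomSpec(
        shape=(n_steps, n_rows, 1),
        column_pve=cols,
        lesion_box=(0, 0, 0, 0),  # empty: no lesion on the ramp
        lesion_amide_factor=1.0,
        b0_coeffs=(0.0, 0.0, 0.0, 0.0, 0.0),
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
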