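"""Readers/writers for the NIfTI volumes, offset lists and configs.

All volumes are NIfTI-1 float32; saturation offsets live in a plain-text file
with one ppm value per line whose order must match the 4th dimension of the
CEST data; the protocol/config files are YAML-compatible key/value text.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from cestpvc.forward import SaturationProtocol

__all__ = [
    "DatasetBundle",
    "load_offsets",
    "load_protocol",
    "load_volume",
    "load_bundle",
    "write_maps",
    "GridMismatchError",
]

log = logging.getLogger("cestpvc")

AFFINE_TOL = 1e-3


class GridMismatchError(ValueError):
    """Volumes expected on one grid disagree in shape or affine."""


@dataclass
class DatasetBundle:
    """A loaded, grid-checked CEST dataset."""

    data_4d: np.ndarray
    affine: np.ndarray
    offsets: np.ndarray
    protocol: SaturationProtocol
    s0_volume: np.ndarray | None = None
    tissue_pve: np.ndarray | None = None
    csf_pve: np.ndarray | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    valid_mask: np.ndarray | None = None


def load_offsets(path: str | Path) -> np.ndarray:
    """One ppm value per line; order must match the 4D volume order."""
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            values.append(float(line))
    if not values:
        raise ValueError(f"no offsets found in {path}")
    return np.asarray(values)


def load_protocol(path: str | Path, offsets: np.ndarray) -> SaturationProtocol:
    """Key/value protocol config: b1_uT, t_sat_s, larmor_MHz, reference_ppm."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"protocol file {path} must contain key: value pairs")
    return SaturationProtocol(
        b1=float(cfg.get("b1_uT", 0.55)),
        t_sat=float(cfg.get("t_sat_s", 2.0)),
        offsets=tuple(offsets),
        larmor=float(cfg.get("larmor_MHz", 127.74)),
        reference_offset=float(cfg.get("reference_ppm", 300.0)),
    )


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def _check_grid(name: str, shape, affine, ref_shape, ref_affine) -> None:
    if tuple(shape[:3]) != tuple(ref_shape[:3]):
        raise GridMismatchError(
            f"{name}: shape {tuple(shape[:3])} does not match data grid {tuple(ref_shape[:3])}"
        )
    if not np.allclose(affine, ref_affine, atol=AFFINE_TOL):
        raise GridMismatchError(
            f"{name}: affine differs from the data affine by more than {AFFINE_TOL}\n"
            f"{affine}\nvs\n{ref_affine}"
        )


def load_bundle(
    data_path: str | Path,
    offsets_path: str | Path,
    protocol_path: str | Path | None = None,
    s0_path: str | Path | None = None,
    tissue_pve_path: str | Path | None = None,
    csf_pve_path: str | Path | None = None,
    mask_paths: Mapping[str, str | Path] | None = None,
) -> DatasetBundle:
    """Load and validate a CEST dataset.

    Checks that the offset count matches the 4th data dimension and that all
    auxiliary volumes share the data grid and affine; voxels with non-finite
    data are warned about and excluded via ``valid_mask``.
    """
    data, affine = load_volume(data_path)
    if data.ndim != 4:
        raise ValueError(f"{data_path}: expected a 4D volume, got shape {data.shape}")
    offsets = load_offsets(offsets_path)
    if data.shape[3] != offsets.size:
        raise ValueError(
            f"offset count mismatch: {offsets.size} offsets in {offsets_path} "
            f"but {data.shape[3]} volumes in {data_path}"
        )
    if protocol_path is not None:
        protocol = load_protocol(protocol_path, offsets)
    else:
        protocol = SaturationProtocol(b1=0.55, t_sat=2.0, offsets=tuple(offsets))

    bundle = DatasetBundle(data_4d=data, affine=affine, offsets=offsets, protocol=protocol)

    for name, path, attr in (
        ("s0 volume", s0_path, "s0_volume"),
        ("tissue PVE map", tissue_pve_path, "tissue_pve"),
        ("CSF PVE map", csf_pve_path, "csf_pve"),
    ):
        if path is not None:
            vol, aff = load_volume(path)
            _check_grid(name, vol.shape, aff, data.shape, affine)
            setattr(bundle, attr, vol)
    for name, path in (mask_paths or {}).items():
        vol, aff = load_volume(path)
        _check_grid(f"mask {name!r}", vol.shape, aff, data.shape, affine)
        bundle.masks[name] = vol > 0.5

    valid = np.all(np.isfinite(data), axis=3)
    n_bad = int(np.sum(~valid))
    if n_bad:
        warnings.warn(f"{n_bad} voxels contain non-finite data and will be masked out")
        log.warning("masking %d non-finite voxels", n_bad)
    bundle.valid_mask = valid
    return bundle


def config_hash(config: Mapping | str) -> str:
    text = config if isinstance(config, str) else json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_maps(
    maps: Mapping[str, np.ndarray],
    affine: np.ndarray,
    out_dir: str | Path,
    provenance: Mapping | None = None,
) -> list[Path]:
    """Write each map as float32 NIfTI plus a provenance manifest.

    The manifest (``manifest.json``) lists every written file together with
    the provenance dictionary (model, config hash, seed, ...) so a rerun with
    the same configuration reproduces the same hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, arr in maps.items():
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.asarray(affine)), str(path))
        written.append(path)
    manifest = {
        "files": [p.name for p in written],
        "provenance": dict(provenance or {}),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written.append(manifest_path)
    log.info("wrote %d files to %s", len(written), out_dir)
    return written
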