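"""Robustness statistics for comparing APT quantification pipelines.

Covers the four evaluation axes used to compare corrected and uncorrected
APTR* measures: repeatability (coefficient of variation of ROI means between
time points or between subjects), spatial variability (CoV of voxel values
within an ROI), ischemic-core contrast-to-noise ratio, and the variability of
APTR* across CSF-fraction bins.  Sample (n-1) standard deviations are used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiSample",
    "coefficient_of_variation",
    "repeatability",
    "spatial_variability",
    "contrast_to_noise",
    "csf_fraction_profile",
    "StatisticError",
]


class StatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero mean)."""


@dataclass
class RoiSample:
    """APTR* values of the member voxels of one ROI.

    ``label`` is one of ``ischemic_core``, ``contralateral``, ``whole``,
    ``low_pve`` or ``high_pve``; ``subject_id`` / ``timepoint_id`` identify
    the acquisition the sample came from.
    """

    label: str
    values: np.ndarray
    subject_id: str = ""
    timepoint_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError(f"ROI {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"ROI {self.label!r} contains non-finite values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation, percent: 100 * sample sd / mean."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise StatisticError("CoV needs at least 2 values")
    mean = float(np.mean(arr))
    if mean == 0:
        raise StatisticError("CoV undefined for zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / mean


def repeatability(
    roi_means: pd.DataFrame,
    mode: str = "timepoints",
) -> tuple[float, float | None]:
    """Between-timepoint or between-subject repeatability of ROI means.

    Parameters
    ----------
    roi_means:
        Tidy frame with columns ``subject``, ``timepoint`` and ``value``
        (one ROI mean per subject-timepoint).
    mode:
        ``"timepoints"`` — CoV of each subject's per-timepoint means,
        averaged over subjects; returns ``(mean CoV %, sd of CoVs)``.
        ``"subjects"`` — CoV across per-subject mean values (each subject's
        timepoints averaged first); returns ``(CoV %, None)``.
    """
    if mode not in ("timepoints", "subjects"):
        raise ValueError(f"mode must be 'timepoints' or 'subjects', got {mode!r}")
    required = {"subject", "timepoint", "value"}
    if not required.issubset(roi_means.columns):
        raise ValueError(f"roi_means needs columns {sorted(required)}")

    if mode == "timepoints":
        covs = []
        for _, grp in roi_means.groupby("subject"):
            if grp["timepoint"].nunique() < 2:
                raise StatisticError(
                    "timepoint repeatability needs >= 2 timepoints per subject"
                )
            covs.append(coefficient_of_variation(grp.groupby("timepoint")["value"].mean()))
        covs = np.asarray(covs)
        sd = float(np.std(covs, ddof=1)) if covs.size > 1 else None
        return float(np.mean(covs)), sd

    per_subject = roi_means.groupby("subject")["value"].mean()
    if per_subject.size < 2:
        raise StatisticError("subject repeatability needs >= 2 subjects")
    return coefficient_of_variation(per_subject.to_numpy()), None


def spatial_variability(roi: RoiSample) -> float:
    """CoV (percent) of voxel values within one ROI — spatial heterogeneity."""
    return coefficient_of_variation(roi.values)


def contrast_to_noise(core: RoiSample, contra: RoiSample) -> float:
    """Ischemic-core CNR: (mean core - mean contralateral) / sd contralateral."""
    sd_co = contra.sd
    if sd_co == 0:
        raise StatisticError("CNR undefined: contralateral ROI has zero sd")
    return (core.mean - contra.mean) / sd_co


def csf_fraction_profile(
    aptr_values: np.ndarray,
    csf_pve_map: np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = 10,
    max_csf: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean APTR* in equal CSF-fraction bins and the CoV of the bin means.

    CSF PVE is binned into ``n_bins`` equal ranges over [0, ``max_csf``]
    (default: ten 5%-wide bins up to 50% CSF, the interpretability limit);
    the upper edge of the last bin is inclusive.  Returns
    ``(bin_edges, bin_means, cov_percent)`` where empty bins hold NaN and the
    CoV is taken over the non-empty bin means.
    """
    aptr = np.asarray(aptr_values, dtype=float).ravel()
    csf = np.asarray(csf_pve_map, dtype=float).ravel()
    if aptr.size != csf.size:
        raise ValueError("APTR* map and CSF PVE map must share a grid")
    keep = np.isfinite(aptr)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    edges = np.linspace(0.0, max_csf, n_bins + 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        hi_ok = csf <= edges[b + 1] if b == n_bins - 1 else csf < edges[b + 1]
        sel = keep & (csf >= edges[b]) & hi_ok
        if np.any(sel):
            means[b] = float(np.mean(aptr[sel]))
    filled = means[np.isfinite(means)]
    if filled.size == 0:
        raise StatisticError("all CSF-fraction bins are empty")
    cov = coefficient_of_variation(filled) if filled.size > 1 else 0.0
    return edges, means, cov


def tidy_statistics(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble statistic rows into the tidy output table.

    Each row supplies ``subject``, ``timepoint``, ``roi``, ``mask_band``,
    ``model``, ``statistic`` and ``value``; missing keys are filled with "".
    """
    cols = ["subject", "timepoint", "roi", "mask_band", "model", "statistic", "value"]
    frame = pd.DataFrame(list(rows))
    for c in cols:
        if c not in frame.columns:
            frame[c] = ""
    return frame[cols]
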