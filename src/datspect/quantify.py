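"""DVR conversion and putamen SBR extraction.

A stereotactically normalized scan is converted to a distribution volume
ratio (DVR) image by voxelwise scaling to the 75th percentile of the
intensity in a reference region (whole brain without striata, thalamus/
brainstem, cerebellum and ventricles). The putamen specific binding ratio
is then SBR = DVR - 1, extracted either by hottest-voxels analysis (mean of
the n highest DVR values inside a generously oversized unilateral putamen
mask, n fixed by a total volume of 10 ml) or by the mean over a tight
anatomical putamen mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .registration import NormalizationResult, RegistrationOptions, normalize
from .voxel_core import (
    GridMismatchError,
    ROIMaskSet,
    VolumetricImage,
    masked_percentile,
)

REFERENCE_QUANTILE = 0.75
HV_VOLUME_ML = 10.0


@dataclass(frozen=True)
class SBRRecord:
    """Per-scan quantification result for one template mode and ROI method."""

    scan_id: str
    template_mode: Literal["single", "multiple"]
    roi_method: Literal["HV", "AAL"]
    sbr_left: float
    sbr_right: float
    det: float
    label: Literal["normal", "reduced", "unset"] = "unset"

    @property
    def sbr_min(self) -> float:
        return min(self.sbr_left, self.sbr_right)

    @property
    def sbr_mean(self) -> float:
        return (self.sbr_left + self.sbr_right) / 2.0

    def as_row(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "template_mode": self.template_mode,
            "roi_method": self.roi_method,
            "sbr_left": self.sbr_left,
            "sbr_right": self.sbr_right,
            "sbr_min": self.sbr_min,
            "sbr_mean": self.sbr_mean,
            "det": self.det,
            "label": self.label,
        }


def to_dvr(img: VolumetricImage, reference_mask: VolumetricImage) -> VolumetricImage:
    """Scale a template-space image to DVR units.

    Divides by the 75th percentile of the in-mask intensity, so the output
    is invariant under any positive global rescaling of the input.
    """
    p = masked_percentile(img, reference_mask, REFERENCE_QUANTILE)
    if p <= 0:
        raise ValueError("degenerate scan: nonpositive reference percentile")
    return img.with_data(img.data / p)


def hottest_voxels_sbr(
    dvr: VolumetricImage,
    unilateral_mask: VolumetricImage,
    volume_ml: float = HV_VOLUME_ML,
) -> float:
    """Hottest-voxels SBR: mean of the n largest in-mask DVR values, minus 1.

    n = round(volume_ml * 1000 / voxel volume); at 2 mm isotropic voxels and
    10 ml this is exactly 1250 voxels. Ties at the n-th value are broken by
    descending value with deterministic index order (np.sort).
    """
    if not dvr.same_grid(unilateral_mask):
        raise GridMismatchError("mask is on a different grid than the DVR image")
    n = int(round(volume_ml * 1000.0 / dvr.voxel_volume_mm3))
    vals = dvr.data[unilateral_mask.data > 0]
    if vals.size < n:
        raise ValueError(f"mask holds {vals.size} voxels, fewer than n={n}")
    hottest = np.sort(vals)[-n:]
    return float(hottest.mean() - 1.0)


def roi_mean_sbr(dvr: VolumetricImage, anat_mask: VolumetricImage) -> float:
    """Anatomical-ROI SBR: in-mask mean DVR minus 1."""
    if not dvr.same_grid(anat_mask):
        raise GridMismatchError("mask is on a different grid than the DVR image")
    sel = anat_mask.data > 0
    if not sel.any():
        raise ValueError("anatomical mask is empty")
    return float(dvr.data[sel].mean() - 1.0)


def quantify_normalized(
    dvr: VolumetricImage,
    masks: ROIMaskSet,
    scan_id: str,
    template_mode: Literal["single", "multiple"],
    det: float,
    hv_volume_ml: float = HV_VOLUME_ML,
) -> list[SBRRecord]:
    """Both ROI methods on an already-normalized DVR image."""
    records = []
    for method in ("HV", "AAL"):
        if method == "HV":
            left = hottest_voxels_sbr(dvr, masks.hv_putamen_left, hv_volume_ml)
            right = hottest_voxels_sbr(dvr, masks.hv_putamen_right, hv_volume_ml)
        else:
            left = roi_mean_sbr(dvr, masks.anat_putamen_left)
            right = roi_mean_sbr(dvr, masks.anat_putamen_right)
        records.append(
            SBRRecord(scan_id, template_mode, method, left, right, det)
        )
    return records


def quantify_scan(
    scan: VolumetricImage,
    templates: VolumetricImage | Sequence[VolumetricImage],
    masks: ROIMaskSet,
    template_mode: Literal["single", "multiple"] = "single",
    scan_id: str = "scan",
    reg_opts: RegistrationOptions | None = None,
) -> tuple[list[SBRRecord], NormalizationResult]:
    """Full per-scan pipeline: normalize -> DVR -> HV and anatomical SBR.

    Returns one record per ROI method (HV, AAL) for the requested template
    mode, plus the normalization result (transform, coefficients, DET).
    """
    result = normalize(scan, templates, masks.head_mask, opts=reg_opts)
    dvr = to_dvr(result.normalized, masks.reference_mask)
    records = quantify_normalized(
        dvr, masks, scan_id, template_mode, result.transform.det
    )
    return records, result
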