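"""Volumetric image data model and shared grid operations.

All stages of the pipeline work on :class:`VolumetricImage` objects: a 3-D
scalar grid together with a 4x4 homogeneous voxel-to-world affine (mm).
Coordinate convention: voxel indices are 0-based; the template grid mimics
MNI 2 mm isotropic with the left-right axis along the first grid axis and
the mirror plane at the grid's central sagittal plane.

Intensity semantics are tracked loosely through ``space_tag`` / the DVR flag
carried by callers; this module is agnostic to units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class Space(str, Enum):
    NATIVE = "native"
    TEMPLATE = "template"


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid are not."""


class InvalidTransformError(ValueError):
    """Affine transform is singular or otherwise unusable."""


@dataclass(frozen=True)
class VolumetricImage:
    """3-D scalar volume with a voxel-to-world (mm) affine.

    Parameters
    ----------
    data:
        3-D float array of intensities (counts-like, arbitrary units, or DVR).
    v2w:
        4x4 homogeneous affine mapping 0-based voxel indices to world mm.
    space_tag:
        Whether the grid is the subject's native space or template space.
    """

    data: np.ndarray
    v2w: np.ndarray
    space_tag: Space = Space.NATIVE

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        v2w = np.asarray(self.v2w, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"expected a 3-D grid, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("image intensities must be finite")
        if v2w.shape != (4, 4):
            raise ValueError("v2w must be a 4x4 homogeneous matrix")
        if abs(np.linalg.det(v2w[:3, :3])) < 1e-12:
            raise InvalidTransformError("v2w has a singular linear part")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "v2w", v2w)
        if not isinstance(self.space_tag, Space):
            object.__setattr__(self, "space_tag", Space(self.space_tag))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.v2w[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.v2w[:3, :3])))

    def same_grid(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.v2w, other.v2w, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "VolumetricImage":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def world_coords(self, stride: int = 1) -> np.ndarray:
        """World-mm coordinates of (strided) voxel centers, shape (N, 3)."""
        grids = np.meshgrid(
            *(np.arange(0, n, stride) for n in self.shape), indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
        return idx @ self.v2w[:3, :3].T + self.v2w[:3, 3]

    # --- NIfTI-1 I/O ------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.v2w)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(
        cls, path: str | Path, space_tag: Space = Space.NATIVE
    ) -> "VolumetricImage":
        img = nib.load(str(path))
        return cls(
            np.asarray(img.get_fdata(), dtype=np.float64),
            np.asarray(img.affine, dtype=np.float64),
            space_tag,
        )


def save_mask(mask: VolumetricImage, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI, preserving the affine."""
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.v2w), str(path))


@dataclass(frozen=True)
class AxisSpec:
    """Left-right axis of the grid and the sagittal mirror plane.

    ``plane`` is the voxel coordinate of the mirror plane along ``axis``;
    the default convention puts it at the grid center, (n - 1) / 2, so that
    the flip is the exact index reversal ``i -> n - 1 - i``.
    """

    axis: int = 0
    plane: float | None = None

    def mirror_index(self, i: np.ndarray | int, n: int) -> np.ndarray | int:
        plane = (n - 1) / 2.0 if self.plane is None else self.plane
        return np.round(2.0 * plane - np.asarray(i)).astype(int)


@dataclass(frozen=True)
class ROIMaskSet:
    """Binary masks on the template grid used throughout the pipeline.

    ``head_mask`` weights the registration (whole head minus cerebellum);
    ``reference_mask`` is the nondisplaceable-binding region (brain without
    striata, thalamus/brainstem, cerebellum and ventricles); the ``hv_*``
    masks are generously oversized unilateral putamen masks for hottest-voxels
    analysis; the ``anat_*`` masks are tight anatomical putamen masks.
    """

    head_mask: VolumetricImage
    reference_mask: VolumetricImage
    hv_putamen_left: VolumetricImage
    hv_putamen_right: VolumetricImage
    anat_putamen_left: VolumetricImage
    anat_putamen_right: VolumetricImage
    midsagittal: AxisSpec = field(default_factory=AxisSpec)

    def __post_init__(self) -> None:
        masks = self.all_masks()
        ref = self.head_mask
        for name, m in masks.items():
            if not m.same_grid(ref):
                raise GridMismatchError(f"mask {name!r} is on a different grid")
            vals = np.unique(m.data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"mask {name!r} is not strictly binary")
        if np.any(self.hv_putamen_left.data * self.hv_putamen_right.data):
            raise ValueError("left and right putamen masks overlap")
        if np.any(self.anat_putamen_left.data * self.anat_putamen_right.data):
            raise ValueError("left and right anatomical putamen masks overlap")
        for side in ("left", "right"):
            hv = getattr(self, f"hv_putamen_{side}")
            if np.any(self.reference_mask.data * hv.data):
                raise ValueError(f"reference mask overlaps hv putamen {side}")
            if mask_volume_ml(hv) < 10.0:
                raise ValueError(f"hv putamen {side} mask smaller than 10 ml")

    def all_masks(self) -> dict[str, VolumetricImage]:
        return {
            "head_mask": self.head_mask,
            "reference_mask": self.reference_mask,
            "hv_putamen_left": self.hv_putamen_left,
            "hv_putamen_right": self.hv_putamen_right,
            "anat_putamen_left": self.anat_putamen_left,
            "anat_putamen_right": self.anat_putamen_right,
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, m in self.all_masks().items():
            save_mask(m, directory / f"{name}.nii.gz")

    @classmethod
    def load(cls, directory: str | Path) -> "ROIMaskSet":
        directory = Path(directory)
        kwargs = {}
        for name in (
            "head_mask",
            "reference_mask",
            "hv_putamen_left",
            "hv_putamen_right",
            "anat_putamen_left",
            "anat_putamen_right",
        ):
            kwargs[name] = VolumetricImage.load(
                directory / f"{name}.nii.gz", Space.TEMPLATE
            )
        return cls(**kwargs)


def mask_volume_ml(mask: VolumetricImage) -> float:
    return float(mask.data.sum()) * mask.voxel_volume_mm3 / 1000.0


# --- grid operations ------------------------------------------------------


def resample(
    img: VolumetricImage,
    world_xf: np.ndarray,
    target: VolumetricImage,
    order: int = 1,
) -> VolumetricImage:
    """Resample ``img`` onto ``target``'s grid under a world-to-world affine.

    ``world_xf`` maps source-world mm to target-world mm (e.g. native ->
    template). Trilinear interpolation by default; voxels that map outside
    the source field of view are zero (no wraparound). Intensities are not
    Jacobian-modulated ("preserve concentrations" semantics: plain
    interpolation).
    """
    world_xf = np.asarray(world_xf, dtype=np.float64)
    if world_xf.shape != (4, 4) or abs(np.linalg.det(world_xf[:3, :3])) < 1e-12:
        raise InvalidTransformError("world transform must be an invertible 4x4")
    # output voxel j -> source voxel i:  i = v2w_src^-1 . xf^-1 . v2w_tgt . j
    m = np.linalg.inv(img.v2w) @ np.linalg.inv(world_xf) @ target.v2w
    out = ndimage.affine_transform(
        img.data,
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order <= 1,
    )
    return VolumetricImage(out, target.v2w, target.space_tag)


def flip_lr(img: VolumetricImage, axis_spec: AxisSpec | None = None) -> VolumetricImage:
    """Mirror the image at the midsagittal plane (exact index reversal).

    An involution: ``flip_lr(flip_lr(x)) == x`` bitwise. Requires the mirror
    plane to sit at the grid's central plane of the flip axis.
    """
    spec = axis_spec or AxisSpec()
    if not 0 <= spec.axis < 3:
        raise ValueError(f"axis {spec.axis} outside the 3-D grid")
    n = img.shape[spec.axis]
    if spec.plane is not None and not np.isclose(spec.plane, (n - 1) / 2.0):
        raise ValueError(
            "flip_lr only supports the central mirror plane; "
            f"got plane={spec.plane} for axis length {n}"
        )
    return img.with_data(np.flip(img.data, axis=spec.axis))


def gaussian_smooth(
    img: VolumetricImage, fwhm_mm: float | Sequence[float]
) -> VolumetricImage:
    """Separable Gaussian smoothing with per-axis FWHM given in mm.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units via
    the grid's voxel size. Reflective padding so constants are preserved;
    fwhm = 0 returns the input unchanged.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=np.float64), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm == 0):
        return img
    sigma_vox = fwhm * FWHM_TO_SIGMA / img.voxel_size
    return img.with_data(ndimage.gaussian_filter(img.data, sigma_vox, mode="reflect"))


def masked_percentile(img: VolumetricImage, mask: VolumetricImage, q: float) -> float:
    """q-quantile (q in [0, 1]) of in-mask intensities.

    Linear interpolation between closest order statistics (the common
    default quantile rule), pinned for reproducibility.
    """
    if not img.same_grid(mask):
        raise GridMismatchError("mask is on a different grid than the image")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be within [0, 1]")
    sel = mask.data > 0
    if not sel.any():
        raise ValueError("mask is empty")
    return float(np.quantile(img.data[sel], q, method="linear"))


def soft_mean(imgs: Iterable[VolumetricImage]) -> VolumetricImage:
    """Voxelwise arithmetic mean of images sharing one grid."""
    imgs = list(imgs)
    if not imgs:
        raise ValueError("need at least one image")
    first = imgs[0]
    for i, im in enumerate(imgs[1:], start=1):
        if not im.same_grid(first):
            raise GridMismatchError(f"image {i} is on a different grid")
    return first.with_data(np.mean([im.data for im in imgs], axis=0))


def centered_grid(
    shape: Sequence[int], voxel_mm: float | Sequence[float] = 2.0,
    space_tag: Space = Space.TEMPLATE,
) -> VolumetricImage:
    """Empty volume whose world origin sits at the grid center.

    The voxel-to-world affine is diagonal with the given spacing and a
    translation placing world (0,0,0) at voxel ((n-1)/2, ...), so the grid is
    symmetric under the left-right index reversal.
    """
    shape = tuple(int(n) for n in shape)
    vox = np.broadcast_to(np.asarray(voxel_mm, dtype=np.float64), (3,))
    v2w = np.eye(4)
    v2w[:3, :3] = np.diag(vox)
    v2w[:3, 3] = -vox * (np.asarray(shape) - 1) / 2.0
    return VolumetricImage(np.zeros(shape), v2w, space_tag)
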