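"""Iterative construction of the 8-template DVR set.

Each category template (normal; moderate deficit right/left; strong; each
with and without scalp signal) is built from a handful of scans of that
category by repeated single-template normalization to the current target,
DVR scaling, and soft-mean averaging. The normal template is additionally
symmetrized (average of the image and its left-right flip); moderate-
category scans are flipped before averaging so the deficit is always in the
right hemisphere, and the left-deficit template is the exact mirror of the
right-deficit one. The strong template averages scans as-is, with neither
deficit orientation nor symmetrization. This module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .quantify import hottest_voxels_sbr, to_dvr
from .registration import RegistrationOptions, normalize
from .voxel_core import (
    AxisSpec,
    ROIMaskSet,
    VolumetricImage,
    flip_lr,
    soft_mean,
)

Category = Literal["normal", "moderate_right", "moderate_left", "strong"]


@dataclass(frozen=True)
class TemplateSet:
    """Ordered DVR templates on one grid with category/scalp labels."""

    templates: tuple[VolumetricImage, ...]
    labels: tuple[tuple[str, str], ...]  # (category, with_scalp/without_scalp)

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.labels):
            raise ValueError("one label per template required")
        if len(self.templates) not in (1, 8):
            raise ValueError("template set must hold 1 or 8 templates")
        grid = self.templates[0]
        for t in self.templates[1:]:
            if not t.same_grid(grid):
                raise ValueError("templates must share one grid")

    def __len__(self) -> int:
        return len(self.templates)

    def single(self) -> VolumetricImage:
        """The normal (with attenuation/scatter correction) template."""
        for t, (cat, scalp) in zip(self.templates, self.labels):
            if cat == "normal" and scalp == "without_scalp":
                return t
        return self.templates[0]


def symmetrize(img: VolumetricImage, axis_spec: AxisSpec | None = None) -> VolumetricImage:
    """Average an image with its left-right flip; an exact flip fixed point."""
    flipped = flip_lr(img, axis_spec)
    return img.with_data(0.5 * (img.data + flipped.data))


def make_left_variant(template_right: VolumetricImage) -> VolumetricImage:
    """Mirror a right-deficit template into its left-deficit counterpart."""
    return flip_lr(template_right)


def orient_deficit_right(
    dvr_scans: Sequence[VolumetricImage], masks: ROIMaskSet
) -> list[VolumetricImage]:
    """Flip template-space DVR scans so the deficit is right-hemispheric.

    A scan is flipped when its right-putamen hottest-voxels SBR exceeds the
    left one; exactly equal sides are left unchanged (pinned tie rule).
    After the call right HV-SBR <= left HV-SBR for every scan.
    """
    out = []
    for scan in dvr_scans:
        left = hottest_voxels_sbr(scan, masks.hv_putamen_left)
        right = hottest_voxels_sbr(scan, masks.hv_putamen_right)
        out.append(flip_lr(scan, masks.midsagittal) if right > left else scan)
    return out


def build_template(
    scans: Sequence[VolumetricImage],
    target0: VolumetricImage,
    masks: ROIMaskSet,
    category: Category = "normal",
    iterations: int = 3,
    reg_opts: RegistrationOptions | None = None,
) -> VolumetricImage:
    """Iterative normalization-averaging of one category's scans.

    Per iteration: normalize every scan to the current target (single-
    template mode), scale to DVR, orient the deficit right for the moderate
    category, soft-mean, and symmetrize for the normal category. The first
    target is ``target0`` (the bootstrap template); later targets are the
    previous iteration's output. Default is three passes in total (an
    initial pass plus two repetitions).
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("need at least 2 scans to build a template")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    target = target0
    for _ in range(iterations):
        dvr_scans = []
        for i, scan in enumerate(scans):
            result = normalize(scan, target, masks.head_mask, opts=reg_opts)
            if not result.converged:
                raise RuntimeError(f"normalization did not converge for scan {i}")
            dvr_scans.append(to_dvr(result.normalized, masks.reference_mask))
        if category in ("moderate_right", "moderate_left"):
            dvr_scans = orient_deficit_right(dvr_scans, masks)
        target = soft_mean(dvr_scans)
        if category == "normal":
            target = symmetrize(target, masks.midsagittal)
    if category == "moderate_left":
        target = make_left_variant(target)
    return target


def build_template_set(
    scans_by_label: dict[tuple[str, str], Sequence[VolumetricImage]],
    target0: VolumetricImage,
    masks: ROIMaskSet,
    iterations: int = 3,
    reg_opts: RegistrationOptions | None = None,
) -> TemplateSet:
    """Build the full 8-template set from per-(category, scalp) scan lists.

    ``moderate_left`` entries need no scans of their own: each is derived by
    mirroring the corresponding ``moderate_right`` template.
    """
    order = [
        (cat, scalp)
        for cat in ("normal", "moderate_right", "moderate_left", "strong")
        for scalp in ("without_scalp", "with_scalp")
    ]
    built: dict[tuple[str, str], VolumetricImage] = {}
    for cat, scalp in order:
        if cat == "moderate_left":
            built[(cat, scalp)] = make_left_variant(built[("moderate_right", scalp)])
            continue
        key = (cat, scalp)
        if key not in scans_by_label:
            raise ValueError(f"no scans supplied for template {key}")
        built[key] = build_template(
            scans_by_label[key], target0, masks, cat, iterations, reg_opts
        )
    return TemplateSet(
        templates=tuple(built[k] for k in order), labels=tuple(order)
    )
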