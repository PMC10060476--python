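"""Synthetic DAT-SPECT cohort generator with ground truth.

Emulates reconstructed striatal-tracer SPECT volumes directly (no projection
physics): bright bilateral striatal compartments (caudate + putamen) painted
as ellipsoids on a dimmer brain background of DVR 1, an optional scalp shell
(mimicking omission of attenuation/scatter correction), putamen-predominant
signal reduction with left/right asymmetry for 'reduced' subjects,
point-spread blurring, additive truncated Gaussian noise, and a random
affine misalignment from template space with an arbitrary global intensity
scale.

All anatomy dimensions are free modeling choices recorded in
:class:`PhantomSpec`; left/right structures are exact mirror images across
the central sagittal plane so that masks satisfy the flip symmetry exactly.
The cohort mixture (fraction of reduced subjects, per-category mean/SD of
the minimum putamen SBR) defaults to the values observed for the
hottest-voxels minimum SBR under multi-template normalization in a large
clinical sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .registration import AffineTransform12
from .voxel_core import (
    AxisSpec,
    ROIMaskSet,
    Space,
    VolumetricImage,
    centered_grid,
    flip_lr,
    gaussian_smooth,
    resample,
)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (mm, world) and semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def mirrored(self) -> "Ellipsoid":
        c = self.center
        return Ellipsoid((-c[0], c[1], c[2]), self.semi_axes)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        d = (coords - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(d * d, axis=-1) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model of the digital head phantom.

    The grid mimics template space at 2 mm isotropic voxels with the
    left-right axis first. Right-hemisphere structures are given explicitly;
    left ones are their exact mirrors. Misalignment ranges bound the random
    true affine (uniform draws); ``scale_range`` bounds the arbitrary global
    intensity multiplier of a native scan.
    """

    grid_shape: tuple[int, int, int] = (64, 72, 64)
    native_shape: tuple[int, int, int] = (88, 96, 88)
    voxel_mm: float = 2.0
    brain: Ellipsoid = Ellipsoid((0.0, -4.0, 6.0), (54.0, 62.0, 50.0))
    scalp_thickness_mm: float = 6.0
    caudate_right: Ellipsoid = Ellipsoid((11.0, 14.0, 8.0), (5.0, 12.0, 7.0))
    putamen_right: Ellipsoid = Ellipsoid((26.0, -2.0, 2.0), (9.0, 20.0, 14.0))
    cerebellum: Ellipsoid = Ellipsoid((0.0, -48.0, -24.0), (36.0, 22.0, 18.0))
    ventricles: Ellipsoid = Ellipsoid((0.0, -12.0, 14.0), (14.0, 24.0, 10.0))
    thalamus: Ellipsoid = Ellipsoid((0.0, -16.0, 4.0), (18.0, 14.0, 10.0))
    hv_dilation_mm: float = 12.0  # inflation of the oversized HV putamen masks
    background_dvr: float = 1.0
    scalp_dvr_range: tuple[float, float] = (0.4, 1.2)
    psf_fwhm_mm: float = 4.0
    noise_sd: float = 0.05  # fraction of the background level
    # apparent striatal shrinkage for reduced uptake: low-contrast striata
    # look smaller; emulated by shrinking painted semi-axes linearly down to
    # this fraction at SBR 0. Off (1.0) by default; enabled for cohorts
    # built with deliberate template-mismatch geometry.
    reduced_shrink_at_zero: float = 1.0
    translation_mm: float = 10.0
    rotation_deg: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shear_max: float = 0.05
    scale_range: tuple[float, float] = (0.5, 2.0)

    def template_grid(self) -> VolumetricImage:
        return centered_grid(self.grid_shape, self.voxel_mm, Space.TEMPLATE)

    def __post_init__(self) -> None:
        if self.zoom_range[0] <= 0:
            raise ValueError("zoom range must exclude 0")
        grid = self.template_grid()
        half = np.abs(grid.v2w[:3, 3])
        for name in ("brain", "caudate_right", "putamen_right", "cerebellum"):
            e: Ellipsoid = getattr(self, name)
            hi = np.abs(np.asarray(e.center)) + np.asarray(e.semi_axes)
            margin = self.scalp_thickness_mm if name == "brain" else 0.0
            if np.any(hi + margin > half + self.voxel_mm):
                raise ValueError(f"structure {name!r} does not fit the grid")


@dataclass(frozen=True)
class CohortMixture:
    """Two-component mixture of the minimum putamen SBR.

    Component 1 is the reduced (Parkinson-typical) group, component 2 the
    normal group; draws are truncated at SBR > -0.5 to keep DVR positive.
    """

    p_reduced: float = 0.45
    m_reduced: float = 0.58
    sd_reduced: float = 0.15
    m_normal: float = 1.57
    sd_normal: float = 0.32
    asymmetry_reduced: float = 0.2  # better-minus-worse putamen SBR
    asymmetry_normal: float = 0.05
    caudate_excess_reduced: float = 0.5  # caudate SBR above putamen SBR
    truncation: float = -0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reduced <= 1.0:
            raise ValueError("p_reduced must be a probability")
        if self.sd_reduced <= 0 or self.sd_normal <= 0:
            raise ValueError("mixture SDs must be positive")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one simulated subject."""

    category: Literal["normal", "reduced"]
    worse_side: Literal["left", "right"]
    putamen_sbr: dict[str, float]  # keys "left", "right"
    caudate_sbr: dict[str, float]
    true_affine: AffineTransform12
    intensity_scale: float = 1.0

    @property
    def putamen_dvr(self) -> dict[str, float]:
        return {k: v + 1.0 for k, v in self.putamen_sbr.items()}

    @property
    def sbr_min(self) -> float:
        return min(self.putamen_sbr.values())


def _paint(
    coords: np.ndarray,
    shape: tuple[int, ...],
    regions: Sequence[tuple[Ellipsoid, float]],
    background: float = 0.0,
) -> np.ndarray:
    """Paint nested ellipsoid regions (later entries overwrite earlier)."""
    out = np.full(shape, background, dtype=np.float64)
    for ell, value in regions:
        out[ell.contains(coords)] = value
    return out


def make_anatomy(spec: PhantomSpec) -> tuple[ROIMaskSet, VolumetricImage]:
    """Template-space masks and an integer label image.

    Labels: 0 outside, 1 brain background, 2 scalp shell, 3 cerebellum,
    4 ventricles, 5 thalamus/brainstem placeholder, 6/7 caudate R/L,
    8/9 putamen R/L.
    """
    grid = spec.template_grid()
    coords = grid.world_coords().reshape(grid.shape + (3,))
    brain = spec.brain.contains(coords)
    outer = Ellipsoid(
        spec.brain.center,
        tuple(a + spec.scalp_thickness_mm for a in spec.brain.semi_axes),
    )
    scalp = outer.contains(coords) & ~brain
    cereb = spec.cerebellum.contains(coords) & brain
    vent = spec.ventricles.contains(coords) & brain
    thal = spec.thalamus.contains(coords) & brain
    cau_r = spec.caudate_right.contains(coords)
    cau_l = spec.caudate_right.mirrored().contains(coords)
    put_r = spec.putamen_right.contains(coords)
    put_l = spec.putamen_right.mirrored().contains(coords)
    striatal = [cau_r, cau_l, put_r, put_l]
    for i in range(len(striatal)):
        for j in range(i + 1, len(striatal)):
            if np.any(striatal[i] & striatal[j]):
                raise ValueError("striatal structures overlap")

    label = np.zeros(grid.shape, dtype=np.int16)
    label[brain] = 1
    label[scalp] = 2
    label[cereb] = 3
    label[vent] = 4
    label[thal] = 5
    for lab, m in zip((6, 7, 8, 9), striatal):
        label[m] = lab

    head = (brain | scalp) & ~cereb
    n_dil = max(1, int(round(spec.hv_dilation_mm / spec.voxel_mm)))
    hv_r = ndimage.binary_dilation(put_r, iterations=n_dil)
    hv_l = ndimage.binary_dilation(put_l, iterations=n_dil)
    # keep the oversized masks disjoint at the midline (left voxels to left)
    x = coords[..., 0]
    hv_r &= x > 0
    hv_l &= x < 0
    # the oversized putamen masks avoid the caudate so caudate counts never
    # dominate the hottest-voxels average of an intact caudate
    cau_env = ndimage.binary_dilation(cau_r | cau_l, iterations=2)
    hv_r &= ~cau_env
    hv_l &= ~cau_env
    # generous striatal exclusion: the reference region stays clear of the
    # oversized putamen masks and the caudate envelope
    reference = brain & ~(cereb | vent | thal | cau_env | hv_r | hv_l)

    def as_mask(a: np.ndarray) -> VolumetricImage:
        return VolumetricImage(a.astype(np.float64), grid.v2w, Space.TEMPLATE)

    masks = ROIMaskSet(
        head_mask=as_mask(head),
        reference_mask=as_mask(reference),
        hv_putamen_left=as_mask(hv_l),
        hv_putamen_right=as_mask(hv_r),
        anat_putamen_left=as_mask(put_l),
        anat_putamen_right=as_mask(put_r),
        midsagittal=AxisSpec(axis=0),
    )
    return masks, VolumetricImage(label.astype(np.float64), grid.v2w, Space.TEMPLATE)


def sample_subject(
    mixture: CohortMixture, rng: np.random.Generator, spec: PhantomSpec | None = None
) -> SubjectTruth:
    """Draw one subject's category, SBR truth, and misalignment."""
    spec = spec or PhantomSpec()
    reduced = rng.random() < mixture.p_reduced
    m, sd = (
        (mixture.m_reduced, mixture.sd_reduced)
        if reduced
        else (mixture.m_normal, mixture.sd_normal)
    )
    # truncated normal by rejection: the cut sits far below both components
    worse = float(rng.normal(m, sd))
    while worse <= mixture.truncation:
        worse = float(rng.normal(m, sd))
    asym = mixture.asymmetry_reduced if reduced else mixture.asymmetry_normal
    better = worse + asym
    worse_side = "left" if rng.random() < 0.5 else "right"
    put = {worse_side: worse, ("right" if worse_side == "left" else "left"): better}
    if reduced:
        cau = {k: v + mixture.caudate_excess_reduced for k, v in put.items()}
    else:
        cau = dict(put)

    t = rng.uniform(-spec.translation_mm, spec.translation_mm, 3)
    r = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg, 3))
    z = rng.uniform(*spec.zoom_range, 3)
    s = rng.uniform(-spec.shear_max, spec.shear_max, 3)
    xf = AffineTransform12(tuple(t), tuple(r), tuple(z), tuple(s))
    return SubjectTruth(
        category="reduced" if reduced else "normal",
        worse_side=worse_side,
        putamen_sbr=put,
        caudate_sbr=cau,
        true_affine=xf,
        intensity_scale=float(rng.uniform(*spec.scale_range)),
    )


def _shrunk(ell: Ellipsoid, sbr: float, spec: PhantomSpec, ref_sbr: float) -> Ellipsoid:
    """Apparent size of a striatal structure at reduced uptake.

    After point-spread blurring, a low-contrast structure's visible extent
    is smaller; the painted semi-axes shrink linearly from full size at the
    normal reference SBR down to ``reduced_shrink_at_zero`` at SBR 0.
    """
    frac = min(1.0, max(0.0, sbr / ref_sbr))
    f = spec.reduced_shrink_at_zero + (1.0 - spec.reduced_shrink_at_zero) * frac
    return Ellipsoid(ell.center, tuple(a * f for a in ell.semi_axes))


def _truth_regions(
    spec: PhantomSpec,
    truth: SubjectTruth,
    scalp_on: bool = False,
    scalp_dvr: float | None = None,
    ref_sbr: float = 1.57,
) -> list[tuple[Ellipsoid, float]]:
    regions: list[tuple[Ellipsoid, float]] = [(spec.brain, spec.background_dvr)]
    if scalp_on:
        outer = Ellipsoid(
            spec.brain.center,
            tuple(a + spec.scalp_thickness_mm for a in spec.brain.semi_axes),
        )
        sd = scalp_dvr if scalp_dvr is not None else np.mean(spec.scalp_dvr_range)
        regions = [(outer, float(sd)), (spec.brain, spec.background_dvr)]
    side_struct = {
        "right": (spec.caudate_right, spec.putamen_right),
        "left": (spec.caudate_right.mirrored(), spec.putamen_right.mirrored()),
    }
    for side, (cau, put) in side_struct.items():
        regions.append(
            (_shrunk(cau, truth.caudate_sbr[side], spec, ref_sbr), 1.0 + truth.caudate_sbr[side])
        )
        regions.append(
            (_shrunk(put, truth.putamen_sbr[side], spec, ref_sbr), 1.0 + truth.putamen_sbr[side])
        )
    return regions


def paint_truth(
    spec: PhantomSpec,
    truth: SubjectTruth,
    scalp_on: bool = False,
    scalp_dvr: float | None = None,
    ref_sbr: float = 1.57,
) -> VolumetricImage:
    """Noise-free template-space DVR image for one subject."""
    grid = spec.template_grid()
    regions = _truth_regions(spec, truth, scalp_on, scalp_dvr, ref_sbr)
    coords = grid.world_coords().reshape(grid.shape + (3,))
    return VolumetricImage(
        _paint(coords, grid.shape, regions), grid.v2w, Space.TEMPLATE
    )


def simulate_scan(
    spec: PhantomSpec,
    truth: SubjectTruth,
    scalp_on: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[VolumetricImage, SubjectTruth]:
    """Native-space scan for one subject.

    Forward model: paint the subject's DVR anatomy directly on the native
    grid (the true affine maps native world to template world, so membership
    of a native voxel in each template-space ellipsoid is tested exactly,
    with no interpolation), blur with the scanner point-spread FWHM, add
    zero-truncated Gaussian noise, and apply an arbitrary global intensity
    multiplier. ``truth.true_affine`` maps the native scan back to template
    space.
    """
    rng = rng or np.random.default_rng(0)
    scalp_dvr = float(rng.uniform(*spec.scalp_dvr_range)) if scalp_on else None
    regions = _truth_regions(spec, truth, scalp_on=scalp_on, scalp_dvr=scalp_dvr)
    native_grid = centered_grid(spec.native_shape, spec.voxel_mm, Space.NATIVE)
    A = truth.true_affine.matrix
    coords = native_grid.world_coords() @ A[:3, :3].T + A[:3, 3]
    coords = coords.reshape(native_grid.shape + (3,))
    img = VolumetricImage(
        _paint(coords, native_grid.shape, regions), native_grid.v2w, Space.NATIVE
    )
    img = gaussian_smooth(img, spec.psf_fwhm_mm)
    if spec.noise_sd > 0:
        noisy = img.data + rng.normal(
            0.0, spec.noise_sd * spec.background_dvr, img.shape
        )
        img = img.with_data(np.clip(noisy, 0.0, None))
    return img.with_data(img.data * truth.intensity_scale), truth


def simulate_cohort(
    spec: PhantomSpec,
    n: int,
    mixture: CohortMixture | None = None,
    seed: int = 0,
    scalp_fraction: float = 0.5,
) -> tuple[list[VolumetricImage], list[SubjectTruth], pd.DataFrame]:
    """Reproducible cohort of native scans, truths, and a manifest table."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    mixture = mixture or CohortMixture()
    rng = np.random.default_rng(seed)
    scans, truths, rows = [], [], []
    for i in range(n):
        truth = sample_subject(mixture, rng, spec)
        scalp_on = rng.random() < scalp_fraction
        scan, truth = simulate_scan(spec, truth, scalp_on=scalp_on, rng=rng)
        scans.append(scan)
        truths.append(truth)
        xf = truth.true_affine
        rows.append(
            {
                "scan_id": f"scan_{i:05d}",
                "category": truth.category,
                "worse_side": truth.worse_side,
                "scalp_on": scalp_on,
                "true_sbr_left": truth.putamen_sbr["left"],
                "true_sbr_right": truth.putamen_sbr["right"],
                "true_sbr_min": truth.sbr_min,
                "true_det": xf.det,
                "intensity_scale": truth.intensity_scale,
                **{f"t{k}": xf.translation[k] for k in range(3)},
                **{f"r{k}": xf.rotation[k] for k in range(3)},
                **{f"z{k}": xf.zoom[k] for k in range(3)},
                **{f"s{k}": xf.shear[k] for k in range(3)},
            }
        )
    return scans, truths, pd.DataFrame(rows)


def category_truth(
    spec: PhantomSpec,
    category: Literal["normal", "moderate_right", "moderate_left", "strong"],
    sbr_levels: dict[str, float] | None = None,
) -> SubjectTruth:
    """Idealized subject truth for one template category.

    Default minimum putamen SBR levels per category follow the typical
    values of template-building scans in a large clinical sample: normal
    1.896, moderate 0.663 (worse right; asymmetry 0.3), strong 0.282
    (near-symmetric).
    """
    levels = sbr_levels or {"normal": 1.896, "moderate": 0.663, "strong": 0.282}
    ident = AffineTransform12()
    if category == "normal":
        v = levels["normal"]
        return SubjectTruth(
            "normal", "right", {"left": v, "right": v}, {"left": v, "right": v}, ident
        )
    if category in ("moderate_right", "moderate_left"):
        worse = "right" if category == "moderate_right" else "left"
        better = "left" if worse == "right" else "right"
        v = levels["moderate"]
        put = {worse: v, better: v + 0.3}
        cau = {k: s + 0.5 for k, s in put.items()}
        return SubjectTruth("reduced", worse, put, cau, ident)
    if category == "strong":
        v = levels["strong"]
        put = {"left": v, "right": v}
        cau = {k: s + 0.3 for k, s in put.items()}
        return SubjectTruth("reduced", "right", put, cau, ident)
    raise ValueError(f"unknown category {category!r}")


def painted_template_set(
    spec: PhantomSpec, psf: bool = True
) -> tuple[list[VolumetricImage], list[tuple[str, str]]]:
    """Noise-free 8-template set painted directly from category truths.

    Categories (normal, moderate_right, moderate_left, strong) each with and
    without a scalp shell, blurred with the phantom point-spread function.
    Used as registration targets when the iterative template builder is not
    exercised.
    """
    templates, labels = [], []
    for cat in ("normal", "moderate_right", "moderate_left", "strong"):
        for scalp in (False, True):
            t = paint_truth(spec, category_truth(spec, cat), scalp_on=scalp,
                            scalp_dvr=float(np.mean(spec.scalp_dvr_range)))
            if psf:
                t = gaussian_smooth(t, spec.psf_fwhm_mm)
            templates.append(t)
            labels.append((cat, "with_scalp" if scalp else "without_scalp"))
    return templates, labels
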