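"""Affine stereotactical normalization to the template grid.

A native scan is mapped into template space by a 12-parameter affine
(translations, rotations, zooms, shears; no nonlinear warping). The target
is either a single template or a set of templates: at every cost evaluation
the weighted linear least-squares problem for the template-combination
coefficients (plus a constant offset column) is solved in closed form, and
the affine parameters are optimized by Nelder-Mead over a coarse-to-fine
smoothing pyramid. Weighting is the product of a template-space head mask
and a 200 mm source cube centered at the scan's center of mass, mapped into
template space. Zooms (log) and shears carry a small quadratic penalty
toward identity so the problem stays well-posed when the masks are loose.

The determinant of the linear part of the native-to-template world mapping
(DET) summarizes the volume stretching: DET > 1 means the native brain is
enlarged into template space, i.e. the native brain is smaller than the
template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .voxel_core import (
    InvalidTransformError,
    Space,
    VolumetricImage,
    gaussian_smooth,
    resample,
)


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass(frozen=True)
class AffineTransform12:
    """12-parameter affine, native world -> template world (mm).

    Composition order is fixed and documented: ``M = T . R . Z . S`` with
    translation T, rotation R = Rx(rx) Ry(ry) Rz(rz), zoom Z = diag(zooms),
    and unit-upper-triangular shear S carrying factors at (0,1), (0,2), (1,2).
    Zooms must be positive, so DET (the determinant of the linear part,
    exactly the product of the zooms) is positive.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zoom: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "zoom", "shear"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3:
                raise ValueError(f"{name} must have 3 components")
            object.__setattr__(self, name, v)
        if any(z <= 0 for z in self.zoom):
            raise InvalidTransformError("zooms must be strictly positive")

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous native->template world matrix (T.R.Z.S)."""
        S = np.eye(3)
        S[0, 1], S[0, 2], S[1, 2] = self.shear
        A = _rotation_matrix(*self.rotation) @ np.diag(self.zoom) @ S
        m = np.eye(4)
        m[:3, :3] = A
        m[:3, 3] = self.translation
        return m

    @property
    def det(self) -> float:
        """Determinant of the 3x3 linear part (= product of the zooms)."""
        return float(np.linalg.det(self.matrix[:3, :3]))

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.zoom, self.shear])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "AffineTransform12":
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (12,):
            raise ValueError("parameter vector must have 12 entries")
        return cls(tuple(v[0:3]), tuple(v[3:6]), tuple(v[6:9]), tuple(v[9:12]))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform12":
        """Decompose a 4x4 affine into T.R.Z.S parameters.

        Uses the QR factorization A = R.(Z.S) with positive zoom signs; the
        round-trip parameters -> matrix -> parameters is exact to 1e-10 for
        proper (DET > 0) transforms with rotations inside gimbal range.
        """
        m = np.asarray(m, dtype=np.float64)
        A = m[:3, :3]
        if np.linalg.det(A) <= 0:
            raise InvalidTransformError("matrix must have positive determinant")
        Q, U = np.linalg.qr(A)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q = Q * signs
        U = signs[:, None] * U
        zoom = np.diag(U).copy()
        S = U / zoom[:, None]
        # Euler angles for Q = Rx(rx) Ry(ry) Rz(rz)
        ry = np.arcsin(np.clip(Q[0, 2], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-9:
            rx = np.arctan2(-Q[1, 2], Q[2, 2])
            rz = np.arctan2(-Q[0, 1], Q[0, 0])
        else:  # gimbal lock: fold rz into rx
            rx = np.arctan2(Q[2, 1], Q[1, 1])
            rz = 0.0
        return cls(
            tuple(m[:3, 3]),
            (float(rx), float(ry), float(rz)),
            tuple(zoom),
            (float(S[0, 1]), float(S[0, 2]), float(S[1, 2])),
        )


def det_of(xf: AffineTransform12) -> float:
    """DET of the affine normalization (linear-part determinant)."""
    return xf.det


def source_cube_mask(img: VolumetricImage, edge_mm: float = 200.0) -> VolumetricImage:
    """Binary cube of given edge length centered at the intensity COM.

    The cube is axis-aligned in the scan's native world coordinates; it
    restricts the registration cost to the head region.
    """
    total = img.data.sum()
    if total <= 0:
        raise ValueError("image has no positive intensity mass")
    coords = img.world_coords().reshape(img.shape + (3,))
    com = (img.data[..., None] * coords).sum(axis=(0, 1, 2)) / total
    inside = np.all(np.abs(coords - com) <= edge_mm / 2.0, axis=-1)
    return VolumetricImage(inside.astype(np.float64), img.v2w, img.space_tag)


@dataclass
class RegistrationOptions:
    """Tuning knobs for :func:`normalize`.

    ``pyramid`` is a list of levels (method, added smoothing fwhm mm, grid
    stride, free parameter count, iteration budget). The coarse level uses
    derivative-free Nelder-Mead ("nm") over the rigid subset for capture
    range; finer levels refine by finite-difference Gauss-Newton ("gn",
    scipy trust-region least squares) over progressively more parameters.
    ``reg_lambda`` weights the quadratic penalty on log-zooms and shears; it
    is kept small so self-registration and moderate true zooms are
    recovered without bias.
    """

    pyramid: list[tuple[str, float, int, int, int]] = field(
        default_factory=lambda: [
            ("nm", 8.0, 3, 9, 300),
            ("nm", 4.0, 3, 9, 150),
            ("gn", 4.0, 2, 9, 25),
            ("gn", 0.0, 2, 12, 40),
        ]
    )
    # coarse-level multi-start over initial isotropic zooms: anisotropic
    # zoom of a near-ellipsoidal head can masquerade as a large rotation,
    # so several zoom seeds are raced and the lowest cost wins
    zoom_starts: tuple[float, ...] = (1.0, 0.93, 1.08)
    reg_lambda: float = 1e-4
    # quadratic penalty pulling rotations toward identity (rad^-2); steers
    # the coarse search away from spurious near-symmetric head orientations
    # while leaving realistic rotations (~10 deg, penalty ~3e-4) unbiased
    rot_lambda: float = 1e-2
    cube_edge_mm: float = 200.0
    # extra template smoothing compensating the resolution loss that one
    # trilinear resampling inflicts on the moved image (a 2 mm voxel linear
    # kernel carries variance ~voxel^2/6, i.e. about 1.9 mm fwhm)
    template_fwhm_mm: float = 1.9
    # outward padding of the head weighting mask: keeps the head-air
    # boundary inside the cost so zoom cannot push bright scalp out of view
    head_pad_mm: float = 8.0
    xatol: float = 1e-3
    fatol: float = 1e-10


@dataclass
class NormalizationResult:
    transform: AffineTransform12
    template_coefficients: np.ndarray  # per-template weights, offset excluded
    normalized: VolumetricImage  # scan resampled to the template grid
    cost_trace: list[float]
    converged: bool


# internal scaling so a unit Nelder-Mead step is comparable across parameter
# kinds: mm for translations, rad/0.05 for rotations, log-zoom/0.02, shear/0.02
_PARAM_SCALE = np.array([5.0, 5.0, 5.0, 0.05, 0.05, 0.05, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02])


def _vec_to_xf(x: np.ndarray) -> AffineTransform12:
    p = x * _PARAM_SCALE[: len(x)]
    full = np.zeros(12)
    full[: len(p)] = p
    return AffineTransform12(
        tuple(full[0:3]),
        tuple(full[3:6]),
        tuple(np.exp(full[6:9])),
        tuple(full[9:12]),
    )


def _xf_to_vec(xf: AffineTransform12, n: int) -> np.ndarray:
    full = np.concatenate(
        [xf.translation, xf.rotation, np.log(xf.zoom), xf.shear]
    )
    return full[:n] / _PARAM_SCALE[:n]


def _strided(img: VolumetricImage, stride: int) -> VolumetricImage:
    if stride == 1:
        return img
    data = img.data[::stride, ::stride, ::stride]
    v2w = img.v2w.copy()
    v2w[:3, :3] *= stride
    return VolumetricImage(np.ascontiguousarray(data), v2w, img.space_tag)


def _com_world(img: VolumetricImage) -> np.ndarray:
    total = img.data.sum()
    coords = img.world_coords().reshape(img.shape + (3,))
    return (img.data[..., None] * coords).sum(axis=(0, 1, 2)) / total


def normalize(
    img: VolumetricImage,
    templates: VolumetricImage | Sequence[VolumetricImage],
    head_mask: VolumetricImage,
    source_mask: VolumetricImage | None = None,
    opts: RegistrationOptions | None = None,
) -> NormalizationResult:
    """Affine-normalize a native scan against one or several templates.

    Minimizes the head-mask/source-cube weighted sum of squared differences
    between the resampled scan and the best linear combination of the
    templates (coefficients solved in closed form at every evaluation, with
    a constant offset column), over a coarse-to-fine smoothing pyramid.
    """
    if isinstance(templates, VolumetricImage):
        templates = [templates]
    templates = list(templates)
    if not templates:
        raise ValueError("need at least one template")
    grid = templates[0]
    for t in templates[1:]:
        if not t.same_grid(grid):
            raise ValueError("templates must share one grid")
    if not head_mask.same_grid(grid):
        raise ValueError("head mask must live on the template grid")
    if int((head_mask.data > 0).sum()) < len(templates) + 1 + 12:
        raise ValueError("degenerate weight mask: too few in-mask voxels")
    opts = opts or RegistrationOptions()
    if source_mask is None:
        source_mask = source_cube_mask(img, opts.cube_edge_mm)
    if opts.head_pad_mm > 0:
        n_pad = max(1, int(round(opts.head_pad_mm / float(head_mask.voxel_size.min()))))
        head_mask = head_mask.with_data(
            ndimage.binary_dilation(head_mask.data > 0, iterations=n_pad).astype(
                np.float64
            )
        )

    # intensity pre-scaling: the global scale of the scan is arbitrary; fix
    # it so the zoom/shear penalty has a stable meaning relative to the data
    scale = float(np.sqrt(np.mean(img.data**2)))
    if scale <= 0:
        raise ValueError("scan has no signal")
    img_s = img.with_data(img.data / scale)
    src_box = np.asarray(source_mask.data > 0)
    # native-world bounding box of the source cube, for the analytic weight
    src_coords = source_mask.world_coords().reshape(source_mask.shape + (3,))
    lo = src_coords[src_box].min(axis=0)
    hi = src_coords[src_box].max(axis=0)

    # initialization: center-of-mass alignment, unit zooms, no rotation
    t0 = _com_world(head_mask) - _com_world(img_s)
    xf = AffineTransform12(translation=tuple(t0))

    cost_trace: list[float] = []
    converged = True
    n_free_params = 0

    inv_v2w_src = np.linalg.inv(img_s.v2w)
    for level_i, (method, fwhm, stride, n_free, budget) in enumerate(opts.pyramid):
        first_level = level_i == 0
        level_grid = _strided(grid, stride)
        tpl_fwhm = float(np.hypot(fwhm, opts.template_fwhm_mm))
        tpl_data = np.stack(
            [
                gaussian_smooth(_strided(t, stride), tpl_fwhm).data.ravel()
                for t in templates
            ],
            axis=1,
        )
        w_head = _strided(head_mask, stride).data.ravel() > 0
        img_l = gaussian_smooth(img_s, fwhm)
        coords_t = level_grid.world_coords()  # template world, (N, 3)
        n_free_params = n_free
        sqrt_lam = np.sqrt(opts.reg_lambda)

        # weight support frozen at the level's starting transform: head mask
        # (padded) times the source cube mapped into template space
        inv0 = xf.inverse_matrix()
        native0 = coords_t @ inv0[:3, :3].T + inv0[:3, 3]
        w = w_head & np.all((native0 >= lo) & (native0 <= hi), axis=1)
        nw = int(w.sum())
        if nw < tpl_data.shape[1] + 1 + 12:
            raise ValueError("degenerate weight mask: too few in-mask voxels")
        # orthonormal basis of the template + offset columns: the inner
        # closed-form coefficient solve becomes a projection
        X = np.column_stack([tpl_data[w], np.ones(nw)])
        Q, _ = np.linalg.qr(X)
        # voxel indices (level grid) of the in-mask support
        idx = np.stack(
            np.meshgrid(*(np.arange(0, n) for n in level_grid.shape), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)[w]
        sqrt_nw = np.sqrt(nw)
        data_l = img_l.data

        sqrt_rot = np.sqrt(opts.rot_lambda)

        def residuals(x: np.ndarray) -> np.ndarray:
            """Projection residuals of the moved scan onto the template
            subspace at the in-mask voxels, with the zoom/shear/rotation
            penalties appended as extra residual entries."""
            xf_x = _vec_to_xf(x)
            m = inv_v2w_src @ xf_x.inverse_matrix() @ level_grid.v2w
            vox = idx @ m[:3, :3].T + m[:3, 3]
            moved = ndimage.map_coordinates(
                data_l, vox.T, order=1, mode="constant", cval=0.0, prefilter=False
            )
            r_data = (moved - Q @ (Q.T @ moved)) / sqrt_nw
            pen = np.concatenate(
                [
                    sqrt_lam * np.log(xf_x.zoom),
                    sqrt_lam * np.array(xf_x.shear),
                    sqrt_rot * np.array(xf_x.rotation),
                ]
            )
            return np.concatenate([r_data, pen])

        def cost(x: np.ndarray) -> float:
            r = residuals(x)
            return float(r @ r)

        x0 = _xf_to_vec(xf, n_free)
        c0 = cost(x0)
        if method == "nm":
            starts = [x0]
            if first_level and n_free >= 9:
                for z0 in opts.zoom_starts[1:]:
                    alt = x0.copy()
                    alt[6:9] = np.log(z0) / _PARAM_SCALE[6:9]
                    starts.append(alt)
            best_x, best_c = x0, c0
            for xs in starts:
                # explicit initial simplex: one scaled unit per free
                # parameter (scipy's relative default collapses for
                # zero-valued parameters)
                simplex = np.vstack(
                    [xs] + [xs + np.eye(n_free)[i] for i in range(n_free)]
                )
                res = optimize.minimize(
                    cost,
                    xs,
                    method="Nelder-Mead",
                    options={
                        "maxiter": budget,
                        "xatol": opts.xatol,
                        "fatol": opts.fatol * max(c0, 1.0),
                        "adaptive": True,
                        "initial_simplex": simplex,
                    },
                )
                if float(res.fun) < best_c:
                    best_x, best_c = res.x, float(res.fun)
            x_new, c_new, success = best_x, best_c, True
        elif method == "gn":
            res = optimize.least_squares(
                residuals,
                x0,
                method="trf",
                diff_step=1e-2,
                max_nfev=budget,
                x_scale=1.0,
            )
            x_new, c_new, success = res.x, float(2.0 * res.cost), res.status > 0
        else:
            raise ValueError(f"unknown pyramid method {method!r}")
        if c_new <= c0:
            xf = _vec_to_xf(x_new)
            cost_trace.extend([c0, c_new])
        else:  # keep the better point; never accept an uphill level
            cost_trace.extend([c0, c0])
        if not success and c_new > c0:
            converged = False

    # final closed-form coefficients and full-resolution resampling
    tpl_full = np.stack([t.data.ravel() for t in templates], axis=1)
    moved_full = resample(img_s, xf.matrix, grid)
    native = grid.world_coords() @ xf.inverse_matrix()[:3, :3].T + xf.inverse_matrix()[:3, 3]
    w = (head_mask.data.ravel() > 0) & np.all((native >= lo) & (native <= hi), axis=1)
    if int(w.sum()) < tpl_full.shape[1] + 1 + n_free_params:
        raise ValueError("degenerate weight mask: too few in-mask voxels")
    X = np.column_stack([tpl_full[w], np.ones(int(w.sum()))])
    beta, *_ = np.linalg.lstsq(X, moved_full.data.ravel()[w], rcond=None)

    normalized = VolumetricImage(
        resample(img, xf.matrix, grid).data, grid.v2w, Space.TEMPLATE
    )
    return NormalizationResult(
        transform=xf,
        template_coefficients=beta[:-1] * scale,
        normalized=normalized,
        cost_trace=cost_trace,
        converged=converged,
    )
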