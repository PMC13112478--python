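"""Diffeomorphic label propagation: the semi-automatic ground-truth engine.

Two propagation modes are provided on top of one pairwise registration
primitive:

* ``propagate_labels_3d`` extends sparse, fully-labelled short-axis key slices
  through a 3D volume by chaining 2D slice-to-slice registrations from both
  flanking key slices and fusing the two warped label sets with
  inverse-distance weights.
* ``propagate_labels_4d`` carries end-diastolic and end-systolic 3D label maps
  to every intermediate cardiac phase by chaining 3D phase-to-phase
  registrations outward from each source, each target taking the cyclically
  nearer source.

The registration primitive is a multiresolution log-domain demons: a
stationary velocity field updated by intensity forces and Gaussian smoothing,
exponentiated by scaling-and-squaring, which guarantees a positive Jacobian
determinant (a diffeomorphic mapping) by construction.  It is fully
deterministic — no random numbers are involved anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .io_core import BACKGROUND, FOREGROUND_CLASSES, Cine4D, LabelMap4D
from .phantom import KeySliceAnnotation

__all__ = [
    "DeformationField",
    "RegistrationConfig",
    "register_diffeomorphic",
    "warp_labels",
    "warp_image",
    "compose_displacements",
    "propagate_labels_3d",
    "propagate_labels_4d",
]

# Argmax ties when warping one-hot labels are broken by this fixed priority.
_CLASS_PRIORITY = (*FOREGROUND_CLASSES, BACKGROUND)  # LVB > LVM > RVB > background


@dataclass
class RegistrationConfig:
    n_levels: int = 3
    iters_per_level: tuple[int, ...] = (60, 30, 10)  # coarsest level first
    update_smoothing_sigma_mm: float = 2.0
    field_smoothing_sigma_mm: float = 1.0
    step_scale: float = 2.0
    metric: Literal["ssd", "local_cc"] = "ssd"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.update_smoothing_sigma_mm < 0 or self.field_smoothing_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if len(self.iters_per_level) < self.n_levels:
            raise ValueError("iters_per_level must list one entry per level")


@dataclass
class DeformationField:
    """Dense displacement field in mm on a voxel grid (2D or 3D).

    ``displacement[..., k]`` moves a point along grid axis ``k``; the mapping
    x -> x + displacement(x) is the (voxel-to-voxel, mm-scaled) spatial map.
    """

    displacement: np.ndarray  # (*grid, ndim), mm
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        ndim = self.displacement.shape[-1]
        if self.displacement.ndim != ndim + 1:
            raise ValueError("displacement must have shape (*grid, ndim)")

    @property
    def ndim(self) -> int:
        return self.displacement.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.displacement.shape[:-1]

    def displacement_vox(self) -> np.ndarray:
        return self.displacement / self.spacing_mm[: self.ndim]

    def jacobian_determinant(self) -> np.ndarray:
        """det of the Jacobian of x + u(x) at every voxel (dimensionless)."""
        u = self.displacement_vox()
        ndim = self.ndim
        jac = np.empty((*self.grid_shape, ndim, ndim))
        for i in range(ndim):
            grads = np.gradient(u[..., i], axis=tuple(range(ndim)))
            grads = [grads] if ndim == 1 else grads
            for j in range(ndim):
                jac[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
        return np.linalg.det(jac)


def _sample(arr: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def _identity_coords(shape: Sequence[int]) -> np.ndarray:
    # float32 keeps the demons inner loop memory-bandwidth friendly
    return np.indices(shape, dtype=np.float32)


def warp_image(image: np.ndarray, disp_vox: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``image`` at x + disp(x); displacement in voxel units."""
    coords = _identity_coords(image.shape) + np.moveaxis(disp_vox, -1, 0)
    return _sample(image, coords, order).reshape(image.shape)


def compose_displacements(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of x -> x + outer(x) followed by y -> y + inner(y).

    ``result(x) = outer(x) + inner(x + outer(x))`` — both in voxel units.
    """
    coords = _identity_coords(outer.shape[:-1]) + np.moveaxis(outer, -1, 0)
    warped_inner = np.stack(
        [_sample(inner[..., k], coords, order=1) for k in range(inner.shape[-1])], axis=-1
    )
    return outer + warped_inner


def _exponentiate(velocity: np.ndarray) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring."""
    vmax = np.max(np.abs(velocity)) if velocity.size else 0.0
    n_steps = max(0, int(np.ceil(np.log2(max(vmax, 1e-9) / 0.5))))
    disp = velocity / (2.0**n_steps)
    for _ in range(n_steps):
        disp = compose_displacements(disp, disp)
    return disp


def _resize_to(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if arr.shape == tuple(shape):
        return arr
    factors = [t / s for t, s in zip(shape, arr.shape)]
    out = ndimage.zoom(arr, factors, order=1, mode="nearest", grid_mode=True)
    # zoom can be off by one voxel when factors are non-integer; crop or edge-pad
    slices = tuple(slice(0, min(o, t)) for o, t in zip(out.shape, shape))
    out = out[slices]
    pad = [(0, t - o) for o, t in zip(out.shape, shape)]
    if any(p[1] for p in pad):
        out = np.pad(out, pad, mode="edge")
    return out


def _normalize_pair(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = min(fixed.min(), moving.min())
    hi = max(fixed.max(), moving.max())
    scale = hi - lo if hi > lo else 1.0
    return (fixed - lo) / scale, (moving - lo) / scale


def _local_normalize(img: np.ndarray, sigma_vox: float = 4.0) -> np.ndarray:
    mean = ndimage.gaussian_filter(img, sigma_vox)
    var = ndimage.gaussian_filter(img * img, sigma_vox) - mean**2
    return (img - mean) / np.sqrt(np.maximum(var, 1e-6))


def register_diffeomorphic(
    fixed: np.ndarray,
    moving: np.ndarray,
    cfg: RegistrationConfig | None = None,
    spacing_mm: float | Sequence[float] = 1.0,
) -> DeformationField:
    """Multiresolution log-domain demons registration of ``moving`` onto ``fixed``.

    Returns the field mapping fixed-grid points into the moving image, i.e.
    ``moving(x + u(x)) ~ fixed(x)``; ``warp_labels``/``warp_image`` with this
    field pull the moving image (or its labels) onto the fixed grid.
    """
    cfg = cfg or RegistrationConfig()
    fixed = np.asarray(fixed, dtype=np.float32)
    moving = np.asarray(moving, dtype=np.float32)
    if fixed.shape != moving.shape:
        raise ValueError(f"geometry mismatch: {fixed.shape} vs {moving.shape}")
    if not (np.isfinite(fixed).all() and np.isfinite(moving).all()):
        raise ValueError("non-finite voxels in registration input")
    ndim = fixed.ndim
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (ndim,)).copy()

    fixed, moving = _normalize_pair(fixed, moving)
    if cfg.metric == "local_cc":
        fixed, moving = _local_normalize(fixed), _local_normalize(moving)

    full_shape = fixed.shape
    level_shapes = [
        tuple(max(8, s // (2**lvl)) for s in full_shape)
        for lvl in range(cfg.n_levels - 1, -1, -1)
    ]  # coarsest first
    iters = list(cfg.iters_per_level[: cfg.n_levels])

    velocity: np.ndarray | None = None
    for shape, n_iter in zip(level_shapes, iters):
        scale = np.array([f / s for f, s in zip(full_shape, shape)])
        smooth = np.maximum((scale - 1) / 2.0, 0.0)
        fix_l = _resize_to(ndimage.gaussian_filter(fixed, smooth), shape)
        mov_l = _resize_to(ndimage.gaussian_filter(moving, smooth), shape)
        spacing_l = spacing * scale

        if velocity is None:
            velocity = np.zeros((*shape, ndim), dtype=np.float32)
        else:
            prev_shape = velocity.shape[:-1]
            comps = [
                _resize_to(velocity[..., k], shape) * (shape[k] / prev_shape[k])
                for k in range(ndim)
            ]
            velocity = np.stack(comps, axis=-1)

        velocity = _demons_level(fix_l, mov_l, velocity, spacing_l, n_iter, cfg)

    assert velocity is not None
    disp_vox = _exponentiate(velocity)
    disp_mm = disp_vox * spacing
    return DeformationField(disp_mm, spacing)


def _demons_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    velocity: np.ndarray,
    spacing: np.ndarray,
    n_iter: int,
    cfg: RegistrationConfig,
) -> np.ndarray:
    ndim = fixed.ndim
    sigma_update = cfg.update_smoothing_sigma_mm / spacing
    sigma_field = cfg.field_smoothing_sigma_mm / spacing
    grad_fixed = np.stack(np.gradient(fixed), axis=-1)

    best_v, best_ssd = velocity, np.inf
    rising = 0
    for _ in range(n_iter):
        disp = _exponentiate(velocity)
        warped = warp_image(moving, disp, order=1)
        diff = fixed - warped
        ssd = float(np.mean(diff**2))
        if ssd < best_ssd:
            best_ssd, best_v = ssd, velocity
            rising = 0
        else:
            rising += 1
            if rising >= 3:
                warnings.warn("demons metric increased 3 consecutive iterations; "
                              "returning best-so-far field")
                return best_v

        grad_warped = np.stack(np.gradient(warped), axis=-1)
        grad = 0.5 * (grad_fixed + grad_warped)
        gnorm2 = np.sum(grad**2, axis=-1)
        denom = gnorm2 + diff**2
        with np.errstate(divide="ignore", invalid="ignore"):
            update = cfg.step_scale * diff[..., None] * grad / denom[..., None]
        update[~np.isfinite(update)] = 0.0
        for k in range(ndim):
            if sigma_update[k] > 0:
                update[..., k] = ndimage.gaussian_filter(update[..., k], sigma_update)
        velocity = velocity + update
        for k in range(ndim):
            if sigma_field[k] > 0:
                velocity[..., k] = ndimage.gaussian_filter(velocity[..., k], sigma_field)

    disp = _exponentiate(velocity)
    ssd = float(np.mean((fixed - warp_image(moving, disp, order=1)) ** 2))
    return velocity if ssd < best_ssd else best_v


def _warp_onehot(labels: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
    """Warp labels as one-hot probability channels; returns (*grid, 4) floats."""
    coords = _identity_coords(labels.shape) + np.moveaxis(disp_vox, -1, 0)
    probs = np.empty((*labels.shape, 4), dtype=np.float32)
    for code in range(4):
        probs[..., code] = _sample((labels == code).astype(np.float32), coords, order=1).reshape(
            labels.shape
        )
    return probs


def _argmax_priority(probs: np.ndarray) -> np.ndarray:
    """Argmax over the class axis with ties broken LVB > LVM > RVB > background."""
    out = np.full(probs.shape[:-1], _CLASS_PRIORITY[0], dtype=np.uint8)
    best = probs[..., _CLASS_PRIORITY[0]].copy()
    for code in _CLASS_PRIORITY[1:]:
        better = probs[..., code] > best
        out[better] = code
        best = np.where(better, probs[..., code], best)
    return out


def warp_labels(labels: np.ndarray, field: DeformationField) -> np.ndarray:
    """Warp an integer label array with a deformation field.

    Each class is warped as a one-hot channel with linear interpolation and the
    result taken as the per-voxel argmax (fixed priority on ties), which avoids
    nearest-neighbour aliasing on thin structures such as the myocardium.
    """
    labels = np.asarray(labels)
    if labels.shape != field.grid_shape:
        raise ValueError(f"geometry mismatch: labels {labels.shape} vs field {field.grid_shape}")
    return _argmax_priority(_warp_onehot(labels, field.displacement_vox()))


def propagate_labels_3d(
    volume: np.ndarray,
    keys: KeySliceAnnotation,
    cfg: RegistrationConfig | None = None,
    spacing_mm: float | Sequence[float] = 1.0,
) -> np.ndarray:
    """Fill unlabelled slices between key slices by chained 2D registration.

    Every slice between two flanking key slices receives both key label sets,
    each carried along the chain of adjacent-slice registrations, fused by
    inverse-distance weighting of their one-hot channels before the argmax.
    Slices outside the key-slice span stay background.
    """
    cfg = cfg or RegistrationConfig()
    volume = np.asarray(volume, dtype=np.float64)
    axis = keys.slice_axis
    indices = sorted(keys.slice_indices)
    if len(indices) < 2:
        raise ValueError("at least 2 key slices are required")
    interior_empty = [z for z in indices[1:-1] if not keys.slices[z].any()]
    if interior_empty:
        raise ValueError(f"interior key slices without labels: {interior_empty}")

    vol = np.moveaxis(volume, axis, -1)  # (..., z)
    out = np.zeros(vol.shape, dtype=np.uint8)
    ndim_inplane = vol.ndim - 1
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (volume.ndim,))
    inplane_spacing = np.delete(spacing, axis)

    for z in indices:
        out[..., z] = keys.slices[z]

    for k1, k2 in zip(indices[:-1], indices[1:]):
        gap = k2 - k1
        if gap <= 1:
            continue
        probs_up: dict[int, np.ndarray] = {}
        psi = np.zeros((*vol.shape[:-1], ndim_inplane))
        for z in range(k1 + 1, k2):
            step = register_diffeomorphic(vol[..., z], vol[..., z - 1], cfg, inplane_spacing)
            psi = compose_displacements(step.displacement_vox(), psi)
            probs_up[z] = _warp_onehot(keys.slices[k1], psi)
        psi = np.zeros((*vol.shape[:-1], ndim_inplane))
        for z in range(k2 - 1, k1, -1):
            step = register_diffeomorphic(vol[..., z], vol[..., z + 1], cfg, inplane_spacing)
            psi = compose_displacements(step.displacement_vox(), psi)
            w_lo = (k2 - z) / gap  # weight of the lower key's labels
            fused = w_lo * probs_up[z] + (1.0 - w_lo) * _warp_onehot(keys.slices[k2], psi)
            out[..., z] = _argmax_priority(fused)

    return np.moveaxis(out, -1, axis)


def _cyclic_path(src: int, dst: int, n: int) -> list[int]:
    """Phases stepped through from src to dst along the shorter cyclic arc."""
    fwd, bwd = (dst - src) % n, (src - dst) % n
    step = 1 if fwd <= bwd else -1
    length = min(fwd, bwd)
    return [(src + step * k) % n for k in range(1, length + 1)]


def propagate_labels_4d(
    cine: Cine4D,
    ed_labels: np.ndarray,
    es_labels: np.ndarray,
    ed_phase: int,
    es_phase: int,
    cfg: RegistrationConfig | None = None,
) -> LabelMap4D:
    """Propagate ED and ES 3D labels to every cardiac phase.

    Labels for each phase come from the cyclically nearer source (ties go to
    ED), carried by composing registrations between temporally adjacent phases
    outward from the source.  The ED and ES phases keep their input labels.
    """
    cfg = cfg or RegistrationConfig()
    n = cine.n_phases
    ed_labels = np.asarray(ed_labels, dtype=np.uint8)
    es_labels = np.asarray(es_labels, dtype=np.uint8)
    for name, lab in (("ed", ed_labels), ("es", es_labels)):
        if lab.shape != cine.grid_shape:
            raise ValueError(f"{name}_labels shape {lab.shape} != cine grid {cine.grid_shape}")
    if n == 1:
        return LabelMap4D(ed_labels[..., None], cine.spacing_mm, cine.affine, cine.frame_ms)
    if ed_phase == es_phase:
        raise ValueError("ed_phase and es_phase must be distinct")

    out = np.zeros((*cine.grid_shape, n), dtype=np.uint8)
    out[..., ed_phase] = ed_labels
    out[..., es_phase] = es_labels

    sources = {ed_phase: ed_labels, es_phase: es_labels}
    assignment: dict[int, int] = {}
    for t in range(n):
        if t in sources:
            continue
        d_ed = min((t - ed_phase) % n, (ed_phase - t) % n)
        d_es = min((t - es_phase) % n, (es_phase - t) % n)
        assignment[t] = ed_phase if d_ed <= d_es else es_phase

    pair_cache: dict[tuple[int, int], np.ndarray] = {}

    def step_field(fixed_p: int, moving_p: int) -> np.ndarray:
        key = (fixed_p, moving_p)
        if key not in pair_cache:
            field = register_diffeomorphic(
                cine.phase(fixed_p), cine.phase(moving_p), cfg, cine.spacing_mm
            )
            pair_cache[key] = field.displacement_vox()
        return pair_cache[key]

    for src, labels_src in sources.items():
        for direction in (1, -1):
            psi: np.ndarray | None = None
            prev = src
            t = (src + direction) % n
            while t not in sources and assignment.get(t) == src:
                step = step_field(t, prev)
                psi = step if psi is None else compose_displacements(step, psi)
                out[..., t] = _argmax_priority(_warp_onehot(labels_src, psi))
                prev = t
                t = (t + direction) % n

    return LabelMap4D(out, cine.spacing_mm, cine.affine, cine.frame_ms)
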