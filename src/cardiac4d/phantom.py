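"""Seeded synthetic 4D beating-heart phantoms with analytically known volumes.

The phantom stands in for non-shareable patient data: an isotropic slab
(default 96^3 voxels at 1.4 mm) covering a full cardiac cycle in fixed-length
frames.  The left ventricle is a truncated prolate ellipsoid blood pool inside
a myocardial shell; the endocardium contracts with a raised-cosine phase
profile so the blood-pool volume follows a prescribed ejection fraction, while
the epicardial semi-axes are re-solved every phase so the shell (myocardial)
volume is conserved exactly.  The right ventricle is a crescent: a larger
lateral ellipsoid minus the left-ventricular epicardium, restricted to the
septal side.  Blood/myocardium/background intensities emulate either a bSSFP-
or GRE-like contrast, with additive Gaussian noise.

The closed-form (pre-voxelisation) left-ventricular volumes are exposed so
that volume-recovery tests have an oracle that does not depend on the
voxeliser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .io_core import LVB, LVM, RVB, Cine4D, LabelMap4D, centered_affine

__all__ = [
    "GeometryError",
    "PhantomParams",
    "PhantomTruth",
    "KeySliceAnnotation",
    "generate_phantom",
    "analytic_lv_volume",
    "contraction_profile",
    "simulate_key_slice_annotations",
]

# Long axis of the phantom heart is the z axis: short-axis planes are xy slices.
_ELONGATION = 1.6      # endocardial long-axis semi-axis / short-axis semi-axis
_BASAL_FRACTION = 0.7  # basal truncation plane at z = f * c above the LV centre
_MARGIN_VOX = 3


class GeometryError(ValueError):
    """The requested heart does not fit in the grid with the required margin."""


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.4
    n_phases: int = 20
    frame_ms: float = 50.0
    target_EDV_ml: float = 150.0
    target_EF_pct: float = 60.0
    wall_thickness_mm: float = 10.0
    rv_scale: float = 1.0
    contrast_mode: Literal["bssfp_like", "gre_like"] = "bssfp_like"
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if not 2 <= self.n_phases <= 30:
            raise ValueError("n_phases must be in [2, 30]")
        if not 0 < self.target_EF_pct < 100:
            raise ValueError("target_EF_pct must be in (0, 100)")
        if self.target_EDV_ml <= 0:
            raise ValueError("target_EDV_ml must be positive")
        if self.wall_thickness_mm <= 0 or self.rv_scale <= 0:
            raise ValueError("wall_thickness_mm and rv_scale must be positive")


@dataclass
class PhantomTruth:
    labels: LabelMap4D
    lvb_volume_ml: np.ndarray   # closed form, per phase
    lvm_volume_ml: np.ndarray   # closed form (constant by construction), per phase
    rvb_volume_ml: np.ndarray   # voxel counts (crescent has no simple closed form)
    ed_phase: int
    es_phase: int


@dataclass
class KeySliceAnnotation:
    """Sparse set of fully labelled short-axis slices for one cardiac phase."""

    phase: int
    slice_axis: int                      # axis of the SAX stack (z = 2 for phantoms)
    slice_indices: list[int]
    slices: dict[int, np.ndarray] = field(default_factory=dict)  # index -> 2D uint8

    def to_sparse_volume(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Key labels embedded in an otherwise all-zero volume."""
        vol = np.zeros(grid_shape, dtype=np.uint8)
        for idx, arr in self.slices.items():
            sl = [slice(None)] * 3
            sl[self.slice_axis] = idx
            vol[tuple(sl)] = arr
        return vol


def _es_phase_index(n_phases: int) -> int:
    return max(1, round(0.4 * n_phases))


def contraction_profile(params: PhantomParams) -> np.ndarray:
    """Fractional systolic contraction s(p) in [0, 1]; 0 at ED (p=0), 1 at ES.

    Raised cosine from ED to ES, then raised-cosine relaxation back towards the
    (cyclic) next ED, giving smooth motion with a single volume minimum.
    """
    n = params.n_phases
    p_es = _es_phase_index(n)
    phases = np.arange(n)
    s = np.where(
        phases <= p_es,
        0.5 * (1.0 - np.cos(np.pi * phases / p_es)),
        0.5 * (1.0 - np.cos(np.pi * (n - phases) / (n - p_es))),
    )
    return s


def _truncated_factor(f: float) -> float:
    # Volume of {x^2/a^2+y^2/b^2+z^2/c^2 <= 1, z <= f*c} is pi*a*b*c * (2/3 + f - f^3/3)
    return 2.0 / 3.0 + f - f**3 / 3.0


@dataclass
class _Geometry:
    """Derived ED geometry in world mm (world origin = grid centre)."""

    a_endo: float
    c_endo: float
    wall: float
    lv_center: np.ndarray
    rv_center: np.ndarray
    rv_axes: np.ndarray
    shell_volume_mm3: float

    @property
    def a_epi(self) -> float:
        return self.a_endo + self.wall

    @property
    def c_epi(self) -> float:
        return self.c_endo + self.wall


def derive_geometry(params: PhantomParams) -> _Geometry:
    edv_mm3 = params.target_EDV_ml * 1000.0
    T = _truncated_factor(_BASAL_FRACTION)
    a = (edv_mm3 / (math.pi * _ELONGATION * T)) ** (1.0 / 3.0)
    c = _ELONGATION * a
    wall = params.wall_thickness_mm
    A0, C0 = a + wall, c + wall

    # Epicardial truncated volume at ED with the basal plane at z0 = f*c (endo frame).
    g0 = _BASAL_FRACTION * c / C0
    v_epi_ed = math.pi * A0 * A0 * C0 * _truncated_factor(g0)
    shell = v_epi_ed - edv_mm3

    # Place the LV so that LV + lateral RV crescent sit symmetrically in x,
    # and the apex-to-base span symmetrically in z.
    rv_axes = np.array([1.10 * A0, 0.95 * A0, 0.95 * C0]) * params.rv_scale
    rv_dx = -0.60 * A0 * params.rv_scale
    x_lo, x_hi = rv_dx - rv_axes[0], A0
    cx = -(x_lo + x_hi) / 2.0
    z_lo, z_hi = -C0, _BASAL_FRACTION * c
    cz = -(z_lo + z_hi) / 2.0
    lv_center = np.array([cx, 0.0, cz])
    rv_center = lv_center + np.array([rv_dx, 0.0, 0.0])
    geom = _Geometry(a, c, wall, lv_center, rv_center, rv_axes, shell)

    half_fov = (np.asarray(params.grid_shape, dtype=float) - 1) / 2.0 * params.spacing_mm
    margin = _MARGIN_VOX * params.spacing_mm
    extents = np.array(
        [
            max(abs(cx + x_lo), abs(cx + x_hi)),
            max(A0, rv_axes[1]),
            max(abs(cz + z_lo), abs(cz + z_hi)),
        ]
    )
    for ax, (ext, half) in enumerate(zip(extents, half_fov)):
        if ext + margin > half:
            raise GeometryError(
                f"heart extent {ext:.1f} mm + {_MARGIN_VOX}-voxel margin exceeds the "
                f"{half:.1f} mm half-field along axis {'xyz'[ax]}"
            )
    return geom


def analytic_lv_volume(params: PhantomParams, phase: int) -> float:
    """Closed-form LV blood-pool volume (mL) used by the generator at ``phase``."""
    if not 0 <= phase < params.n_phases:
        raise IndexError(f"phase {phase} out of range [0, {params.n_phases})")
    s = contraction_profile(params)[phase]
    return params.target_EDV_ml * (1.0 - s * params.target_EF_pct / 100.0)


def _solve_epi_scale(geom: _Geometry, v_endo_mm3: float, z0: float) -> float:
    """Epicardial scale factor keeping the closed-form shell volume at its ED value."""
    A0, C0 = geom.a_epi, geom.c_epi
    target = geom.shell_volume_mm3 + v_endo_mm3

    def shell_gap(mu: float) -> float:
        g = min(z0 / (C0 * mu), 1.0)
        return math.pi * A0 * A0 * C0 * mu**3 * _truncated_factor(g) - target

    return brentq(shell_gap, 0.3, 1.5, xtol=1e-12)


def _epi_threshold_for_count(q_pool: np.ndarray, target: int, mu_analytic: float) -> float:
    """Squared epicardial scale whose discrete shell count equals ``target``.

    The epicardium is the level set q <= mu^2 of the fixed quadratic form q, so
    conserving the voxelised myocardial count exactly reduces to choosing mu^2
    between two order statistics of q over the eligible (non-endocardial,
    sub-basal) voxels.  Falls back to the closed-form scale when the pool is
    too small.
    """
    if target >= q_pool.size or target < 1:
        return mu_analytic**2
    part = np.partition(q_pool, [target - 1, target])
    return 0.5 * (part[target - 1] + part[target])


_CONTRASTS = {
    "bssfp_like": {"blood": 1.00, "myo": 0.50, "bg": 0.15},
    "gre_like": {"blood": 1.00, "myo": 0.30, "bg": 0.22},
}


def generate_phantom(params: PhantomParams) -> tuple[Cine4D, PhantomTruth]:
    """Generate a seeded 4D phantom and its ground truth.

    Same parameters and seed give bit-identical images, labels and truth.
    """
    geom = derive_geometry(params)
    spacing = np.full(3, params.spacing_mm)
    affine = centered_affine(params.grid_shape, spacing)
    idx = np.indices(params.grid_shape, dtype=np.float64)
    world = [idx[k] * spacing[k] + affine[k, 3] for k in range(3)]

    s_profile = contraction_profile(params)
    n = params.n_phases
    voxvol_ml = float(np.prod(spacing)) / 1000.0

    labels = np.zeros((*params.grid_shape, n), dtype=np.uint8)
    lvb_ml = np.empty(n)
    lvm_ml = np.empty(n)
    rvb_ml = np.empty(n)

    cx, cy, cz = geom.lv_center
    dx2 = (world[0] - cx) ** 2
    dy2 = (world[1] - cy) ** 2
    dz = world[2] - cz
    rx, ry, rz = geom.rv_axes
    rdx2 = ((world[0] - geom.rv_center[0]) / rx) ** 2
    rdy2 = ((world[1] - geom.rv_center[1]) / ry) ** 2
    rdz = world[2] - geom.rv_center[2]
    septal_side = world[0] < cx
    # Quadratic form of the ED epicardial ellipsoid: epi at scale mu is q <= mu^2.
    q_epi = dx2 / geom.a_epi**2 + dy2 / geom.a_epi**2 + (dz / geom.c_epi) ** 2
    shell_target: int | None = None

    for p in range(n):
        v_endo_ml = params.target_EDV_ml * (1.0 - s_profile[p] * params.target_EF_pct / 100.0)
        lam = (v_endo_ml / params.target_EDV_ml) ** (1.0 / 3.0)
        a_p, c_p = geom.a_endo * lam, geom.c_endo * lam
        z0 = _BASAL_FRACTION * c_p
        mu = _solve_epi_scale(geom, v_endo_ml * 1000.0, z0)
        rho = lam  # RV contracts in phase with the LV
        below_base = dz <= z0

        endo = (dx2 / a_p**2 + dy2 / a_p**2 + (dz / c_p) ** 2 <= 1.0) & below_base
        # Conserve the *voxelised* myocardial volume exactly: choose the
        # epicardial level set whose discrete shell count matches ED's.
        pool = below_base & ~endo
        if shell_target is None:  # phase 0 is ED by construction
            epi = (q_epi <= mu * mu) & below_base
            shell_target = int(np.count_nonzero(epi & ~endo))
        else:
            musq = _epi_threshold_for_count(q_epi[pool], shell_target, mu)
            epi = (q_epi <= musq) & below_base
        rv = (rdx2 / rho**2 + rdy2 / rho**2 + (rdz / (rz * rho)) ** 2 <= 1.0)
        crescent = rv & ~epi & septal_side & below_base

        lab = np.zeros(params.grid_shape, dtype=np.uint8)
        lab[crescent] = RVB
        lab[epi] = LVM
        lab[endo] = LVB
        labels[..., p] = lab

        lvb_ml[p] = v_endo_ml
        lvm_ml[p] = geom.shell_volume_mm3 / 1000.0
        rvb_ml[p] = np.count_nonzero(crescent) * voxvol_ml

    intens = _CONTRASTS[params.contrast_mode]
    lut = np.array([intens["bg"], intens["blood"], intens["myo"], intens["blood"]], dtype=np.float32)
    rng = np.random.default_rng(params.seed)
    images = np.empty((*params.grid_shape, n), dtype=np.float32)
    for p in range(n):
        clean = lut[labels[..., p]]
        clean = ndimage.gaussian_filter(clean, sigma=0.7).astype(np.float32)
        if params.noise_sigma > 0:
            clean = clean + rng.normal(
                0.0, params.noise_sigma * intens["myo"], size=clean.shape
            ).astype(np.float32)
        images[..., p] = clean

    cine = Cine4D(images, spacing, affine, params.frame_ms)
    label_map = LabelMap4D(labels, spacing, affine, params.frame_ms)
    truth = PhantomTruth(
        labels=label_map,
        lvb_volume_ml=lvb_ml,
        lvm_volume_ml=lvm_ml,
        rvb_volume_ml=rvb_ml,
        ed_phase=int(np.argmax(lvb_ml)),
        es_phase=int(np.argmin(lvb_ml)),
    )
    return cine, truth


def simulate_key_slice_annotations(
    truth: LabelMap4D,
    phase: int,
    step: int = 5,
    jitter_vox: float = 0.0,
    seed: int = 0,
) -> KeySliceAnnotation:
    """Emulate sparse expert key-slice contours at fixed spatial steps.

    The most basal and most apical foreground slices are always annotated, plus
    every ``step``-th slice between them.  ``jitter_vox`` > 0 applies a seeded
    morphological perturbation (per-structure random dilation or erosion by at
    most ``jitter_vox`` voxels) emulating inter-observer contour variability;
    0 returns the exact truth slices.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    vol = truth.voxels[..., phase]
    fg = np.flatnonzero(vol.any(axis=(0, 1)))
    if fg.size == 0:
        raise ValueError(f"phase {phase} contains no foreground labels")
    lo, hi = int(fg[0]), int(fg[-1])
    indices = sorted(set(range(lo, hi + 1, step)) | {hi})

    rng = np.random.default_rng(seed)
    max_r = int(math.floor(jitter_vox))
    struct = ndimage.generate_binary_structure(2, 1)
    slices: dict[int, np.ndarray] = {}
    for z in indices:
        sl = vol[:, :, z]
        if jitter_vox > 0:
            out = np.zeros_like(sl)
            # recompose lowest-priority first so LVB > LVM > RVB on overlap
            for code in (RVB, LVM, LVB):
                mask = sl == code
                r = int(rng.integers(0, max_r + 1))
                grow = bool(rng.integers(0, 2))
                if r > 0 and mask.any():
                    op = ndimage.binary_dilation if grow else ndimage.binary_erosion
                    mask = op(mask, structure=struct, iterations=r)
                out[mask] = code
            sl = out
        slices[z] = sl.astype(np.uint8).copy()
    return KeySliceAnnotation(phase=phase, slice_axis=2, slice_indices=indices, slices=slices)
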