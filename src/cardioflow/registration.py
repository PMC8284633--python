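"""Myocardial velocimetry by demons deformable image registration.

Consecutive synchronized frames are registered with the classic intensity
demons algorithm (Gaussian regularization of the displacement field), run
coarse-to-fine over a 3-level pyramid. Each frame-to-frame displacement,
divided by the frame interval, gives a per-voxel myocardial velocity in
um/s; the per-frame maps are smoothed with a circular moving average over
the cardiac cycle, and spatial velocity gradients quantify local
deformation rates. A kymograph-based estimator of the wall deformation rate
is provided as an independent 1-D cross-check of the vector field.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datatypes import DisplacementField, RegistrationError, VectorField4D, Volume4D

__all__ = [
    "preprocess_volume",
    "demons_register",
    "displacement_to_velocity",
    "register_cycle",
    "smooth_temporal",
    "velocity_gradient",
    "speed_heatmap",
    "kymograph_deformation_rate",
]

ISO_SPACING_UM = 2.0


def preprocess_volume(
    v: Volume4D, intensity_threshold: Optional[float] = None
) -> Volume4D:
    """Resample to isotropic 2 um and zero out the background.

    Linear interpolation; the background threshold defaults to Otsu's value
    computed on the whole series. Voxels below threshold are set to 0.
    """
    if any(s <= 0 for s in v.spacing_um):
        raise ValueError("voxel spacing must be positive")
    factors = tuple(s / ISO_SPACING_UM for s in v.spacing_um)
    if np.allclose(factors, 1.0):
        data = np.asarray(v.data, dtype=np.float32).copy()
    else:
        data = np.stack(
            [ndimage.zoom(frame, factors, order=1) for frame in v.data]
        ).astype(np.float32)
    if intensity_threshold is None:
        finite = data[np.isfinite(data)]
        if finite.size and finite.max() > finite.min():
            intensity_threshold = float(threshold_otsu(finite))
        else:
            intensity_threshold = 0.0
    data[data < intensity_threshold] = 0.0
    return Volume4D(
        data=data,
        spacing_um=(ISO_SPACING_UM,) * 3,
        frame_interval_s=v.frame_interval_s,
        phase_origin=v.phase_origin,
    )


def _to_sitk(arr: np.ndarray, spacing_um: Sequence[float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing_um[::-1]))  # sitk is (x, y, z)
    return img


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, sigma=[factor / 2.0 * s for s in img.GetSpacing()]
    )
    return sitk.Shrink(smoothed, [factor] * img.GetDimension())


def demons_register(
    reference: np.ndarray,
    moving: np.ndarray,
    spacing_um: Sequence[float] = (ISO_SPACING_UM,) * 3,
    iterations: Sequence[int] = (100, 50, 25),
    smoothing_sigma: float = 1.5,
    source_frame: int = 0,
    target_frame: int = 1,
) -> DisplacementField:
    """Classic (Thirion) demons over a coarse-to-fine pyramid.

    The pyramid has one level per entry of ``iterations`` (downsampling
    factor 2 per level, coarsest first with the largest iteration count);
    the displacement field is Gaussian-regularized with ``smoothing_sigma``
    (voxels) at every iteration. The returned field maps reference voxel
    positions to their moving-frame positions, in micrometres.
    """
    reference = np.asarray(reference)
    moving = np.asarray(moving)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving volumes must share shape")
    fixed_img = _to_sitk(reference, spacing_um)
    moving_img = _to_sitk(moving, spacing_um)

    n_levels = len(iterations)
    field: Optional[sitk.Image] = None
    for level, n_iter in enumerate(iterations):
        factor = 2 ** (n_levels - 1 - level)
        f = _shrink(fixed_img, factor)
        m = _shrink(moving_img, factor)
        demons = sitk.DemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        demons.SetSmoothDisplacementField(True)
        # ITK expects the smoothing standard deviation in physical units;
        # smoothing_sigma is specified in voxels of the current level
        demons.SetStandardDeviations(
            [float(smoothing_sigma) * s for s in f.GetSpacing()]
        )
        if field is None:
            field = demons.Execute(f, m)
        else:
            field = demons.Execute(
                f, m, sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear)
            )
        arr = sitk.GetArrayViewFromImage(field)
        if not np.all(np.isfinite(arr)):
            raise RegistrationError(
                f"non-finite demons update at pyramid level {level} "
                f"({n_iter} iterations)"
            )

    vectors = sitk.GetArrayFromImage(field)[..., ::-1]  # (z,y,x,3) -> zyx components
    return DisplacementField(
        vectors_um=np.ascontiguousarray(vectors, dtype=float),
        spacing_um=tuple(float(s) for s in spacing_um),
        source_frame=source_frame,
        target_frame=target_frame,
    )


def displacement_to_velocity(
    fields: Sequence[DisplacementField],
    frame_interval_s: float,
    mask: Optional[np.ndarray] = None,
) -> VectorField4D:
    """Convert per-frame displacement fields to a masked velocity series.

    ``velocity = displacement / frame_interval`` in um/s; the fields are
    expected to cover consecutive frame pairs over one full cycle (the last
    field wrapping last -> first so every frame has a velocity).
    """
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be positive")
    vel = np.stack([f.vectors_um for f in fields]) / frame_interval_s
    return VectorField4D(
        velocities=vel,
        mask=mask,
        spacing_um=fields[0].spacing_um,
        frame_interval_s=frame_interval_s,
    )


def register_cycle(
    v: Volume4D,
    iterations: Sequence[int] = (100, 50, 25),
    smoothing_sigma: float = 1.5,
    mask: Optional[np.ndarray] = None,
) -> tuple[list[DisplacementField], VectorField4D]:
    """Register every consecutive frame pair over one cycle (wrapping)."""
    n = v.n_frames
    fields = []
    for t in range(n):
        t_next = (t + 1) % n
        fields.append(
            demons_register(
                v.data[t], v.data[t_next], v.spacing_um,
                iterations=iterations, smoothing_sigma=smoothing_sigma,
                source_frame=t, target_frame=t_next,
            )
        )
    return fields, displacement_to_velocity(fields, v.frame_interval_s, mask)


def smooth_temporal(vf: VectorField4D, window: int = 7) -> VectorField4D:
    """Circular per-voxel moving average over the cardiac cycle.

    The window must be odd and no longer than the cycle; time wraps, so the
    per-voxel cycle mean is conserved exactly.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > vf.n_frames:
        raise ValueError("smoothing window exceeds the cycle length")
    if window == 1:
        smoothed = vf.velocities.copy()
    else:
        smoothed = ndimage.uniform_filter1d(
            vf.velocities, size=window, axis=0, mode="wrap"
        )
    return VectorField4D(
        velocities=smoothed,
        mask=vf.mask,
        spacing_um=vf.spacing_um,
        frame_interval_s=vf.frame_interval_s,
    )


def _masked_gradient_axis(
    comp: np.ndarray, mask: np.ndarray, spacing: float, axis: int
) -> np.ndarray:
    """Finite differences along one spatial axis, one-sided at mask boundaries."""

    def shifted(a, offset):
        out = np.zeros_like(a)
        src = [slice(None)] * a.ndim
        dst = [slice(None)] * a.ndim
        if offset > 0:
            src[axis] = slice(0, a.shape[axis] - offset)
            dst[axis] = slice(offset, None)
        else:
            src[axis] = slice(-offset, None)
            dst[axis] = slice(0, a.shape[axis] + offset)
        out[tuple(dst)] = a[tuple(src)]
        return out

    m = mask.astype(bool)
    has_minus = shifted(m, 1) & m         # in-mask neighbor at i-1
    has_plus = shifted(m, -1) & m         # in-mask neighbor at i+1

    f_plus = shifted(comp, -1)            # comp[i+1]
    f_minus = shifted(comp, 1)            # comp[i-1]

    grad = np.zeros_like(comp)
    central = has_plus & has_minus
    fwd = has_plus & ~has_minus
    bwd = has_minus & ~has_plus
    grad[central] = (f_plus[central] - f_minus[central]) / (2.0 * spacing)
    grad[fwd] = (f_plus[fwd] - comp[fwd]) / spacing
    grad[bwd] = (comp[bwd] - f_minus[bwd]) / spacing
    return grad


def velocity_gradient(vf: VectorField4D) -> np.ndarray:
    """Spatial gradients of each velocity component (units 1/s).

    Returns an array of shape ``(t, z, y, x, 3, 3)`` where the last two axes
    index (velocity component, spatial axis), both in (z, y, x) order.
    Central differences in the mask interior, one-sided at mask boundaries,
    zero outside the mask (and everywhere for voxels with no in-mask
    neighbor along the axis).
    """
    mask = vf.mask if vf.mask is not None else np.ones(vf.velocities.shape[1:4], bool)
    t_n = vf.n_frames
    out = np.zeros(vf.velocities.shape + (3,))
    for t in range(t_n):
        for comp in range(3):
            for axis in range(3):
                out[t, ..., comp, axis] = _masked_gradient_axis(
                    vf.velocities[t, ..., comp], mask, vf.spacing_um[axis], axis
                )
    out *= mask[None, ..., None, None]
    return out


def speed_heatmap(vf: VectorField4D) -> np.ndarray:
    """Voxel-wise velocity magnitude, shape ``(t, z, y, x)`` in um/s."""
    return np.linalg.norm(vf.velocities, axis=-1)


def _boundary_crossings(profile: np.ndarray, threshold: float) -> tuple[float, float]:
    """Sub-sample positions of the first and last upward/downward threshold
    crossings of an intensity profile, in sample units."""
    above = profile >= threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("no samples above threshold")
    first, last = int(idx[0]), int(idx[-1])
    lo = float(first)
    if first > 0:
        denom = profile[first] - profile[first - 1]
        if denom > 0:
            lo = first - 1 + (threshold - profile[first - 1]) / denom
    hi = float(last)
    if last < profile.size - 1:
        denom = profile[last] - profile[last + 1]
        if denom > 0:
            hi = last + (profile[last] - threshold) / denom
    return lo, hi


def kymograph_deformation_rate(
    v4d: Volume4D,
    line_start_um: Sequence[float],
    line_end_um: Sequence[float],
    vf: Optional[VectorField4D] = None,
    n_samples: int = 200,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Wall deformation rate from a kymograph, cross-checked on the vector field.

    Intensity is sampled along the fixed line per frame (the kymograph); the
    two wall boundaries are located per frame by threshold crossing (default
    threshold: half the kymograph maximum) and their separation
    differentiated in time to give the kymograph deformation rate (um/s).
    If a velocity field is given, an independent rate is computed as the
    difference of the two boundary-point velocities projected on the line.

    Returns ``(kymograph, boundary_distance_um, rate_kymo_um_s, rate_field_um_s)``.
    1-D sampling is angle-dependent: a line tilted by ``alpha`` from the wall
    motion direction inflates the kymograph rate by ``1 / cos(alpha)``.
    """
    start = np.asarray(line_start_um, dtype=float)
    end = np.asarray(line_end_um, dtype=float)
    direction = end - start
    length = float(np.linalg.norm(direction))
    if length == 0:
        raise ValueError("line endpoints coincide")
    unit = direction / length
    frac = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + frac[:, None] * direction[None, :]
    coords_vox = (pts / np.asarray(v4d.spacing_um)).T      # (3, n_samples)
    ds = length / (n_samples - 1)

    n_frames = v4d.n_frames
    kymo = np.stack(
        [ndimage.map_coordinates(np.asarray(v4d.data[t], dtype=float),
                                 coords_vox, order=1, mode="nearest")
         for t in range(n_frames)]
    )
    if threshold is None:
        threshold = 0.5 * float(kymo.max())

    distances = np.empty(n_frames)
    bounds = np.empty((n_frames, 2))
    for t in range(n_frames):
        try:
            lo, hi = _boundary_crossings(kymo[t], threshold)
        except ValueError as err:
            raise ValueError(f"frame {t}: fewer than two boundary crossings") from err
        if hi <= lo:
            raise ValueError(f"frame {t}: fewer than two boundary crossings")
        bounds[t] = (lo, hi)
        distances[t] = (hi - lo) * ds

    dt = v4d.frame_interval_s
    rate_kymo = np.gradient(distances, dt)

    rate_field = None
    if vf is not None:
        rate_field = np.empty(n_frames)
        spacing = np.asarray(vf.spacing_um)
        for t in range(n_frames):
            p_lo = start + bounds[t, 0] * ds * unit
            p_hi = start + bounds[t, 1] * ds * unit
            v_t = vf.velocities[min(t, vf.n_frames - 1)]
            v_lo = np.array([
                ndimage.map_coordinates(v_t[..., c], (p_lo / spacing)[:, None],
                                        order=1, mode="nearest")[0]
                for c in range(3)
            ])
            v_hi = np.array([
                ndimage.map_coordinates(v_t[..., c], (p_hi / spacing)[:, None],
                                        order=1, mode="nearest")[0]
                for c in range(3)
            ])
            rate_field[t] = float((v_hi - v_lo) @ unit)
    return kymo, distances, rate_kymo, rate_field
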