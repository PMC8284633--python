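"""Flow-centerline geometry and segmental myocardial statistics.

The pooled tracer positions summarize the inflow -> outflow geometry of the
ventricle. A principal plane is found by PCA of the 3-D positions; each
point gets an angle theta about a pre-defined center point after projection
onto that plane; and each spatial coordinate is fitted as a fourth-order
polynomial in theta by ordinary least squares, giving a smooth centerline
oriented from the atrioventricular canal (AVC) to the outflow tract (OFT).
Tangents along the curve define the local flow direction; projecting tracer
velocities on them gives the signed collective flow profile (positive
toward the OFT), whose strong negative excursions mark flow reversal across
the valves. The curve also induces a tube coordinate system (arc length +
two parallel-transported lateral offsets), used to partition the ventricle
into proximal/distal x left/right segments and to compute segmental and
relative myocardial velocities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Centerline, DegenerateGeometryError, TrackSet, VectorField4D

__all__ = [
    "fit_principal_plane",
    "compute_theta",
    "fit_centerline",
    "project_flow_velocity",
    "detect_reversal",
    "to_centerline_coords",
    "from_centerline_coords",
    "centerline_mask",
    "partition_segments",
    "segment_statistics",
    "relative_velocity_by_phase",
    "default_phase_windows",
]


def fit_principal_plane(
    points_um: np.ndarray, rank_tolerance: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal plane of a 3-D point cloud by covariance eigen-decomposition.

    Returns ``(centroid, basis, normal)`` where ``basis`` holds the two
    leading eigenvectors (rows) spanning the plane through the centroid.
    Eigenvector signs are canonicalized (largest-magnitude component
    positive) and the normal is their cross product.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    (near-)collinear cloud.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= rank_tolerance * max(evals[0], 1e-300):
        raise DegenerateGeometryError("points are (near-)collinear; no unique plane")
    basis = evecs[:, :2].T
    for i in range(2):
        j = int(np.argmax(np.abs(basis[i])))
        if basis[i, j] < 0:
            basis[i] = -basis[i]
    normal = np.cross(basis[0], basis[1])
    return centroid, basis, normal / np.linalg.norm(normal)


def compute_theta(
    points_um: np.ndarray,
    center_um: np.ndarray,
    plane_basis: np.ndarray,
) -> np.ndarray:
    """Angle of each point about the center after projection onto the plane.

    Raw angles ``atan2(v, u)`` (u, v: in-plane coordinates) are wrapped onto
    a continuous branch: the 2 pi branch cut is placed inside the largest
    angular gap of the cloud, so a cloud spanning the -pi/pi seam stays
    contiguous.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    d = pts - np.asarray(center_um, dtype=float)
    u = d @ plane_basis[0]
    v = d @ plane_basis[1]
    r = np.hypot(u, v)
    if np.any(r < 1e-12):
        raise ValueError("a point coincides with the center; theta undefined")
    theta = np.arctan2(v, u)
    if theta.size > 1:
        order = np.argsort(theta)
        sorted_t = theta[order]
        gaps = np.diff(np.concatenate([sorted_t, [sorted_t[0] + 2 * np.pi]]))
        cut = sorted_t[int(np.argmax(gaps))] + gaps.max() / 2.0
        theta = ((theta - cut) % (2 * np.pi)) + cut - 2 * np.pi
    return theta


def fit_centerline(
    points_um: np.ndarray,
    center_um: Optional[np.ndarray] = None,
    plane: Optional[tuple[np.ndarray, np.ndarray]] = None,
    order: int = 4,
    n_samples: int = 200,
    av_end: str = "min",
    av_point_um: Optional[np.ndarray] = None,
    min_span_rad: float = np.pi / 4,
    theta: Optional[np.ndarray] = None,
) -> Centerline:
    """Fit the flow centerline as per-coordinate polynomials in theta.

    Each world coordinate is regressed on ``[1, theta, ..., theta^order]``
    by ordinary least squares; the curve is densely sampled, tangents come
    from the analytic derivative, and the orientation is fixed so the curve
    runs AV canal -> OFT. The AV end is ``av_end`` ("min"/"max" theta) or,
    if ``av_point_um`` is given, the theta end whose curve endpoint lies
    nearer that landmark. The angles default to the in-plane angles about
    the center (:func:`compute_theta`); a caller-supplied ``theta`` per
    point overrides them (e.g. a known generating parameterization).

    Raises :class:`DegenerateGeometryError` if fewer than ``3 * (order + 1)``
    points are given or the theta span is below ``min_span_rad`` (an
    ill-conditioned design).
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] < 3 * (order + 1):
        raise DegenerateGeometryError(
            f"need at least {3 * (order + 1)} points for an order-{order} fit"
        )
    if plane is None:
        _, basis, normal = fit_principal_plane(pts)
    else:
        basis = np.asarray(plane[0], dtype=float)
        normal = np.asarray(plane[1], dtype=float)
    center = (
        pts.mean(axis=0) if center_um is None else np.asarray(center_um, dtype=float)
    )
    if theta is None:
        theta = compute_theta(pts, center, basis)
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (pts.shape[0],):
            raise ValueError("theta must give one angle per point")
    span = float(theta.max() - theta.min())
    if span < min_span_rad:
        raise DegenerateGeometryError(
            f"theta span {span:.3f} rad below {min_span_rad:.3f}; fit ill-conditioned"
        )

    design = theta[:, None] ** np.arange(order + 1)[None, :]
    coeffs, _, rank, _ = np.linalg.lstsq(design, pts, rcond=None)
    if rank < order + 1:
        raise DegenerateGeometryError("design matrix is rank-deficient")
    coeffs = coeffs.T                     # (3, order+1), ascending powers
    resid = pts - design @ coeffs.T
    residuals = np.sqrt(np.mean(resid ** 2, axis=0))

    # evaluate within the bulk angular support: the extreme angles are the
    # noisiest observations and extrapolating to them overhangs the data
    lo, hi = np.quantile(theta, [0.005, 0.995])
    theta_dense = np.linspace(lo, hi, n_samples)
    powers = theta_dense[:, None] ** np.arange(order + 1)[None, :]
    samples = powers @ coeffs.T
    dcoeffs = coeffs[:, 1:] * np.arange(1, order + 1)[None, :]
    dpowers = theta_dense[:, None] ** np.arange(order)[None, :]
    derivs = dpowers @ dcoeffs.T
    norms = np.linalg.norm(derivs, axis=1, keepdims=True)
    tangents = derivs / np.maximum(norms, 1e-300)

    if av_point_um is not None:
        av_point = np.asarray(av_point_um, dtype=float)
        d_min = np.linalg.norm(samples[0] - av_point)
        d_max = np.linalg.norm(samples[-1] - av_point)
        av_end = "min" if d_min <= d_max else "max"
    if av_end not in ("min", "max"):
        raise ValueError("av_end must be 'min' or 'max'")
    if av_end == "max":
        samples = samples[::-1].copy()
        tangents = -tangents[::-1].copy()

    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    return Centerline(
        center_um=center,
        plane_basis=basis,
        plane_normal=normal,
        coefficients=coeffs,
        theta_domain=(float(theta.min()), float(theta.max())),
        samples_um=samples,
        arc_length_um=arc,
        tangents=tangents,
        residuals_um=residuals,
        av_end=av_end,
    )


def _transported_frames(c: Centerline) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported lateral frame axes (e1, e2) along the curve.

    e1 starts as the plane normal projected orthogonal to the first tangent
    and is transported by successive re-orthogonalization, avoiding frame
    flips; e2 = tangent x e1 completes the right-handed triad.
    """
    if c._frame_e1 is not None:
        return c._frame_e1, c._frame_e2
    t = c.tangents
    n = t.shape[0]
    e1 = np.empty_like(t)
    first = c.plane_normal - (c.plane_normal @ t[0]) * t[0]
    if np.linalg.norm(first) < 1e-8:
        first = np.array([1.0, 0.0, 0.0]) - t[0, 0] * t[0]
    e1[0] = first / np.linalg.norm(first)
    for i in range(1, n):
        v = e1[i - 1] - (e1[i - 1] @ t[i]) * t[i]
        nv = np.linalg.norm(v)
        e1[i] = v / nv if nv > 1e-12 else e1[i - 1]
    e2 = np.cross(t, e1)
    c._frame_e1, c._frame_e2 = e1, e2
    return e1, e2


def project_flow_velocity(
    tracks: TrackSet, centerline: Centerline
) -> pd.Series:
    """Mean signed flow velocity per frame (um/s), positive toward the OFT.

    Each per-frame track velocity is projected on the unit tangent at the
    nearest centerline sample; the signed projections are averaged over all
    tracked cells present in the frame. Frames with no tracked cell are NaN
    (flagged missing, not zero).
    """
    frames, projections = [], []
    for tr in tracks:
        if tr.velocities_um_s is None:
            raise ValueError("tracks carry no velocities; run track_velocities first")
        valid = np.all(np.isfinite(tr.velocities_um_s), axis=1)
        if not np.any(valid):
            continue
        idx = centerline.nearest_sample(tr.positions_um[valid])
        proj = np.einsum("ij,ij->i", tr.velocities_um_s[valid], centerline.tangents[idx])
        frames.extend(tr.frames[valid].tolist())
        projections.extend(proj.tolist())
    if not frames:
        return pd.Series(dtype=float, name="flow_velocity_um_s")
    df = pd.DataFrame({"frame": frames, "proj": projections})
    out = df.groupby("frame")["proj"].mean()
    full = pd.Series(
        np.nan, index=pd.RangeIndex(int(out.index.max()) + 1), name="flow_velocity_um_s"
    )
    full.loc[out.index] = out.to_numpy()
    return full


def detect_reversal(
    series, magnitude_threshold: float = 1000.0
) -> list[tuple[int, int]]:
    """Maximal frame intervals of flow reversal.

    Reversal frames have projected velocity negative with magnitude above
    the threshold (the |V| > 1000 um/s regurgitation criterion); returns
    inclusive ``(start, end)`` frame intervals.
    """
    v = np.asarray(series, dtype=float)
    mask = np.zeros(v.size, dtype=bool)
    finite = np.isfinite(v)
    mask[finite] = v[finite] < -abs(magnitude_threshold)
    intervals = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, v.size - 1))
    return intervals


def _frame_at(centerline: Centerline, s: np.ndarray):
    """Interpolated curve position and transported frame at arc lengths ``s``.

    Linear interpolation between dense samples (with linear extension beyond
    the curve ends); the tangent and lateral axes are re-orthonormalized
    after interpolation.
    """
    e1s, e2s = _transported_frames(centerline)
    arc = centerline.arc_length_um
    s = np.atleast_1d(np.asarray(s, dtype=float))
    i = np.clip(np.searchsorted(arc, s) - 1, 0, arc.size - 2)
    frac = ((s - arc[i]) / (arc[i + 1] - arc[i]))[:, None]
    pos = centerline.samples_um[i] + frac * (
        centerline.samples_um[i + 1] - centerline.samples_um[i]
    )
    t = centerline.tangents[i] + np.clip(frac, 0.0, 1.0) * (
        centerline.tangents[i + 1] - centerline.tangents[i]
    )
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    e1 = e1s[i] + np.clip(frac, 0.0, 1.0) * (e1s[i + 1] - e1s[i])
    e1 -= np.einsum("ij,ij->i", e1, t)[:, None] * t
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(t, e1)
    return pos, t, e1, e2


def to_centerline_coords(
    points_um: np.ndarray, centerline: Centerline
) -> np.ndarray:
    """Map points to tube coordinates ``(arc_length, offset1, offset2)``.

    The arc length locates the foot of the point on the (interpolated)
    centerline — refined so the residual is orthogonal to the local tangent,
    and extending linearly beyond the curve ends — and the offsets are the
    residual components along the two parallel-transported lateral frame
    axes there.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    idx = centerline.nearest_sample(pts)
    d = pts - centerline.samples_um[idx]
    s = centerline.arc_length_um[idx] + np.einsum(
        "ij,ij->i", d, centerline.tangents[idx]
    )
    for _ in range(3):
        pos, t, e1, e2 = _frame_at(centerline, s)
        s = s + np.einsum("ij,ij->i", pts - pos, t)
    pos, t, e1, e2 = _frame_at(centerline, s)
    d = pts - pos
    return np.stack(
        [s, np.einsum("ij,ij->i", d, e1), np.einsum("ij,ij->i", d, e2)], axis=1
    )


def from_centerline_coords(
    coords: np.ndarray, centerline: Centerline
) -> np.ndarray:
    """Inverse of :func:`to_centerline_coords`."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    pos, _, e1, e2 = _frame_at(centerline, coords[:, 0])
    return pos + coords[:, 1:2] * e1 + coords[:, 2:3] * e2


def centerline_mask(
    shape_zyx: tuple[int, int, int],
    spacing_um: Sequence[float],
    centerline: Centerline,
    radius_um: float = 30.0,
) -> np.ndarray:
    """Ventricular region mask: voxels within ``radius_um`` of the centerline."""
    from scipy.spatial import cKDTree

    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape_zyx, spacing_um)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d, _ = cKDTree(centerline.samples_um).query(pts)
    return (d.reshape(shape_zyx) <= radius_um)


def partition_segments(
    mask: np.ndarray,
    spacing_um: Sequence[float],
    centerline: Centerline,
    n_segments: int = 4,
) -> np.ndarray:
    """Label ventricle voxels by centerline position and laterality.

    The arc length is split into ``n_segments / 2`` equal bins (proximal
    first: nearest the AV canal) and each bin into left/right by the sign of
    the voxel's offset along the lateral axis ``tangent x plane_normal``
    (handedness consistent along the curve). Labels are 1..n_segments with
    segment ``2 * bin + side + 1``; background stays 0. Requires an even
    ``n_segments``.
    """
    if n_segments < 2 or n_segments % 2 != 0:
        raise ValueError("n_segments must be even (left/right pairing)")
    mask = np.asarray(mask, dtype=bool)
    idx_mask = np.flatnonzero(mask.ravel())
    coords_vox = np.stack(np.unravel_index(idx_mask, mask.shape), axis=1)
    pts = coords_vox * np.asarray(spacing_um)[None, :]
    nearest = centerline.nearest_sample(pts)
    frac = centerline.arc_length_um[nearest] / max(centerline.total_length_um, 1e-300)
    n_bins = n_segments // 2
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    lateral = np.cross(centerline.tangents, centerline.plane_normal[None, :])
    lat_norm = lateral / np.maximum(
        np.linalg.norm(lateral, axis=1, keepdims=True), 1e-300
    )
    d = pts - centerline.samples_um[nearest]
    side = (np.einsum("ij,ij->i", d, lat_norm[nearest]) < 0).astype(int)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels.ravel()[idx_mask] = 2 * bins + side + 1
    return labels


def segment_statistics(
    vf: VectorField4D, labels: np.ndarray
) -> pd.DataFrame:
    """Per-frame, per-segment myocardial velocity statistics.

    For each segment: voxel count, unweighted mean velocity vector, the
    magnitude-weighted mean vector ``sum(|v| v) / sum(|v|)`` (the default
    reported segmental velocity), and the mean velocity magnitude. The
    global velocity is the mean magnitude over the whole labeled region, and
    the relative velocity is the segment's mean magnitude divided by it.
    Empty segments yield NaN statistics (flagged missing).
    """
    labels = np.asarray(labels)
    seg_ids = np.unique(labels[labels > 0])
    records = []
    for t in range(vf.n_frames):
        v = vf.velocities[t]
        mag = np.linalg.norm(v, axis=-1)
        region = labels > 0
        global_mag = float(mag[region].mean()) if region.any() else np.nan
        for s in seg_ids:
            sel = labels == s
            n_vox = int(sel.sum())
            if n_vox == 0:
                mean_vec = wmean = np.full(3, np.nan)
                mean_mag = np.nan
            else:
                vs = v[sel]
                ms = mag[sel]
                mean_vec = vs.mean(axis=0)
                wsum = ms.sum()
                wmean = (
                    (ms[:, None] * vs).sum(axis=0) / wsum
                    if wsum > 0 else np.zeros(3)
                )
                mean_mag = float(ms.mean())
            records.append({
                "frame": t, "segment": int(s), "n_vox": n_vox,
                "mean_vz": mean_vec[0], "mean_vy": mean_vec[1], "mean_vx": mean_vec[2],
                "wmean_vz": wmean[0], "wmean_vy": wmean[1], "wmean_vx": wmean[2],
                "mean_mag": mean_mag,
                "global_mag": global_mag,
                "rel_vel": mean_mag / global_mag if global_mag else np.nan,
            })
    return pd.DataFrame.from_records(records)


def default_phase_windows(flow_series: pd.Series) -> dict[str, tuple[int, int]]:
    """Split the cycle into two windows at the zero crossings of the flow.

    The window containing the global flow maximum (forward ejection) is
    labelled systole; the complementary window diastole. Falls back to
    splitting the cycle in half when the profile never changes sign.
    """
    v = np.asarray(flow_series, dtype=float)
    n = v.size
    finite = np.where(np.isfinite(v), v, 0.0)
    sign = finite >= 0
    crossings = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    if crossings.size < 2:
        half = n // 2
        return {"systole": (0, half - 1), "diastole": (half, n - 1)}
    peak = int(np.nanargmax(finite))
    after = crossings[crossings > peak]
    before = crossings[crossings <= peak]
    start = int(before[-1]) if before.size else 0
    end = int(after[0]) - 1 if after.size else n - 1
    return {"systole": (start, end), "diastole": ((end + 1) % n, (start - 1) % n)}


def relative_velocity_by_phase(
    stats: pd.DataFrame, windows: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Cycle-level relative velocity per segment within declared phase windows.

    For each named window (inclusive frame interval, possibly wrapping), the
    relative velocity of a segment is the window mean of its per-frame mean
    magnitude divided by the window mean of the global magnitude.
    """
    n_frames = int(stats["frame"].max()) + 1
    rows = []
    for name, (a, b) in windows.items():
        if a <= b:
            frames = np.arange(a, b + 1)
        else:                                      # wrapping interval
            frames = np.concatenate([np.arange(a, n_frames), np.arange(0, b + 1)])
        sub = stats[stats["frame"].isin(frames)]
        for s, grp in sub.groupby("segment"):
            seg_mean = grp["mean_mag"].mean()
            glob_mean = grp["global_mag"].mean()
            rows.append({
                "phase": name, "segment": int(s),
                "relative_velocity": seg_mean / glob_mean if glob_mean else np.nan,
            })
    return pd.DataFrame(rows)
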