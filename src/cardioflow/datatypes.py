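"""Core containers shared across the pipeline.

Conventions used throughout the package:

* image axes are ``(time, z, y, x)``, 0-based;
* positions and displacement/velocity vectors are expressed in micrometres
  in ``(z, y, x)`` component order;
* time is expressed either in frames (integer index into the cardiac cycle)
  or in seconds via ``frame_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class CardioflowError(Exception):
    """Base class for all package errors."""


class AperiodicSignalError(CardioflowError):
    """Raised when a sequence shows no usable cardiac periodicity."""


class IndistinguishablePhasesError(CardioflowError):
    """Raised when the circular distance profile is flat (no phase information)."""


class DegenerateGeometryError(CardioflowError):
    """Raised when a point cloud has no well-defined plane/curve."""


class RegistrationError(CardioflowError):
    """Raised when deformable registration fails to produce a finite field."""


class FileFormatError(CardioflowError):
    """Raised for malformed on-disk volumes/sidecars."""


class PipelineStageError(CardioflowError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class SliceScan:
    """Per-z-slice time sequences from a slice-scanned acquisition.

    Each z position holds an image time sequence acquired at a fixed frame
    rate; the cardiac phase at frame 0 differs (unknown) between slices.
    """

    z_positions_um: np.ndarray          # (Z,) strictly increasing
    sequences: list[np.ndarray]         # Z arrays of shape (T_i, Y, X)
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
        if self.z_positions_um.ndim != 1 or len(self.sequences) != self.z_positions_um.size:
            raise ValueError("one z position per sequence required")
        if self.z_positions_um.size > 1 and not np.all(np.diff(self.z_positions_um) > 0):
            raise ValueError("z positions must be strictly increasing")
        shapes = {seq.shape[1:] for seq in self.sequences}
        if len(shapes) > 1:
            raise ValueError(f"in-plane shapes differ between slices: {shapes}")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.sequences)


@dataclass
class Volume4D:
    """Phase-synchronized intensity series indexed ``(time, z, y, x)``."""

    data: np.ndarray                    # (T, Z, Y, X)
    spacing_um: tuple[float, float, float]  # (z, y, x)
    frame_interval_s: float
    phase_origin: int = 0               # frame index defining cardiac phase 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (t, z, y, x) data, got shape {self.data.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class SyncResult:
    """Result of retrospective gating: period, per-slice shifts, diagnostics."""

    period_frames: float                        # pooled real-valued estimate
    shifts: np.ndarray                          # (Z,) int, in [0, round(period))
    pair_distances: list[np.ndarray]            # per adjacent pair, distance profile over shifts
    per_slice_periods: np.ndarray               # (Z,) real-valued estimates
    confidences: np.ndarray                     # autocorrelation peak prominences
    phase_origin: int = 0

    @property
    def period_int(self) -> int:
        return int(round(self.period_frames))


@dataclass
class DisplacementField:
    """Dense displacement between a reference and a moving frame.

    ``vectors[z, y, x]`` maps the reference voxel's physical position to its
    position in the moving frame (the transformation T: (x,y,z)->(x',y',z')),
    in micrometres and ``(z, y, x)`` component order.
    """

    vectors_um: np.ndarray              # (Z, Y, X, 3)
    spacing_um: tuple[float, float, float]
    source_frame: int = 0
    target_frame: int = 1

    def __post_init__(self) -> None:
        self.vectors_um = np.asarray(self.vectors_um, dtype=float)
        if self.vectors_um.ndim != 4 or self.vectors_um.shape[-1] != 3:
            raise ValueError("displacement field must have shape (z, y, x, 3)")
        if not np.all(np.isfinite(self.vectors_um)):
            raise RegistrationError("displacement field contains non-finite values")


@dataclass
class VectorField4D:
    """Per-voxel 3-component velocity time series in um/s."""

    velocities: np.ndarray              # (T, Z, Y, X, 3), (z, y, x) components
    mask: Optional[np.ndarray]          # (Z, Y, X) bool or None
    spacing_um: tuple[float, float, float]
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 5 or self.velocities.shape[-1] != 3:
            raise ValueError("velocity field must have shape (t, z, y, x, 3)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.velocities.shape[1:4]:
                raise ValueError("mask shape must match the spatial grid")
            self.velocities = self.velocities * self.mask[None, ..., None]
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]


@dataclass
class Track:
    """One linked particle trajectory."""

    track_id: int
    frames: np.ndarray                  # (n,) strictly increasing ints
    positions_um: np.ndarray            # (n, 3) (z, y, x)
    velocities_um_s: Optional[np.ndarray] = None  # (n, 3); last row NaN

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")
        if self.positions_um.shape != (self.frames.size, 3):
            raise ValueError("positions must be (n_frames, 3)")

    @property
    def span(self) -> int:
        """Duration in frames, inclusive of both endpoints."""
        return int(self.frames[-1] - self.frames[0] + 1)


@dataclass
class TrackSet:
    """A collection of linked trajectories plus the linking parameters used."""

    tracks: list[Track]
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class Centerline:
    """Fitted flow centerline: plane, quartic coordinate polynomials, frames.

    Coordinates are parameterized by the in-plane angle theta about the
    center point; each of the three spatial coordinates is a polynomial in
    theta (coefficient rows in ascending powers). Dense samples run from the
    AV-canal end toward the outflow tract, with unit tangents oriented the
    same way and arc length increasing from the AV end.
    """

    center_um: np.ndarray               # (3,) the pre-defined center point
    plane_basis: np.ndarray             # (2, 3) orthonormal in-plane vectors
    plane_normal: np.ndarray            # (3,)
    coefficients: np.ndarray            # (3, order+1) ascending powers, (z, y, x) rows
    theta_domain: tuple[float, float]
    samples_um: np.ndarray              # (n_samples, 3) AV end first
    arc_length_um: np.ndarray           # (n_samples,) 0 at AV end, increasing
    tangents: np.ndarray                # (n_samples, 3) unit, AV -> OFT
    residuals_um: np.ndarray            # (3,) per-coordinate RMS fit residual
    av_end: str = "min"                 # which theta end is the AV canal

    _frame_e1: Optional[np.ndarray] = None   # parallel-transported frame axes
    _frame_e2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.center_um = np.asarray(self.center_um, dtype=float)
        self.plane_basis = np.asarray(self.plane_basis, dtype=float)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)
        if not np.allclose(self.plane_basis @ self.plane_basis.T, np.eye(2), atol=1e-8):
            raise ValueError("plane basis must be orthonormal")
        if self.arc_length_um.size > 1 and not np.all(np.diff(self.arc_length_um) > 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def total_length_um(self) -> float:
        return float(self.arc_length_um[-1])

    def evaluate(self, theta: np.ndarray) -> np.ndarray:
        """Evaluate the fitted curve at angles ``theta`` -> (n, 3) positions."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        powers = theta[:, None] ** np.arange(self.coefficients.shape[1])[None, :]
        return powers @ self.coefficients.T

    def nearest_sample(self, points_um: np.ndarray) -> np.ndarray:
        """Index of the nearest dense sample for each query point."""
        from scipy.spatial import cKDTree

        points_um = np.atleast_2d(points_um)
        _, idx = cKDTree(self.samples_um).query(points_um)
        return idx
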