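"""File I/O: TIFF volumes with JSON sidecars, CSV tables, JSON reports.

Every array written by the package is re-readable by the package's own
readers. Volumes are multi-page TIFFs accompanied by a ``<name>.json``
sidecar declaring the axes order, voxel spacing and frame interval, so no
silent transposes can occur.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    Centerline,
    FileFormatError,
    SliceScan,
    SyncResult,
    Track,
    TrackSet,
    VectorField4D,
    Volume4D,
)

__all__ = [
    "write_volume4d", "read_volume4d",
    "write_slice_scan", "read_slice_scan",
    "write_sync_report", "read_sync_report",
    "write_vector_field", "read_vector_field", "write_vector_field_vtk",
    "tracks_to_dataframe", "write_tracks", "read_tracks",
    "write_centerline", "read_centerline",
    "write_labels", "read_labels",
]

SIDECAR_KEYS = ("axes", "spacing_um", "frame_interval_s")


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".json")


def _load_sidecar(path: Union[str, Path]) -> dict:
    sp = _sidecar_path(path)
    if not sp.exists():
        raise FileFormatError(
            f"missing sidecar {sp}; required keys: {', '.join(SIDECAR_KEYS)}"
        )
    with open(sp) as fh:
        meta = json.load(fh)
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise FileFormatError(f"sidecar {sp} missing keys: {', '.join(missing)}")
    return meta


def write_volume4d(v: Volume4D, path: Union[str, Path]) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(v.data, dtype=np.float32))
    meta = {
        "axes": "TZYX",
        "shape": list(v.data.shape),
        "spacing_um": list(v.spacing_um),
        "frame_interval_s": v.frame_interval_s,
        "phase_origin": v.phase_origin,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_volume4d(path: Union[str, Path]) -> Volume4D:
    meta = _load_sidecar(path)
    if meta["axes"] != "TZYX":
        raise FileFormatError(f"unsupported axes order {meta['axes']!r}; need TZYX")
    data = tifffile.imread(path)
    shape = tuple(meta.get("shape", data.shape))
    if int(np.prod(data.shape)) != int(np.prod(shape)):
        raise FileFormatError(
            f"TIFF holds {data.shape} samples but sidecar declares shape {shape}"
        )
    data = data.reshape(shape)
    if data.ndim != 4:
        raise FileFormatError(f"expected 4-D TZYX data, got shape {data.shape}")
    return Volume4D(
        data=data,
        spacing_um=tuple(meta["spacing_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        phase_origin=int(meta.get("phase_origin", 0)),
    )


def write_slice_scan(scan: SliceScan, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, seq in enumerate(scan.sequences):
        tifffile.imwrite(directory / f"slice_{k:04d}.tif",
                         np.asarray(seq, dtype=np.float32))
    meta = {
        "z_positions_um": scan.z_positions_um.tolist(),
        "frame_rate_hz": scan.frame_rate_hz,
        "pixel_size_um": scan.pixel_size_um,
        "n_slices": scan.n_slices,
    }
    with open(directory / "scan.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_slice_scan(directory: Union[str, Path]) -> SliceScan:
    directory = Path(directory)
    meta_path = directory / "scan.json"
    if not meta_path.exists():
        raise FileFormatError(f"missing {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    sequences = [
        tifffile.imread(directory / f"slice_{k:04d}.tif")
        for k in range(int(meta["n_slices"]))
    ]
    return SliceScan(
        z_positions_um=np.asarray(meta["z_positions_um"]),
        sequences=sequences,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def write_sync_report(sync: SyncResult, path: Union[str, Path]) -> None:
    report = {
        "period_frames": sync.period_frames,
        "shifts": sync.shifts.tolist(),
        "per_slice_periods": sync.per_slice_periods.tolist(),
        "confidences": sync.confidences.tolist(),
        "phase_origin": sync.phase_origin,
        "pair_distance_profiles": [p.tolist() for p in sync.pair_distances],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def read_sync_report(path: Union[str, Path]) -> SyncResult:
    with open(path) as fh:
        r = json.load(fh)
    return SyncResult(
        period_frames=float(r["period_frames"]),
        shifts=np.asarray(r["shifts"], dtype=int),
        pair_distances=[np.asarray(p) for p in r["pair_distance_profiles"]],
        per_slice_periods=np.asarray(r["per_slice_periods"]),
        confidences=np.asarray(r["confidences"]),
        phase_origin=int(r.get("phase_origin", 0)),
    )


def write_vector_field(vf: VectorField4D, prefix: Union[str, Path]) -> None:
    """One TIFF per component (z, y, x) plus a JSON sidecar."""
    prefix = Path(prefix)
    for i, comp in enumerate("zyx"):
        tifffile.imwrite(
            Path(f"{prefix}_v{comp}.tif"),
            np.ascontiguousarray(vf.velocities[..., i], dtype=np.float32),
        )
    if vf.mask is not None:
        tifffile.imwrite(Path(f"{prefix}_mask.tif"),
                         vf.mask.astype(np.uint8), photometric="minisblack")
    meta = {
        "axes": "TZYX",
        "shape": list(vf.velocities.shape[:4]),
        "spacing_um": list(vf.spacing_um),
        "frame_interval_s": vf.frame_interval_s,
        "components": "zyx",
        "has_mask": vf.mask is not None,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_vector_field(prefix: Union[str, Path]) -> VectorField4D:
    prefix = Path(prefix)
    meta_path = Path(f"{prefix}.json")
    if not meta_path.exists():
        raise FileFormatError(f"missing sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape"])
    comps = [
        tifffile.imread(Path(f"{prefix}_v{c}.tif")).reshape(shape) for c in "zyx"
    ]
    mask = None
    if meta.get("has_mask"):
        mask = tifffile.imread(Path(f"{prefix}_mask.tif")).reshape(shape[1:]) > 0
    return VectorField4D(
        velocities=np.stack(comps, axis=-1),
        mask=mask,
        spacing_um=tuple(meta["spacing_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
    )


def write_vector_field_vtk(
    vf: VectorField4D, frame: int, path: Union[str, Path]
) -> None:
    """One frame as a legacy-VTK structured-points file (for visualization)."""
    v = vf.velocities[frame]
    nz, ny, nx = v.shape[:3]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cardioflow velocity field, frame {frame}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        sz, sy, sx = vf.spacing_um
        fh.write(f"SPACING {sx} {sy} {sz}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity float\n")
        flat = v.reshape(-1, 3)
        for vz, vy, vx in flat:
            fh.write(f"{vx:.6g} {vy:.6g} {vz:.6g}\n")


def tracks_to_dataframe(tracks: TrackSet, frame_interval_s: float) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        vel = tr.velocities_um_s
        for i, f in enumerate(tr.frames):
            row = {
                "track_id": tr.track_id,
                "frame": int(f),
                "t_seconds": float(f) * frame_interval_s,
                "z_um": tr.positions_um[i, 0],
                "y_um": tr.positions_um[i, 1],
                "x_um": tr.positions_um[i, 2],
            }
            if vel is not None:
                row.update(vz=vel[i, 0], vy=vel[i, 1], vx=vel[i, 2])
            rows.append(row)
    return pd.DataFrame(rows)


def write_tracks(
    tracks: TrackSet, frame_interval_s: float, path: Union[str, Path]
) -> None:
    tracks_to_dataframe(tracks, frame_interval_s).to_csv(path, index=False)


def read_tracks(path: Union[str, Path]) -> TrackSet:
    df = pd.read_csv(path)
    has_vel = "vz" in df.columns
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                positions_um=grp[["z_um", "y_um", "x_um"]].to_numpy(),
                velocities_um_s=(
                    grp[["vz", "vy", "vx"]].to_numpy() if has_vel else None
                ),
            )
        )
    return TrackSet(tracks=tracks)


def write_centerline(c: Centerline, path: Union[str, Path]) -> None:
    doc = {
        "center_um": c.center_um.tolist(),
        "plane_basis": c.plane_basis.tolist(),
        "plane_normal": c.plane_normal.tolist(),
        "coefficients": c.coefficients.tolist(),
        "theta_domain": list(c.theta_domain),
        "av_end": c.av_end,
        "residuals_um": c.residuals_um.tolist(),
        "n_samples": int(c.samples_um.shape[0]),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    samples = pd.DataFrame({
        "arc_length_um": c.arc_length_um,
        "z_um": c.samples_um[:, 0],
        "y_um": c.samples_um[:, 1],
        "x_um": c.samples_um[:, 2],
        "tz": c.tangents[:, 0],
        "ty": c.tangents[:, 1],
        "tx": c.tangents[:, 2],
    })
    samples.to_csv(Path(str(path)).with_suffix(".samples.csv"), index=False)


def read_centerline(path: Union[str, Path]) -> Centerline:
    with open(path) as fh:
        doc = json.load(fh)
    samples = pd.read_csv(Path(str(path)).with_suffix(".samples.csv"))
    return Centerline(
        center_um=np.asarray(doc["center_um"]),
        plane_basis=np.asarray(doc["plane_basis"]),
        plane_normal=np.asarray(doc["plane_normal"]),
        coefficients=np.asarray(doc["coefficients"]),
        theta_domain=tuple(doc["theta_domain"]),
        samples_um=samples[["z_um", "y_um", "x_um"]].to_numpy(),
        arc_length_um=samples["arc_length_um"].to_numpy(),
        tangents=samples[["tz", "ty", "tx"]].to_numpy(),
        residuals_um=np.asarray(doc["residuals_um"]),
        av_end=doc["av_end"],
    )


def write_labels(labels: np.ndarray, path: Union[str, Path]) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32),
                     photometric="minisblack")


def read_labels(path: Union[str, Path]) -> np.ndarray:
    return tifffile.imread(path)
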