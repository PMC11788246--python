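"""Reading and writing dynamic series and result maps.

Dynamic magnitude/phase series are read either from a pair of 4D NIfTI-1
volumes (time last) or from a directory of DICOM files holding paired
magnitude and phase images.  Result maps (temperature, dose, flow) are
written as NIfTI with the voxel spacing in the affine, so any standard
viewer displays them at the right scale.

DICOM stored phase is vendor-encoded as integers; by default a linear map
of ``[0, 4096)`` onto ``[-pi, pi)`` is assumed, overridable with an explicit
``(slope, intercept)`` pair for other dialects.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .series import DynamicSeries, wrap_phase

__all__ = [
    "read_series",
    "write_series",
    "write_map",
    "read_map",
    "dicom_phase_to_radians",
]

#: Default DICOM stored-phase convention: integers in [0, 4096).
DEFAULT_PHASE_SCALE = (2.0 * np.pi / 4096.0, -np.pi)


def dicom_phase_to_radians(
    stored: np.ndarray,
    rescale: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map vendor stored-phase integers onto radians in ``[-pi, pi)``.

    ``rescale=(slope, intercept)`` overrides the default linear map
    ``phi = stored * 2*pi/4096 - pi``.
    """
    slope, intercept = rescale if rescale is not None else DEFAULT_PHASE_SCALE
    return wrap_phase(np.asarray(stored, dtype=float) * slope + intercept)


# ---------------------------------------------------------------------------
# NIfTI series layout: <dir>/magnitude.nii + <dir>/phase.nii (4D, time last)
# plus <dir>/series.json carrying timestamps and the nominal frame interval.
# ---------------------------------------------------------------------------

def _to_nifti_array(stack4d: np.ndarray) -> np.ndarray:
    # internal (t, z, row, col) -> NIfTI (x=col, y=row, z, t)
    return np.ascontiguousarray(np.transpose(stack4d, (3, 2, 1, 0)))


def _from_nifti_array(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (3, 2, 1, 0))


def _affine(voxel_spacing: tuple[float, float, float]) -> np.ndarray:
    dx, dy, dz = voxel_spacing
    return np.diag([dx, dy, dz, 1.0])


def write_series(series: DynamicSeries, path: str | Path) -> dict[str, Path]:
    """Write a dynamic series as paired 4D NIfTI volumes plus JSON metadata.

    Returns the mapping of component name to file path.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.voxel_spacing)
    out: dict[str, Path] = {}
    for name, stack in (("magnitude", series.magnitude), ("phase", series.phase)):
        img = nib.Nifti1Image(_to_nifti_array(stack), aff)
        img.header.set_zooms(
            tuple(series.voxel_spacing) + (series.frame_interval,)
        )
        fname = path / f"{name}.nii"
        nib.save(img, fname)
        out[name] = fname
    meta = {
        "timestamps": series.timestamps.tolist(),
        "frame_interval": series.frame_interval,
        "voxel_spacing": list(series.voxel_spacing),
    }
    meta_path = path / "series.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    out["meta"] = meta_path
    return out


def _read_nifti_series(path: Path) -> DynamicSeries:
    mag_path = _find_component(path, "magnitude")
    phase_path = _find_component(path, "phase")
    mag_img = nib.load(mag_path)
    phase_img = nib.load(phase_path)
    mag = np.asarray(mag_img.dataobj, dtype=float)
    phase = np.asarray(phase_img.dataobj, dtype=float)
    if mag.ndim == 3:  # single frame
        mag = mag[..., None]
        phase = phase[..., None]
    if mag.shape != phase.shape:
        raise ValueError(
            f"magnitude grid {mag.shape} does not match phase grid {phase.shape}"
        )
    zooms = mag_img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    meta_path = path / "series.json" if path.is_dir() else None
    n_frames = mag.shape[-1]
    if meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        timestamps = np.asarray(meta["timestamps"], dtype=float)
        frame_interval = float(meta.get("frame_interval", 0.0))
        spacing = tuple(meta.get("voxel_spacing", spacing))
    else:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        timestamps = np.arange(n_frames) * dt
        frame_interval = dt
    return DynamicSeries(
        magnitude=_from_nifti_array(mag),
        phase=_from_nifti_array(phase),
        timestamps=timestamps,
        voxel_spacing=spacing,  # type: ignore[arg-type]
        frame_interval=frame_interval,
    )


def _find_component(path: Path, name: str) -> Path:
    if path.is_file():
        raise ValueError(
            "NIfTI series path must be a directory containing "
            "magnitude.nii and phase.nii"
        )
    for ext in (".nii", ".nii.gz"):
        cand = path / f"{name}{ext}"
        if cand.exists():
            return cand
    raise FileNotFoundError(f"no {name}.nii[.gz] under {path}")


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _acq_seconds(ds: pydicom.Dataset) -> float:
    """Acquisition time tag (TM: HHMMSS.frac) as seconds since midnight."""
    tm = str(getattr(ds, "AcquisitionTime", "") or "000000")
    hh, mm = int(tm[0:2] or 0), int(tm[2:4] or 0)
    ss = float(tm[4:] or 0.0)
    return hh * 3600.0 + mm * 60.0 + ss


def _is_phase(ds: pydicom.Dataset) -> bool:
    image_type = [str(v).upper() for v in getattr(ds, "ImageType", [])]
    return "P" in image_type or "PHASE" in image_type


def _read_dicom_series(
    path: Path, phase_rescale: tuple[float, float] | None
) -> DynamicSeries:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM files under {path}")

    mag_ds = [d for d in datasets if not _is_phase(d)]
    phs_ds = [d for d in datasets if _is_phase(d)]

    def sort_key(d):
        return (_acq_seconds(d), int(getattr(d, "InstanceNumber", 0)))

    mag_ds.sort(key=sort_key)
    phs_ds.sort(key=sort_key)

    def group_frames(dss):
        frames: dict[int, list] = {}
        for d in dss:
            acq = int(getattr(d, "AcquisitionNumber", 0) or 0)
            frames.setdefault(acq, []).append(d)
        return {
            k: sorted(v, key=lambda d: (float(getattr(d, "SliceLocation", 0.0) or 0.0),
                                        int(getattr(d, "InstanceNumber", 0))))
            for k, v in frames.items()
        }

    mag_frames = group_frames(mag_ds)
    phs_frames = group_frames(phs_ds)
    if set(mag_frames) != set(phs_frames):
        missing = sorted(set(mag_frames) ^ set(phs_frames))
        raise ValueError(
            f"unpaired magnitude/phase frames: {len(missing)} frame(s) "
            f"without a partner (acquisition numbers {missing})"
        )
    frame_ids = sorted(mag_frames)
    mags, phases, times = [], [], []
    for fid in frame_ids:
        m_stack = np.stack([d.pixel_array.astype(float) for d in mag_frames[fid]])
        p_raw = np.stack([d.pixel_array.astype(float) for d in phs_frames[fid]])
        if m_stack.shape != p_raw.shape:
            raise ValueError(
                f"frame {fid}: magnitude stack {m_stack.shape} != phase stack "
                f"{p_raw.shape}"
            )
        mags.append(m_stack)
        phases.append(dicom_phase_to_radians(p_raw, phase_rescale))
        times.append(min(_acq_seconds(d) for d in mag_frames[fid]))
    timestamps = np.asarray(times, dtype=float)
    timestamps -= timestamps[0]
    if len(timestamps) > 1 and not np.all(np.diff(timestamps) > 0):
        raise ValueError("non-monotonic DICOM acquisition timestamps")

    ref = mag_frames[frame_ids[0]][0]
    px = getattr(ref, "PixelSpacing", [2.5, 2.5])
    dz = float(getattr(ref, "SliceThickness", 3.0) or 3.0)
    spacing = (float(px[1]), float(px[0]), dz)  # (col, row, slice)
    return DynamicSeries(
        magnitude=np.stack(mags),
        phase=np.stack(phases),
        timestamps=timestamps,
        voxel_spacing=spacing,
    )


def read_series(
    path: str | Path,
    format: str = "nifti",
    phase_rescale: tuple[float, float] | None = None,
) -> DynamicSeries:
    """Read a dynamic magnitude/phase series.

    Parameters
    ----------
    path : directory containing the series.
    format : "nifti" (magnitude.nii + phase.nii, 4D time-last) or "dicom".
    phase_rescale : optional (slope, intercept) overriding the default
        DICOM stored-phase convention ``[0, 4096) -> [-pi, pi)``.
    """
    path = Path(path)
    if format == "nifti":
        return _read_nifti_series(path)
    if format == "dicom":
        return _read_dicom_series(path, phase_rescale)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom'")


# ---------------------------------------------------------------------------
# Single-quantity maps (temperature, dose, flow components)
# ---------------------------------------------------------------------------

def write_map(
    stack: np.ndarray,
    path: str | Path,
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 3.0),
) -> Path:
    """Write a 3D (z, row, col) or 4D (t, z, row, col) map as NIfTI.

    NaN values (e.g. dose outside the body mask) are preserved.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 3:
        data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    elif arr.ndim == 4:
        data = _to_nifti_array(arr)
    else:
        raise ValueError(f"map must be 3D or 4D, got ndim={arr.ndim}")
    img = nib.Nifti1Image(data, _affine(voxel_spacing))
    zooms = tuple(voxel_spacing) + ((1.0,) if arr.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, path)
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a map written by :func:`write_map`; returns (array, spacing)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if data.ndim == 3:
        arr = np.transpose(data, (2, 1, 0))
    else:
        arr = _from_nifti_array(data)
    return arr, spacing  # type: ignore[return-value]
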