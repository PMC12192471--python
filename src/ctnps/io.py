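"""Standard-format I/O: NIfTI/DICOM/array-dump stacks, curve CSVs, sidecars.

Ensembles are written as 4D NIfTI volumes (H, W, n_slice, n_rep) with a JSON
sidecar carrying method, dose fraction, seed and pixel size.  Image stacks
can be read from NIfTI, from a DICOM series directory (rescale slope and
intercept applied, slices ordered by position) or from a plain ``.npy``
array dump with a JSON sidecar.  Spectra are exchanged as CSV with columns
``frequency_mm^-1, power_HU2mm2, support_count``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .ensemble import NoiseEnsemble
from .nps import NPSCurve
from .phantom import ImageStack

__all__ = [
    "write_ensemble_nifti",
    "read_ensemble_nifti",
    "read_image_stack",
    "write_array_dump",
    "write_curve_csv",
    "read_curve_csv",
    "write_json",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".npy"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_ensemble_nifti(ens: NoiseEnsemble, path: str | Path) -> Path:
    """Write an ensemble as 4D NIfTI plus a JSON sidecar; returns the path."""
    path = Path(path)
    data = np.moveaxis(ens.images.astype(np.float32), (0, 1), (3, 2))  # H,W,slice,rep
    affine = np.diag([ens.pixel_size, ens.pixel_size, 4.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((ens.pixel_size, ens.pixel_size, 4.0, 1.0))
    nib.save(img, str(path))
    prov = {k: v for k, v in ens.provenance.items() if k != "profile"}
    profile = ens.provenance.get("profile")
    if profile is not None:
        prov["profile"] = {
            "method_name": profile.method_name,
            "amplitude": profile.amplitude,
            "f0": profile.f0,
            "p": profile.p,
            "q": profile.q,
            "dose_fraction": profile.dose_fraction,
        }
    write_json({"pixel_size": ens.pixel_size, "n_rep": ens.n_rep, **prov}, _sidecar_path(path))
    return path


def read_ensemble_nifti(path: str | Path) -> NoiseEnsemble:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D ensemble volume, got {data.ndim}D")
    images = np.moveaxis(data, (3, 2), (0, 1))
    sidecar = _sidecar_path(path)
    prov: dict[str, Any] = {}
    pixel_size = float(img.header.get_zooms()[0])
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
        pixel_size = float(prov.pop("pixel_size", pixel_size))
        prov.pop("n_rep", None)
        if "profile" in prov:
            from .profiles import MethodProfile

            prov["profile"] = MethodProfile(**prov["profile"])
    return NoiseEnsemble(images, pixel_size, provenance=prov)


def write_array_dump(stack: ImageStack, path: str | Path) -> Path:
    """Plain array dump: ``.npy`` values plus a JSON sidecar with geometry."""
    path = Path(path)
    np.save(path, stack.values.astype(np.float32))
    out = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    write_json({"pixel_size": stack.pixel_size}, _sidecar_path(out))
    return out


def _read_dicom_series(path: Path) -> ImageStack:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append((f, pydicom.dcmread(str(f))))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM files")
    spacings = {}
    for f, ds in datasets:
        spacings[f.name] = tuple(float(v) for v in ds.PixelSpacing)
    unique = set(spacings.values())
    if len(unique) > 1:
        detail = ", ".join(f"{name}: {sp}" for name, sp in spacings.items())
        raise ValueError(f"{path}: mixed pixel sizes across series ({detail})")
    (row_sp, col_sp) = unique.pop()
    if not np.isclose(row_sp, col_sp):
        raise ValueError(f"{path}: anisotropic pixels ({row_sp} x {col_sp} mm) unsupported")

    def z_key(item):
        _, ds = item
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_key)
    slices = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    return ImageStack(np.stack(slices), pixel_size=row_sp)


def read_image_stack(path: str | Path, format: str) -> ImageStack:
    """Read an image stack in HU; ``format`` selects the dialect.

    ``nifti``: 3D volume, slices along the last axis.  ``dicom_series``:
    directory of single-slice files, ordered by slice position, rescale
    slope/intercept applied.  ``array_dump``: ``.npy`` (n_slice, H, W) with
    a JSON sidecar holding ``pixel_size``.
    """
    path = Path(path)
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume")
        zooms = img.header.get_zooms()
        if not np.isclose(zooms[0], zooms[1]):
            raise ValueError(f"{path}: anisotropic in-plane pixels unsupported")
        return ImageStack(np.moveaxis(data, 2, 0), pixel_size=float(zooms[0]))
    if format == "array_dump":
        values = np.load(path)
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"{path}: missing JSON sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        return ImageStack(values.astype(float), pixel_size=float(meta["pixel_size"]))
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown stack format {format!r}")


def write_curve_csv(curve: NPSCurve, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frequency_mm^-1": curve.frequencies,
            "power_HU2mm2": curve.power,
            "support_count": curve.support_count,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_curve_csv(path: str | Path, kind: str = "cohort_mean") -> NPSCurve:
    df = pd.read_csv(path)
    return NPSCurve(
        frequencies=df["frequency_mm^-1"].to_numpy(),
        power=df["power_HU2mm2"].to_numpy(),
        kind=kind,
        support_count=df["support_count"].to_numpy(),
    )
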