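"""Standard-format persistence: NIfTI label volumes and fields, HDF5
artifacts (pressure/intensity/sample sets/surrogates/UQ fields), YAML
configs, CSV traces and JSON metrics."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acoustics import IntensityField
from .montecarlo import ConvergenceTrace, UQField
from .pce import PCEBasisSpec, PCESurrogate
from .phantom import LabelVolume
from .tissuedb import SampleSet

__all__ = [
    "save_label_volume_nifti",
    "load_label_volume_nifti",
    "save_label_volume_h5",
    "load_label_volume_h5",
    "save_intensity_nifti",
    "save_intensity_h5",
    "load_intensity_h5",
    "save_sample_set",
    "load_sample_set",
    "save_surrogate",
    "load_surrogate",
    "save_uq_field",
    "load_uq_field",
    "save_trace_csv",
]


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.diag([spacing_mm] * 3 + [1.0])
    aff[:3, 3] = spacing_mm / 2.0  # voxel centers at (index + 0.5) * spacing
    return aff


def save_label_volume_nifti(vol: LabelVolume, path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), _affine(vol.spacing_mm))
    img.header.set_zooms((vol.spacing_mm,) * 3)
    img.header["descrip"] = json.dumps(vol.names)[:79].encode()
    nib.save(img, str(path))
    with open(str(path) + ".labels.json", "w") as fh:
        json.dump({"names": dict(vol.names), "spacing_mm": vol.spacing_mm}, fh)


def load_label_volume_nifti(path) -> LabelVolume:
    img = nib.load(str(path))
    spacing = float(img.header.get_zooms()[0])
    names = None
    sidecar = Path(str(path) + ".labels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = meta["names"]
        spacing = float(meta.get("spacing_mm", spacing))
    arr = np.asarray(img.dataobj).astype(np.int16)
    if names is not None:
        return LabelVolume(arr, spacing, names)
    return LabelVolume(arr, spacing)


def save_label_volume_h5(vol: LabelVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=vol.labels.astype(np.int16))
        f.attrs["spacing_mm"] = vol.spacing_mm
        f.attrs["names"] = json.dumps(dict(vol.names))


def load_label_volume_h5(path) -> LabelVolume:
    with h5py.File(path, "r") as f:
        return LabelVolume(
            f["labels"][...],
            float(f.attrs["spacing_mm"]),
            json.loads(f.attrs["names"]),
        )


def save_intensity_nifti(field: IntensityField, path) -> None:
    img = nib.Nifti1Image(
        field.intensity.astype(np.float32), _affine(field.voxel_spacing_mm)
    )
    nib.save(img, str(path))


def save_intensity_h5(field: IntensityField, path, name: str = "intensity") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(name, data=field.intensity)
        d.attrs["spacing_mm"] = field.voxel_spacing_mm
        d.attrs["provenance"] = field.provenance
        d.attrs["units"] = "W/cm^2"


def load_intensity_h5(path, name: str = "intensity") -> IntensityField:
    with h5py.File(path, "r") as f:
        d = f[name]
        return IntensityField(
            d[...], float(d.attrs["spacing_mm"]), str(d.attrs["provenance"])
        )


def save_sample_set(samples: SampleSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=samples.values)
        f.create_dataset("standardized", data=samples.standardized)
        f.create_dataset("means", data=samples.means)
        f.create_dataset("stds", data=samples.stds)
        f.attrs["seed"] = samples.seed
        f.attrs["index"] = json.dumps([list(p) for p in samples.index])


def load_sample_set(path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            f["values"][...],
            f["standardized"][...],
            tuple(tuple(p) for p in json.loads(f.attrs["index"])),
            f["means"][...],
            f["stds"][...],
            int(f.attrs["seed"]),
        )


def save_surrogate(sur: PCESurrogate, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs", data=sur.coeffs)
        f.create_dataset("means", data=sur.means)
        f.create_dataset("stds", data=sur.stds)
        f.create_dataset("residual_norm", data=sur.residual_norm)
        if sur.mask is not None:
            f.create_dataset("mask", data=sur.mask)
        f.attrs["grid_shape"] = sur.grid_shape
        f.attrs["u"] = sur.basis.u
        f.attrs["order"] = sur.basis.order
        f.attrs["cross_terms"] = sur.basis.cross_terms
        f.attrs["n_training"] = sur.n_training
        f.attrs["index"] = json.dumps([list(p) for p in sur.property_index])


def load_surrogate(path) -> PCESurrogate:
    from .pce import build_basis

    with h5py.File(path, "r") as f:
        basis = build_basis(
            int(f.attrs["u"]), int(f.attrs["order"]), bool(f.attrs["cross_terms"])
        )
        return PCESurrogate(
            basis=basis,
            coeffs=f["coeffs"][...],
            grid_shape=tuple(int(s) for s in f.attrs["grid_shape"]),
            mask=f["mask"][...].astype(bool) if "mask" in f else None,
            means=f["means"][...],
            stds=f["stds"][...],
            property_index=tuple(tuple(p) for p in json.loads(f.attrs["index"])),
            residual_norm=f["residual_norm"][...],
            n_training=int(f.attrs["n_training"]),
        )


def save_uq_field(uq: UQField, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=uq.mean)
        f.create_dataset("std", data=uq.std)
        f.attrs["n_samples"] = uq.n_samples
        f.attrs["source"] = uq.source
        if uq.seed is not None:
            f.attrs["seed"] = uq.seed


def load_uq_field(path) -> UQField:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return UQField(
            f["mean"][...], f["std"][...], int(f.attrs["n_samples"]),
            str(f.attrs["source"]), seed,
        )


def save_trace_csv(trace: ConvergenceTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("k,value,running_mean,running_std\n")
        for k in range(trace.n_samples):
            fh.write(
                f"{k + 1},{trace.values[k]:.10g},"
                f"{trace.running_mean[k]:.10g},{trace.running_std[k]:.10g}\n"
            )
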