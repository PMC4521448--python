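"""File I/O: HDF5 fields, NIfTI label volumes, YAML configs, CSV tables."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .acoustic import PhasorField
from .media import AcousticMedium, MaterialVolume, ThermalMedium, build_material_volume
from .transducers import DriveVector, TransducerArray

__all__ = [
    "save_phasor_field",
    "load_phasor_field",
    "save_labels_nifti",
    "load_labels_nifti",
    "save_label_table",
    "load_label_table",
    "save_drive_vector",
    "load_drive_vector",
    "save_array_geometry",
    "load_array_geometry",
    "write_metrics_csv",
]


def save_phasor_field(path, field: PhasorField) -> None:
    """Write amplitude/phase datasets plus grid metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=field.amplitude, compression="gzip")
        f.create_dataset("phase", data=field.phase, compression="gzip")
        f.attrs["frequency_Hz"] = field.frequency
        for name, ax in zip("xyz", field.axes):
            f.create_dataset(f"axis_{name}", data=np.asarray(ax))


def load_phasor_field(path) -> PhasorField:
    import h5py

    with h5py.File(path, "r") as f:
        amp = f["amplitude"][()]
        ph = f["phase"][()]
        axes = tuple(f[f"axis_{n}"][()] for n in "xyz")
        freq = float(f.attrs["frequency_Hz"])
    return PhasorField(phasor=amp * np.exp(1j * ph), frequency=freq, axes=axes)


def save_labels_nifti(path, volume: MaterialVolume) -> None:
    """Write the label grid as NIfTI with the voxel spacing in the affine."""
    import nibabel as nib

    affine = np.diag([*(s * 1e3 for s in volume.spacing), 1.0])  # mm
    affine[:3, 3] = [o * 1e3 for o in volume.origin]
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_labels_nifti(path, label_table) -> MaterialVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) * 1e-3 for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) * 1e-3 for v in img.affine[:3, 3])
    return build_material_volume(
        np.asarray(img.dataobj).astype(np.int16), spacing, label_table,
        origin=origin)


def _medium_to_dict(m) -> dict:
    if m is None:
        return None
    return {k: v for k, v in m.__dict__.items() if v is not None}


def save_label_table(path, label_table, label_names=None) -> None:
    """Label → media table as YAML (or JSON by extension)."""
    import yaml

    doc = {}
    for lab, (ac, th) in label_table.items():
        doc[int(lab)] = {
            "name": (label_names or {}).get(lab),
            "acoustic": _medium_to_dict(ac),
            "thermal": _medium_to_dict(th),
        }
    text = (json.dumps(doc, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(doc))
    Path(path).write_text(text)


def load_label_table(path):
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    table, names = {}, {}
    for lab, entry in doc.items():
        ac = AcousticMedium(**entry["acoustic"])
        th = ThermalMedium(**entry["thermal"]) if entry.get("thermal") else None
        table[int(lab)] = (ac, th)
        if entry.get("name"):
            names[int(lab)] = entry["name"]
    return table, names


def save_drive_vector(path, drive: DriveVector) -> None:
    """Element id, amplitude (Pa), phase (rad), active flag as CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["element", "amplitude_Pa", "phase_rad", "active"])
        for i, (a, p, act) in enumerate(
            zip(drive.amplitudes, drive.phases, drive.active)
        ):
            w.writerow([i, repr(float(a)), repr(float(p)), int(act)])


def load_drive_vector(path) -> DriveVector:
    rows = list(csv.DictReader(open(path)))
    return DriveVector(
        amplitudes=[float(r["amplitude_Pa"]) for r in rows],
        phases=[float(r["phase_rad"]) for r in rows],
        active=[bool(int(r["active"])) for r in rows],
    )


def save_array_geometry(path, array: TransducerArray) -> None:
    doc = {
        "frequency_Hz": array.frequency,
        "geometric_focus_m": array.geometric_focus.tolist(),
        "radius_m": array.radius,
        "centers_m": array.centers.tolist(),
        "normals": array.normals.tolist(),
        "areas_m2": array.areas.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_array_geometry(path) -> TransducerArray:
    doc = json.loads(Path(path).read_text())
    return TransducerArray(
        centers=doc["centers_m"], normals=doc["normals"],
        areas=doc["areas_m2"], geometric_focus=doc["geometric_focus_m"],
        frequency=doc["frequency_Hz"], radius=doc.get("radius_m"),
    )


def write_metrics_csv(path, rows: list[dict]) -> None:
    """One row per target/strategy with the focal-metrics columns."""
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)
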