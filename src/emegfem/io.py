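"""File formats: NIfTI volumes, whitespace sensor tables, HDF5 containers.

* Label volumes and tensor fields are NIfTI-1 (via nibabel).  Tensors are
  stored as 6 volumes in lower-triangle order ``xx, xy, yy, xz, yz, zz``.
  The label table travels in a ``<stem>.labels.json`` sidecar.
* Sensor arrays are whitespace-separated text, one row per sensor:
  ``name x y z`` for EEG and ``name x y z ox oy oz baseline`` for MEG
  (units mm, RAS; ``#``-comments carry the MEG type and reference).
* Meshes, epoched/evoked data and leadfields live in HDF5 containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .fem import LeadfieldSet
from .inverse import EvokedData
from .mesh import HexMesh
from .phantom import ChannelMeta, LabeledVoxelGrid, RawTrials, SensorArray, TensorField

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_tensor_field",
    "load_tensor_field",
    "save_sensor_array",
    "load_sensor_array",
    "save_mesh",
    "load_mesh",
    "save_raw_trials",
    "load_raw_trials",
    "save_evoked",
    "load_evoked",
    "save_leadfields",
    "load_leadfields",
]

_TRIL_ORDER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]  # xx xy yy xz yz zz

def _ds(f, name, data) -> None:
    """Deterministic dataset write (no embedded timestamps)."""
    f.create_dataset(name, data=data, track_times=False)



def _affine(grid: LabeledVoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.voxel_size
    aff[:3, 3] = grid.origin + grid.voxel_size / 2.0  # voxel centers
    return aff


def save_label_volume(grid: LabeledVoxelGrid, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(grid.labels.astype(np.int16), _affine(grid))
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    Path(str(sidecar) + ".labels.json").write_text(
        json.dumps({str(k): v for k, v in grid.label_table.items()}, indent=0)
    )


def load_label_volume(path) -> LabeledVoxelGrid:
    path = Path(path)
    img = nib.load(path)
    aff = img.affine
    voxel = float(aff[0, 0])
    if not np.allclose(aff[:3, :3], voxel * np.eye(3)):
        raise ValueError("only axis-aligned isotropic volumes are supported")
    origin = aff[:3, 3] - voxel / 2.0
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".labels.json")
    table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabeledVoxelGrid(np.asarray(img.dataobj).astype(int), voxel, origin, table)


def save_tensor_field(tf: TensorField, path) -> None:
    comps = np.stack([tf.tensors[..., i, j] for i, j in _TRIL_ORDER], axis=-1)
    img = nib.Nifti1Image(comps.astype(np.float64), _affine(tf.grid))
    img.header["intent_name"] = tf.kind.encode()[:15]
    nib.save(img, Path(path))


def load_tensor_field(tf_path, grid: LabeledVoxelGrid, kind: str | None = None) -> TensorField:
    img = nib.load(Path(tf_path))
    comps = np.asarray(img.dataobj)
    if comps.shape != grid.shape + (6,):
        raise ValueError("tensor volume shape does not match the grid")
    T = np.empty(grid.shape + (3, 3))
    for c, (i, j) in enumerate(_TRIL_ORDER):
        T[..., i, j] = comps[..., c]
        T[..., j, i] = comps[..., c]
    if kind is None:
        kind = img.header["intent_name"].tobytes().rstrip(b"\x00").decode() or "diffusion"
    return TensorField(grid, T, kind)


def save_sensor_array(sensors: SensorArray, path) -> None:
    lines = [
        "# emegfem sensor array; mm, RAS",
        f"# meg_type {sensors.meg_type}",
        f"# reference {sensors.reference}",
    ]
    for name, p in zip(sensors.eeg_labels, sensors.eeg_positions):
        lines.append(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    bl = sensors.baseline if sensors.baseline is not None else 0.0
    for name, p, o in zip(sensors.meg_labels, sensors.meg_centers, sensors.meg_orientations):
        lines.append(
            f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {o[0]:.8f} {o[1]:.8f} {o[2]:.8f} {bl:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_sensor_array(path) -> SensorArray:
    meg_type, reference = "magnetometer", "average"
    eeg_p, eeg_n, meg_p, meg_o, meg_n, baselines = [], [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "meg_type":
                meg_type = parts[1]
            elif len(parts) == 2 and parts[0] == "reference":
                reference = parts[1]
            continue
        parts = line.split()
        if len(parts) == 4:
            eeg_n.append(parts[0])
            eeg_p.append([float(x) for x in parts[1:4]])
        elif len(parts) == 8:
            meg_n.append(parts[0])
            meg_p.append([float(x) for x in parts[1:4]])
            meg_o.append([float(x) for x in parts[4:7]])
            baselines.append(float(parts[7]))
        else:
            raise ValueError(f"malformed sensor row: {line!r}")
    baseline = baselines[0] if baselines and baselines[0] > 0 else None
    return SensorArray(
        eeg_positions=np.array(eeg_p).reshape(-1, 3),
        eeg_labels=eeg_n,
        meg_centers=np.array(meg_p).reshape(-1, 3),
        meg_orientations=np.array(meg_o).reshape(-1, 3),
        meg_labels=meg_n,
        meg_type=meg_type,
        baseline=baseline,
        reference=reference,
    )


def save_mesh(mesh: HexMesh, path) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "nodes", mesh.nodes)
        _ds(f, "elements", mesh.elements)
        _ds(f, "element_labels", mesh.element_labels)
        _ds(f, "element_voxels", mesh.element_voxels)
        if mesh.element_tensors is not None:
            _ds(f, "element_tensors", mesh.element_tensors)
        f.attrs["voxel_size"] = mesh.voxel_size
        f.attrs["origin"] = mesh.origin
        f.attrs["grid_shape"] = mesh.grid_shape
        f.attrs["label_table"] = json.dumps({str(k): v for k, v in mesh.label_table.items()})


def load_mesh(path) -> HexMesh:
    with h5py.File(path, "r") as f:
        return HexMesh(
            nodes=f["nodes"][()],
            elements=f["elements"][()],
            element_labels=f["element_labels"][()],
            voxel_size=float(f.attrs["voxel_size"]),
            origin=np.asarray(f.attrs["origin"]),
            element_voxels=f["element_voxels"][()],
            grid_shape=tuple(int(s) for s in f.attrs["grid_shape"]),
            label_table={int(k): v for k, v in json.loads(f.attrs["label_table"]).items()},
            element_tensors=f["element_tensors"][()] if "element_tensors" in f else None,
        )


def _write_channel_meta(f, meta: list[ChannelMeta]) -> None:
    _ds(f, "channel_names", np.array([m.name for m in meta], dtype="S32"))
    _ds(f, "channel_modality", np.array([m.modality for m in meta], dtype="S8"))
    _ds(f, "noise_std", np.array([m.noise_std for m in meta]))


def _read_channel_meta(f) -> list[ChannelMeta]:
    names = [n.decode() for n in f["channel_names"][()]]
    mods = [m.decode() for m in f["channel_modality"][()]]
    stds = f["noise_std"][()]
    return [ChannelMeta(n, m, float(s)) for n, m, s in zip(names, mods, stds)]


def save_raw_trials(trials: RawTrials, path) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "data", trials.data)
        _write_channel_meta(f, trials.channel_meta)
        f.attrs["sampling_rate"] = trials.sampling_rate
        f.attrs["event_latency"] = trials.event_latency
        f.attrs["kind"] = "raw_trials"


def load_raw_trials(path) -> RawTrials:
    with h5py.File(path, "r") as f:
        return RawTrials(
            f["data"][()], _read_channel_meta(f), float(f.attrs["sampling_rate"]), int(f.attrs["event_latency"])
        )


def save_evoked(ev: EvokedData, path) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "data", ev.data)
        _write_channel_meta(f, ev.channel_meta)
        f.attrs["sampling_rate"] = ev.sampling_rate
        f.attrs["time_zero"] = ev.time_zero
        f.attrs["kind"] = "evoked"


def load_evoked(path) -> EvokedData:
    with h5py.File(path, "r") as f:
        return EvokedData(
            f["data"][()], _read_channel_meta(f), float(f.attrs["sampling_rate"]), int(f.attrs["time_zero"])
        )


def save_leadfields(lf: LeadfieldSet, path) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "matrix", lf.matrix)
        _ds(f, "row_modality", np.array(lf.row_modality, dtype="S8"))
        _ds(f, "row_names", np.array(lf.row_names, dtype="S32"))
        _ds(f, "source_positions", lf.source_positions)
        _ds(f, "source_nearest_node", lf.source_nearest_node)
        f.attrs["spacing"] = lf.spacing
        f.attrs["units"] = json.dumps(lf.units)
        f.attrs["source_space_hash"] = lf.source_space_hash()
        f.attrs["shape"] = lf.matrix.shape


def load_leadfields(path) -> LeadfieldSet:
    with h5py.File(path, "r") as f:
        lf = LeadfieldSet(
            matrix=f["matrix"][()],
            row_modality=np.array([m.decode() for m in f["row_modality"][()]]),
            row_names=[n.decode() for n in f["row_names"][()]],
            source_positions=f["source_positions"][()],
            source_nearest_node=f["source_nearest_node"][()],
            spacing=float(f.attrs["spacing"]),
            units=json.loads(f.attrs["units"]),
        )
        stored = f.attrs["source_space_hash"]
        if stored != lf.source_space_hash():
            raise ValueError("leadfield source-space hash mismatch (corrupt file?)")
        return lf
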