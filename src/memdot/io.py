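"""File I/O for meshes, montages, channel data, sensitivities and maps.

Standard formats via standard libraries: FreeSurfer / GIfTI surfaces and
NIfTI volumes through nibabel, SNIRF (an HDF5 dialect) through h5py,
sensitivity matrices and cortical maps as plain HDF5 with named dimensions,
events as TSV, parcellations as CSV label tables.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import CorticalMesh, SensitivityModel, VoxelGrid
from .montage import MontageGeometry
from .preprocess import ChannelTimeSeries

__all__ = [
    "save_mesh_gifti", "load_mesh_gifti",
    "save_mesh_freesurfer", "load_mesh_freesurfer",
    "save_voxels_nifti", "load_voxels_nifti",
    "save_sensitivity_h5", "load_sensitivity_h5",
    "save_montage_json", "load_montage_json",
    "save_snirf", "load_snirf",
    "save_events_tsv", "load_events_tsv",
    "save_labels_csv", "load_labels_csv",
    "save_map_h5", "load_map_h5",
]


def save_mesh_gifti(mesh: CorticalMesh, path) -> None:
    coords = nib.gifti.GiftiDataArray(
        mesh.vertex_positions.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    img = nib.gifti.GiftiImage(darrays=[coords, tris])
    img.meta["scalp_radius_mm"] = str(mesh.scalp_radius)
    nib.save(img, str(path))


def load_mesh_gifti(path) -> CorticalMesh:
    img = nib.load(str(path))
    coords = img.darrays[0].data.astype(float)
    tris = img.darrays[1].data.astype(int)
    radius = float(img.meta.get("scalp_radius_mm", 80.0))
    return CorticalMesh(vertex_positions=coords, triangles=tris, scalp_radius=radius)


def save_mesh_freesurfer(mesh: CorticalMesh, path) -> None:
    nib.freesurfer.io.write_geometry(str(path), mesh.vertex_positions, mesh.triangles)


def load_mesh_freesurfer(path, scalp_radius: float = 80.0) -> CorticalMesh:
    coords, tris = nib.freesurfer.io.read_geometry(str(path))
    return CorticalMesh(
        vertex_positions=np.asarray(coords, float),
        triangles=np.asarray(tris, int),
        scalp_radius=scalp_radius,
    )


def save_voxels_nifti(grid: VoxelGrid, path) -> None:
    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), str(path))


def load_voxels_nifti(path) -> VoxelGrid:
    img = nib.load(str(path))
    aff = img.affine
    return VoxelGrid(
        origin=aff[:3, 3], spacing=np.diag(aff)[:3], values=np.asarray(img.dataobj, float)
    )


def save_sensitivity_h5(model: SensitivityModel, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.attrs["wavelengths_nm"] = list(model.wavelengths)
        for wl in model.wavelengths:
            d = f.create_dataset(f"sensitivity/{wl:g}", data=model.matrices[wl])
            d.attrs["dims"] = ["channel", "vertex"]


def load_sensitivity_h5(path, mesh: CorticalMesh) -> SensitivityModel:
    with h5py.File(str(path), "r") as f:
        wls = tuple(float(w) for w in f.attrs["wavelengths_nm"])
        mats = {wl: f[f"sensitivity/{wl:g}"][()] for wl in wls}
    return SensitivityModel(matrices=mats, wavelengths=wls, mesh=mesh)


def save_montage_json(montage: MontageGeometry, path) -> None:
    with open(path, "w") as f:
        f.write(montage.to_json())


def load_montage_json(path) -> MontageGeometry:
    with open(path) as f:
        return MontageGeometry.from_json(f.read())


def save_snirf(data: ChannelTimeSeries, montage: MontageGeometry | None, path) -> None:
    """Minimal SNIRF writer: one data block plus the probe geometry."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        g = f.create_group("nirs1")
        d = g.create_group("data1")
        d.create_dataset("dataTimeSeries", data=data.values.T)   # time x channels
        d.create_dataset("time", data=data.times)
        d.create_dataset("channelIds", data=np.asarray(data.channel_ids, int))
        if data.wavelength is not None:
            d.attrs["wavelength_nm"] = float(data.wavelength)
        if montage is not None:
            p = g.create_group("probe")
            p.create_dataset("sourcePos3D", data=montage.source_positions)
            p.create_dataset("detectorPos3D", data=montage.detector_positions)
            p.create_dataset("wavelengths", data=list(montage.wavelengths))
            ml = np.array([[s, d_, c] for s, d_, c in montage.channels])
            p.create_dataset("measurementList", data=ml)
            p.create_dataset("proximityIndices", data=np.asarray(montage.proximity_indices, int))
        if data.events:
            s = g.create_group("stim1")
            s.create_dataset("data", data=np.array([[on, du, 1.0] for on, du in data.events]))


def load_snirf(path):
    """Read back the minimal SNIRF layout; returns (series, montage or None)."""
    with h5py.File(str(path), "r") as f:
        g = f["nirs1"]
        vals = g["data1/dataTimeSeries"][()].T
        times = g["data1/time"][()]
        ids = g["data1/channelIds"][()]
        wl = g["data1"].attrs.get("wavelength_nm")
        fs = 1.0 / float(np.median(np.diff(times)))
        events = []
        if "stim1" in g:
            events = [(float(r[0]), float(r[1])) for r in g["stim1/data"][()]]
        series = ChannelTimeSeries(
            values=vals,
            sampling_rate=fs,
            channel_ids=np.asarray(ids, int),
            wavelength=float(wl) if wl is not None else None,
            events=events,
            t0=float(times[0]),
        )
        montage = None
        if "probe" in g:
            p = g["probe"]
            montage = MontageGeometry(
                source_positions=p["sourcePos3D"][()],
                detector_positions=p["detectorPos3D"][()],
                proximity_indices=p["proximityIndices"][()],
                channels=[(int(s), int(d), float(c)) for s, d, c in p["measurementList"][()]],
                wavelengths=tuple(float(w) for w in p["wavelengths"][()]),
            )
    return series, montage


def save_events_tsv(events, path) -> None:
    pd.DataFrame(
        [{"onset": on, "duration": du, "label": "task"} for on, du in events]
    ).to_csv(path, sep="\t", index=False)


def load_events_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [(float(r.onset), float(r.duration)) for r in df.itertuples()]


def save_labels_csv(labels, path) -> None:
    pd.DataFrame({"vertex": np.arange(len(labels)), "parcel": np.asarray(labels, int)}).to_csv(
        path, index=False
    )


def load_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.sort_values("vertex")["parcel"].to_numpy()


def save_map_h5(amplitudes, times, method_tag: str, path) -> None:
    with h5py.File(str(path), "w") as f:
        d = f.create_dataset("amplitudes", data=np.asarray(amplitudes))
        d.attrs["dims"] = ["vertex", "time"]
        f.create_dataset("times", data=np.asarray(times))
        f.attrs["method"] = method_tag


def load_map_h5(path):
    with h5py.File(str(path), "r") as f:
        return f["amplitudes"][()], f["times"][()], str(f.attrs["method"])
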