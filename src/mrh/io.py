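"""File formats: NIfTI volumes, FSL-style schemes, HDF5 patch sets, models.

NIfTI round-trips preserve the data array and affine bitwise.  Patch
sets live in a single HDF5 container (datasets ``inputs``, ``targets``,
``coords`` plus attributes).  Model checkpoints are a single ``.npz``
archive holding every weight array next to a JSON header with the
architecture spec, normalization statistics, channel labels, and
training history.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .mrhnet import MRHNet, NetworkSpec, TrainedModel, TrainingConfig
from .contrasts import DiffusionScheme
from .patches import NormalizationStats, PatchSet, ScalarStats
from .phantom import DisplacementField
from .volumes import MultiContrastVolume, TargetVolume

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "read_scheme",
    "write_scheme",
    "save_patchset",
    "load_patchset",
    "save_model",
    "load_model",
    "save_displacement_field",
    "load_displacement_field",
]


def _voxel_size(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def save_volume(
    volume: MultiContrastVolume | TargetVolume | np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a volume as NIfTI-1 (optionally .nii.gz)."""
    if isinstance(volume, (MultiContrastVolume, TargetVolume)):
        data, affine = volume.data, volume.affine
    else:
        data = np.asarray(volume)
        affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(
    path: str | Path,
    channel_labels: list[str] | None = None,
) -> MultiContrastVolume | TargetVolume:
    """Read a 3D (target) or 4D (multi-channel) NIfTI volume.

    4D files need a channel manifest whose length matches the fourth
    dimension; labels are attached in file order.  Without a manifest,
    generic channel names are generated.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        if channel_labels is not None:
            raise ValueError("channel manifest given for a 3D (single-map) file")
        return TargetVolume(data, Path(path).stem.split(".")[0],
                            _voxel_size(img), img.affine.copy())
    if data.ndim != 4:
        raise ValueError(f"expected 3D or 4D NIfTI, got {data.ndim}D")
    C = data.shape[3]
    if channel_labels is None:
        channel_labels = [f"ch{i:02d}" for i in range(C)]
    if len(channel_labels) != C:
        raise ValueError(
            f"manifest has {len(channel_labels)} entries for {C} channels"
        )
    return MultiContrastVolume(data, list(channel_labels),
                               _voxel_size(img), img.affine.copy())


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


# -- diffusion schemes (FSL bval/bvec convention) ---------------------------

def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Read b-values and directions from FSL-style bval/bvec files.

    bval: one row (or column) of b-values in s/mm^2.  bvec: 3 rows x n
    columns (or n x 3), one unit vector per image.
    """
    b = np.loadtxt(bval_path).ravel()
    g = np.loadtxt(bvec_path)
    if g.ndim != 2:
        raise ValueError("bvec file must be 2D")
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape[1] != 3:
        raise ValueError(f"bvec shape {g.shape} not interpretable as (n, 3)")
    return DiffusionScheme(b, g)


def write_scheme(scheme: DiffusionScheme,
                 bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.b_values[None], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


# -- patch sets (HDF5) ------------------------------------------------------

def save_patchset(patchset: PatchSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=patchset.inputs, compression="gzip")
        f.create_dataset("targets", data=patchset.targets, compression="gzip")
        f.create_dataset("coords", data=patchset.coords)
        f.create_dataset("subject_ids", data=patchset.subject_ids)
        f.attrs["k"] = patchset.k
        f.attrs["axis"] = patchset.axis
        if patchset.channel_labels:
            f.attrs["channel_labels"] = json.dumps(patchset.channel_labels)
        if patchset.norm_stats is not None:
            f.create_dataset("norm_location", data=patchset.norm_stats.location)
            f.create_dataset("norm_scale", data=patchset.norm_stats.scale)
        if patchset.target_stats is not None:
            f.attrs["target_location"] = patchset.target_stats.location
            f.attrs["target_scale"] = patchset.target_stats.scale


def load_patchset(path: str | Path) -> PatchSet:
    with h5py.File(path, "r") as f:
        labels = (
            json.loads(f.attrs["channel_labels"])
            if "channel_labels" in f.attrs
            else None
        )
        stats = None
        if "norm_location" in f:
            stats = NormalizationStats(f["norm_location"][:], f["norm_scale"][:], labels)
        tstats = None
        if "target_location" in f.attrs:
            tstats = ScalarStats(
                float(f.attrs["target_location"]), float(f.attrs["target_scale"])
            )
        return PatchSet(
            inputs=f["inputs"][:],
            targets=f["targets"][:],
            coords=f["coords"][:],
            axis=int(f.attrs["axis"]),
            subject_ids=f["subject_ids"][:],
            channel_labels=labels,
            norm_stats=stats,
            target_stats=tstats,
        )


# -- model checkpoints ------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-archive checkpoint: weights + spec + stats + history."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.network.conv_layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    header = {
        "spec": {
            "in_channels": model.spec.in_channels,
            "n_residual_blocks": model.spec.n_residual_blocks,
            "channels_per_layer": model.spec.channels_per_layer,
            "kernel_size": model.spec.kernel_size,
            "patch_size": model.spec.patch_size,
        },
        "channel_labels": model.channel_labels,
        "history": model.history,
        "selected_epoch": model.selected_epoch,
        "config": None if model.config is None else vars(model.config),
        "target_stats": (
            None
            if model.target_stats is None
            else [model.target_stats.location, model.target_stats.scale]
        ),
    }
    if model.norm_stats is not None:
        arrays["norm_location"] = model.norm_stats.location
        arrays["norm_scale"] = model.norm_stats.scale
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as f:
        header = json.loads(bytes(f["header"]).decode())
        spec = NetworkSpec(**header["spec"])
        net = MRHNet(spec, seed=0)
        net.set_weights(
            [(f[f"W{i}"], f[f"b{i}"]) for i in range(spec.n_conv_layers)]
        )
        stats = None
        if "norm_location" in f:
            stats = NormalizationStats(
                f["norm_location"], f["norm_scale"], header["channel_labels"]
            )
        tstats = None
        if header["target_stats"] is not None:
            tstats = ScalarStats(*header["target_stats"])
        config = (
            TrainingConfig(**header["config"]) if header["config"] else None
        )
    return TrainedModel(
        spec=spec,
        network=net,
        norm_stats=stats,
        target_stats=tstats,
        channel_labels=header["channel_labels"],
        history=header["history"],
        selected_epoch=header["selected_epoch"],
        config=config,
    )


# -- displacement fields ----------------------------------------------------

def save_displacement_field(field: DisplacementField, path: str | Path) -> None:
    """Store the two in-plane components as a multi-channel NIfTI."""
    img = nib.Nifti1Image(field.field, np.eye(4))
    img.header["descrip"] = (
        f"axis={field.axis};spacing={field.grid_spacing_mm};"
        f"scale={field.magnitude_scale}".encode()
    )
    nib.save(img, str(path))


def load_displacement_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    meta = dict(
        kv.split("=")
        for kv in img.header["descrip"].tobytes().decode().strip("\x00").split(";")
    )
    return DisplacementField(
        np.asarray(img.dataobj),
        axis=int(meta["axis"]),
        grid_spacing_mm=float(meta["spacing"]),
        magnitude_scale=float(meta["scale"]),
    )


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
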