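"""Persistence of meshes, masks, contours and fitted models.

Canonical formats: LVMesh grids as JSON (lossless, topology-aware) with PLY
export for visualization; masks as NIfTI with the voxel spacing in the
affine; contour stacks as JSON; PCA/LDA models as HDF5.  HDF5 datasets are
written with ``track_times=False`` so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .discriminant import LDAModel
from .imaging import BinaryMask, ContourStack
from .mesh import LVMesh
from .ssm import PCAModel

__all__ = [
    "save_mesh_json",
    "load_mesh_json",
    "save_mesh_ply",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_contours_json",
    "load_contours_json",
    "save_pca_h5",
    "load_pca_h5",
    "save_lda_h5",
    "load_lda_h5",
]


# ------------------------------------------------------------------- meshes
def save_mesh_json(mesh: LVMesh, path) -> None:
    payload = {
        "format": "lvshape-mesh",
        "version": 1,
        "topology_id": mesh.topology_id,
        "node_theta": mesh.node_theta.tolist(),
        "node_u": mesh.node_u.tolist(),
        "endo_points": mesh.endo_points.tolist(),
        "epi_points": mesh.epi_points.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_mesh_json(path) -> LVMesh:
    payload = json.loads(Path(path).read_text())
    return LVMesh(
        endo_points=np.asarray(payload["endo_points"]),
        epi_points=np.asarray(payload["epi_points"]),
        node_theta=np.asarray(payload["node_theta"]),
        node_u=np.asarray(payload["node_u"]),
        topology_id=payload["topology_id"],
    )


def save_mesh_ply(mesh: LVMesh, path) -> None:
    """Both surfaces concatenated into one ASCII PLY triangle mesh."""
    import trimesh

    endo = mesh.to_trimesh("endo")
    epi = mesh.to_trimesh("epi")
    combined = trimesh.util.concatenate([endo, epi])
    Path(path).write_bytes(combined.export(file_type="ply", encoding="ascii"))


# -------------------------------------------------------------------- masks
def save_mask_nifti(mask: BinaryMask, path) -> None:
    import nibabel as nib

    nib.save(mask.to_nifti(), str(path))


def load_mask_nifti(path) -> BinaryMask:
    import nibabel as nib

    return BinaryMask.from_nifti(nib.load(str(path)))


# ----------------------------------------------------------------- contours
def save_contours_json(contours: ContourStack, path) -> None:
    Path(path).write_text(contours.to_json())


def load_contours_json(path) -> ContourStack:
    return ContourStack.from_json(Path(path).read_text())


# ------------------------------------------------------------------- models
def save_pca_h5(model: PCAModel, path) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["kind"] = "lvshape-pca"
        f.attrs["topology_id"] = model.topology_id
        f.attrs["n_subjects"] = model.n_subjects
        if model.n_modes_selected is not None:
            f.attrs["n_modes_selected"] = model.n_modes_selected
        for name, data in (
            ("mean_shape", model.mean_shape),
            ("modes", model.modes),
            ("variances", model.variances),
            ("explained_ratio", model.explained_ratio),
        ):
            f.create_dataset(name, data=data, track_times=False)


def load_pca_h5(path) -> PCAModel:
    with h5py.File(path, "r") as f:
        return PCAModel(
            mean_shape=f["mean_shape"][()],
            modes=f["modes"][()],
            variances=f["variances"][()],
            explained_ratio=f["explained_ratio"][()],
            n_subjects=int(f.attrs["n_subjects"]),
            topology_id=str(f.attrs.get("topology_id", "")),
            n_modes_selected=(
                int(f.attrs["n_modes_selected"])
                if "n_modes_selected" in f.attrs
                else None
            ),
        )


def save_lda_h5(model: LDAModel, path) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["kind"] = "lvshape-lda"
        f.attrs["score_mean"] = model.score_mean
        f.attrs["score_sd"] = model.score_sd
        f.attrs["orientation_sign"] = model.orientation_sign
        f.attrs["labels"] = list(model.labels)
        f.attrs["shrinkage"] = str(model.shrinkage)
        f.create_dataset("weights", data=model.weights, track_times=False)
        f.create_dataset(
            "included_modes", data=np.asarray(model.included_modes), track_times=False
        )


def load_lda_h5(path) -> LDAModel:
    with h5py.File(path, "r") as f:
        shrink = str(f.attrs["shrinkage"])
        try:
            shrink = float(shrink)
        except ValueError:
            pass
        return LDAModel(
            weights=f["weights"][()],
            included_modes=f["included_modes"][()],
            score_mean=float(f.attrs["score_mean"]),
            score_sd=float(f.attrs["score_sd"]),
            orientation_sign=float(f.attrs["orientation_sign"]),
            labels=tuple(str(l) for l in f.attrs["labels"]),
            shrinkage=shrink,
        )
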