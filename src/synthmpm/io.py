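"""NIfTI-1 and JSON-sidecar input/output.

Weighted volumes are stored as 4-D NIfTI stacks (echo as the 4th axis) with
a JSON sidecar carrying the acquisition metadata (``tr_s``, ``fa_deg``,
``te_s``, ``contrast``, ``mt_pulse``); quantitative maps as 3-D NIfTI with a
sidecar holding ``kind``/``provenance``.  Volumes use an RAS affine scaled by
the isotropic voxel size.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import QuantitativeMap, WeightedVolume

log = logging.getLogger(__name__)

__all__ = [
    "load_map",
    "read_weighted_volume",
    "save_map",
    "save_weighted_volume",
    "sidecar_path",
]

REQUIRED_SIDECAR = ("tr_s", "fa_deg", "te_s", "contrast")


def sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def save_weighted_volume(volume: WeightedVolume, path, voxel_size_mm: float = 1.0):
    """Write a weighted volume as 4-D NIfTI plus JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(volume.echoes, 0, -1)  # (x, y, z, echo)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(voxel_size_mm)), path)
    meta = {"tr_s": volume.tr_s,
            "fa_deg": float(np.rad2deg(volume.flip_rad)),
            "te_s": list(volume.te_s),
            "contrast": volume.contrast,
            "mt_pulse": bool(volume.mt_pulse)}
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_weighted_volume(path, sidecar=None) -> WeightedVolume:
    """Read a 4-D weighted volume and its sidecar.

    Echoes are reordered by TE if the sidecar lists them out of order (a
    notice is logged).  Missing required sidecar fields raise ``KeyError``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_SIDECAR if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar} missing required fields: {missing}")

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    echoes = np.moveaxis(data, -1, 0)
    te = np.asarray(meta["te_s"], dtype=float)
    if te.shape[0] != echoes.shape[0]:
        raise ValueError(f"{te.shape[0]} echo times in sidecar for "
                         f"{echoes.shape[0]} echo images in {path.name}")
    order = np.argsort(te, kind="stable")
    if not np.array_equal(order, np.arange(te.size)):
        log.info("reordering echoes of %s by echo time", path.name)
        te = te[order]
        echoes = echoes[order]
    return WeightedVolume(echoes=echoes, te_s=tuple(te), tr_s=float(meta["tr_s"]),
                          flip_rad=float(np.deg2rad(meta["fa_deg"])),
                          contrast=meta["contrast"],
                          mt_pulse=bool(meta.get("mt_pulse", False)))


def save_map(qmap: QuantitativeMap, path, voxel_size_mm: float = 1.0):
    path = Path(path)
    nib.save(nib.Nifti1Image(qmap.values.astype(np.float32),
                             _affine(voxel_size_mm)), path)
    meta = {"kind": qmap.kind, "provenance": qmap.provenance, "units": qmap.units}
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_map(path) -> QuantitativeMap:
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    img = nib.load(path)
    return QuantitativeMap(np.asarray(img.dataobj, dtype=float),
                           kind=meta["kind"], provenance=meta["provenance"])
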