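"""Readers and writers for every format the pipeline touches.

Native formats are deliberately simple and text-friendly:

* volumes and structure masks: uncompressed MetaImage (.mha) written by a
  small built-in codec, or NIfTI (.nii/.nii.gz) through nibabel (converted
  to the LPS frame on read);
* planar images: 16-bit PNG plus a JSON sidecar carrying the projection
  geometry and the intensity scaling (so the round trip is lossless to the
  declared 16-bit quantization);
* contours, structures' slice polygons, mismatch-case manifests: JSON;
* ratings: CSV.

All serialized coordinates are millimetres in the LPS patient frame.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .backprojection import Contour2D, Structure3D
from .drr import PlanarImage, VoxelVolume
from .geometry import (ProjectionGeometry, RigidPose, geometry_from_dict,
                       geometry_to_dict)
from .mismatch import (MismatchErrorSpec, RatingRecord, RegistrationCase)

PathLike = Union[str, Path]

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def _write_mha(path: Path, values: np.ndarray, origin: np.ndarray,
               spacing: np.ndarray) -> None:
    arr = np.asarray(values)
    if arr.dtype not in _MET_NAMES:
        arr = arr.astype(np.float32)
    # MetaImage stores x fastest; our arrays are [ix, iy, iz] C-order, so
    # transpose before dumping
    raw = np.ascontiguousarray(arr.transpose(2, 1, 0))
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}\n"
        f"ElementSpacing = {spacing[0]:.17g} {spacing[1]:.17g} {spacing[2]:.17g}\n"
        f"Offset = {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}\n"
        "TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        "AnatomicalOrientation = LPS\n"
        f"ElementType = {_MET_NAMES[arr.dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(raw.tobytes())


def _read_mha(path: Path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    header: Dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: no ElementDataFile key found")
            key, _, val = line.decode("ascii", errors="replace").partition("=")
            key, val = key.strip(), val.strip()
            header[key] = val
            if key == "ElementDataFile":
                if val != "LOCAL":
                    raise ValueError("only ElementDataFile = LOCAL is supported")
                break
        if header.get("CompressedData", "False") == "True":
            raise ValueError("compressed MetaImage is not supported")
        if header.get("BinaryDataByteOrderMSB", "False") == "True":
            raise ValueError("big-endian MetaImage is not supported")
        dims = tuple(int(x) for x in header["DimSize"].split())
        dtype = _MET_TYPES[header["ElementType"]]
        raw = np.frombuffer(fh.read(), dtype=dtype)
    if raw.size != int(np.prod(dims)):
        raise ValueError(f"{path}: raw block size does not match DimSize")
    values = raw.reshape(dims[::-1]).transpose(2, 1, 0)
    spacing = np.array([float(x) for x in header.get(
        "ElementSpacing", "1 1 1").split()])
    origin = np.array([float(x) for x in header.get("Offset", "0 0 0").split()])
    return values, origin, spacing


def read_volume(path: PathLike) -> VoxelVolume:
    """Read a volume from .mha or NIfTI (.nii/.nii.gz).  NIfTI affines are
    converted from RAS to LPS; only axis-aligned orientations are
    accepted."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".mha":
        values, origin, spacing = _read_mha(path)
        return VoxelVolume(origin=origin, spacing=spacing, values=values.copy())
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        scales = np.diag(rot)
        vals = np.asanyarray(img.dataobj).astype(np.float32)
        origin_ras = aff[:3, 3].copy()
        # normalize to positive scales (index increases along +RAS axis)
        for i in range(3):
            if scales[i] < 0:
                vals = np.flip(vals, axis=i)
                origin_ras[i] = origin_ras[i] + scales[i] * (vals.shape[i] - 1)
        spacing = np.abs(scales)
        # RAS -> LPS negates x and y; flip those axes so indices again
        # increase along the +LPS axis, making the grid axis-aligned in LPS
        n = np.array(vals.shape)
        vals = np.flip(np.flip(vals, axis=0), axis=1).copy()
        origin_lps = np.array([
            -(origin_ras[0] + spacing[0] * (n[0] - 1)),
            -(origin_ras[1] + spacing[1] * (n[1] - 1)),
            origin_ras[2]])
        return VoxelVolume(origin=origin_lps, spacing=spacing, values=vals)
    raise ValueError(f"unsupported volume format: {path.name} "
                     "(supported: .mha, .nii, .nii.gz)")


def write_volume(volume: VoxelVolume, path: PathLike) -> None:
    """Write a volume; .mha round-trips origin, spacing, dims and values
    exactly (float32)."""
    path = Path(path)
    if path.suffix == ".mha":
        _write_mha(path, volume.values, volume.origin, volume.spacing)
        return
    suffixes = "".join(path.suffixes)
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        # LPS -> RAS: flip x and y
        vals = np.flip(np.flip(np.asarray(volume.values), axis=0), axis=1)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = volume.spacing
        hi = volume.origin[:2] + volume.spacing[:2] * (np.array(volume.dims[:2]) - 1)
        aff[0, 3] = -hi[0]
        aff[1, 3] = -hi[1]
        aff[2, 3] = volume.origin[2]
        nib.save(nib.Nifti1Image(np.asarray(vals), aff), str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# Planar images (PNG + JSON geometry sidecar)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_planar(image: PlanarImage, path: PathLike) -> None:
    """16-bit PNG plus JSON sidecar (geometry, kind, intensity scale)."""
    import imageio.v3 as iio

    path = Path(path)
    vals = image.values
    vmin, vmax = float(vals.min()), float(vals.max())
    scale = (vmax - vmin) or 1.0
    quant = np.round((vals - vmin) / scale * 65535).astype(np.uint16)
    # PNG rows are the v axis; values are indexed [iu, iv]
    iio.imwrite(path, quant.T)
    sidecar = {
        "kind": image.kind,
        "vmin": vmin,
        "vmax": vmax,
        "geometry": geometry_to_dict(image.geometry),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_planar(path: PathLike) -> PlanarImage:
    import imageio.v3 as iio

    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"geometry sidecar {sidecar_file.name} is missing; planar images "
            "without geometry are rejected")
    sidecar = json.loads(sidecar_file.read_text())
    quant = np.asarray(iio.imread(path)).T.astype(float)
    vmin, vmax = sidecar["vmin"], sidecar["vmax"]
    vals = vmin + quant / 65535 * ((vmax - vmin) or 1.0)
    return PlanarImage(values=vals,
                       geometry=geometry_from_dict(sidecar["geometry"]),
                       kind=sidecar.get("kind", "drr"))


def write_geometry(geometry: ProjectionGeometry, path: PathLike) -> None:
    Path(path).write_text(json.dumps(geometry_to_dict(geometry), indent=1))


def read_geometry(path: PathLike) -> ProjectionGeometry:
    return geometry_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Contours and structures
# ---------------------------------------------------------------------------


def write_contour2d(contour: Contour2D, path: PathLike) -> None:
    Path(path).write_text(json.dumps({
        "view_label": contour.view_label,
        "name": contour.name,
        "units": "mm",
        "vertices": contour.vertices.tolist(),
    }, indent=1))


def read_contour2d(path: PathLike) -> Contour2D:
    d = json.loads(Path(path).read_text())
    return Contour2D(view_label=d["view_label"],
                     vertices=np.array(d["vertices"], dtype=float),
                     name=d.get("name", "target"))


def write_structure3d(structure: Structure3D, mask_path: PathLike,
                      contours_path: Optional[PathLike] = None) -> None:
    """Mask as .mha (uint8) and, optionally, per-slice polygons as JSON."""
    _write_mha(Path(mask_path), structure.mask.astype(np.uint8),
               structure.origin, structure.spacing)
    if contours_path is not None:
        slices = {str(k): [p.tolist() for p in polys]
                  for k, polys in structure.slice_contours().items()}
        Path(contours_path).write_text(json.dumps({
            "name": structure.name,
            "frame": structure.frame,
            "units": "mm",
            "slice_contours": slices,
        }, indent=1))


def read_structure3d(mask_path: PathLike, name: str = "structure") -> Structure3D:
    values, origin, spacing = _read_mha(Path(mask_path))
    return Structure3D(mask=values.astype(bool), origin=origin,
                       spacing=spacing, name=name)


# ---------------------------------------------------------------------------
# Mismatch-study manifests and ratings
# ---------------------------------------------------------------------------


def _pose_to_dict(p: RigidPose) -> dict:
    return {"tx": p.tx, "ty": p.ty, "tz": p.tz,
            "rx": p.rx, "ry": p.ry, "rz": p.rz}


def _pose_from_dict(d: dict) -> RigidPose:
    return RigidPose(**d)


def write_case_manifest(cases: Sequence[RegistrationCase], path: PathLike) -> None:
    out = []
    for c in cases:
        out.append({
            "case_id": c.case_id,
            "subject_id": c.subject_id,
            "reference_pose": _pose_to_dict(c.reference_pose),
            "error": None if c.error is None else {
                "type": c.error.type, "magnitude": c.error.magnitude,
                "axis": c.error.axis},
            "order_index": c.order_index,
        })
    Path(path).write_text(json.dumps(out, indent=1))


def read_case_manifest(path: PathLike) -> List[RegistrationCase]:
    raw = json.loads(Path(path).read_text())
    cases = []
    for d in raw:
        err = d["error"]
        cases.append(RegistrationCase(
            case_id=d["case_id"],
            subject_id=d["subject_id"],
            reference_pose=_pose_from_dict(d["reference_pose"]),
            error=None if err is None else MismatchErrorSpec(**err),
            order_index=d["order_index"]))
    return cases


def write_ratings(records: Sequence[RatingRecord], path: PathLike) -> None:
    pd.DataFrame([{"case_id": r.case_id, "user_id": r.user_id,
                   "decision": r.decision, "correct": r.correct}
                  for r in records]).to_csv(path, index=False)


def read_ratings(path: PathLike) -> List[RatingRecord]:
    df = pd.read_csv(path)
    return [RatingRecord(case_id=row.case_id, user_id=str(row.user_id),
                         decision=row.decision, correct=bool(row.correct))
            for row in df.itertuples()]
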