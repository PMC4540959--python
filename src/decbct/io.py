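"""File I/O: HDF5 containers for projections and look-up tables, MetaImage volumes."""

from __future__ import annotations

import json

import h5py
import numpy as np
import SimpleITK as sitk

from .decomposition import BasisProjections, DecompositionLUT
from .geometry import ScanGeometry
from .materials import BasisPair, Material
from .projector import ProjectionSet
from .reconstruction import Volume
from .spectrum import Spectrum

__all__ = [
    "save_projections", "load_projections",
    "save_basis_projections", "load_basis_projections",
    "save_lut", "load_lut",
    "write_volume_mha", "read_volume_mha",
]


def _geom_to_attrs(grp, geom: ScanGeometry) -> None:
    for f in ScanGeometry.__dataclass_fields__:
        grp.attrs[f"geom_{f}"] = getattr(geom, f)


def _geom_from_attrs(grp) -> ScanGeometry:
    kw = {}
    for f, spec in ScanGeometry.__dataclass_fields__.items():
        val = grp.attrs[f"geom_{f}"]
        kw[f] = int(val) if spec.type == "int" else float(val)
    return ScanGeometry(**kw)


def save_projections(path, *sets: ProjectionSet, names: tuple[str, ...] = ("gH", "gL")) -> None:
    """Write one or more projection sets (datasets /gH, /gL, ...) to HDF5."""
    with h5py.File(path, "w") as f:
        _geom_to_attrs(f, sets[0].geometry)
        for name, p in zip(names, sets):
            d = f.create_dataset(name, data=p.values, compression="gzip")
            d.attrs["spectrum_id"] = p.spectrum_id
            d.attrs["convention"] = p.convention


def load_projections(path, names: tuple[str, ...] = ("gH", "gL")) -> tuple[ProjectionSet, ...]:
    out = []
    with h5py.File(path, "r") as f:
        geom = _geom_from_attrs(f)
        for name in names:
            d = f[name]
            out.append(ProjectionSet(d[...], geom, spectrum_id=d.attrs["spectrum_id"],
                                     convention=d.attrs["convention"]))
    return tuple(out)


def save_basis_projections(path, bp: BasisProjections) -> None:
    with h5py.File(path, "w") as f:
        _geom_to_attrs(f, bp.geometry)
        f.create_dataset("B1", data=bp.B1, compression="gzip")
        f.create_dataset("B2", data=bp.B2, compression="gzip")
        f.attrs["provenance"] = bp.provenance
        f.attrs["n_nonconverged"] = bp.n_nonconverged


def load_basis_projections(path) -> BasisProjections:
    with h5py.File(path, "r") as f:
        return BasisProjections(
            f["B1"][...], f["B2"][...], _geom_from_attrs(f),
            provenance=str(f.attrs["provenance"]),
            n_nonconverged=int(f.attrs["n_nonconverged"]),
        )


def _material_to_json(m: Material) -> str:
    return json.dumps({"name": m.name, "composition": dict(m.composition), "density": m.density})


def _material_from_json(s: str) -> Material:
    d = json.loads(s)
    return Material(d["name"], d["composition"], d["density"])


def save_lut(path, lut: DecompositionLUT) -> None:
    """LUT container: /d1_grid /d2_grid /gH /gL plus basis and spectra attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("d1_grid", data=lut.d1_grid)
        f.create_dataset("d2_grid", data=lut.d2_grid)
        f.create_dataset("gH", data=lut.gH_table)
        f.create_dataset("gL", data=lut.gL_table)
        f.attrs["material1"] = _material_to_json(lut.basis.material1)
        f.attrs["material2"] = _material_to_json(lut.basis.material2)
        f.attrs["rho_e1"] = lut.basis.rho_e1
        f.attrs["rho_e2"] = lut.basis.rho_e2
        for tag, s in zip(("H", "L"), lut.spectra):
            f.create_dataset(f"spectrum_{tag}/energies", data=s.energies)
            f.create_dataset(f"spectrum_{tag}/weights", data=s.weights)
            f[f"spectrum_{tag}"].attrs["kvp"] = s.kvp
            f[f"spectrum_{tag}"].attrs["description"] = s.description


def load_lut(path) -> DecompositionLUT:
    with h5py.File(path, "r") as f:
        basis = BasisPair(
            _material_from_json(f.attrs["material1"]),
            _material_from_json(f.attrs["material2"]),
            float(f.attrs["rho_e1"]), float(f.attrs["rho_e2"]),
        )
        spectra = tuple(
            Spectrum(f[f"spectrum_{tag}/energies"][...], f[f"spectrum_{tag}/weights"][...],
                     kvp=float(f[f"spectrum_{tag}"].attrs["kvp"]),
                     description=str(f[f"spectrum_{tag}"].attrs["description"]))
            for tag in ("H", "L")
        )
        return DecompositionLUT(f["d1_grid"][...], f["d2_grid"][...],
                                f["gH"][...], f["gL"][...], basis, spectra)


def write_volume_mha(path, v: Volume) -> None:
    """Write a volume as MetaImage with quantity and provenance metadata."""
    arr = v.values if v.values.ndim == 3 else v.values[None, ...]
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((v.voxel_size,) * 3)
    ox, oy = v.origin[0], v.origin[1]
    oz = v.origin[2] if len(v.origin) > 2 else 0.0
    img.SetOrigin((ox, oy, oz))
    img.SetMetaData("quantity", v.quantity)
    img.SetMetaData("provenance", json.dumps(v.provenance, default=str))
    sitk.WriteImage(img, str(path))


def read_volume_mha(path) -> Volume:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float)
    if arr.shape[0] == 1:
        arr = arr[0]
    quantity = img.GetMetaData("quantity") if img.HasMetaDataKey("quantity") else "mu"
    prov = (json.loads(img.GetMetaData("provenance"))
            if img.HasMetaDataKey("provenance") else {})
    origin = img.GetOrigin()
    return Volume(arr, img.GetSpacing()[0], tuple(origin), quantity, prov)
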