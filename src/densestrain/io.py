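"""HDF5 / CSV / NIfTI plumbing for phantom subjects and result tables.

One HDF5 container per subject:

* ``/slice_<k>/phase_dir1..3`` wrapped phase maps, ``magnitude``, ``mask``,
  ``contour_endo`` / ``contour_epi`` polygons; attributes carry the encoding
  scheme, pixel spacing and slice metadata.
* ``/truth/slice_<k>/displacement`` (2, H, W) mm plus per-direction strain
  maps, and ``/truth/scar_fractions`` (16,) — the ground-truth sidecar.

Contours are additionally exportable as CSV polygon point lists
(columns x_mm, y_mm, role).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .anatomy import ContourSet
from .dense_sim import ComplexImageSet, EncodingScheme
from .phantom import PhantomSlice, Subject
from .recon import DisplacementField

__all__ = ["write_subject_h5", "read_subject_h5", "contours_to_csv",
           "contours_from_csv", "export_nifti"]

_META_KEYS = ("subject_id", "slice_kind", "level", "view", "frame_label",
              "reference_angle_deg")


def write_subject_h5(path, subject: Subject) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = subject.subject_id
        f.attrs["group"] = subject.group
        f.attrs["n_slices"] = len(subject.slices)
        truth = f.create_group("truth")
        truth.create_dataset("scar_fractions", data=np.asarray(subject.scar_fractions))
        for k, sl in enumerate(subject.slices):
            g = f.create_group(f"slice_{k}")
            img = sl.images
            for d in range(img.phases.shape[0]):
                g.create_dataset(f"phase_dir{d + 1}", data=img.phases[d])
            g.create_dataset("magnitude", data=img.magnitude)
            g.create_dataset("mask", data=img.mask.astype(np.uint8))
            g.create_dataset("contour_endo", data=sl.contours.endo)
            g.create_dataset("contour_epi", data=sl.contours.epi)
            g.attrs["ke_cycles_per_pixel"] = img.scheme.ke_cycles_per_pixel
            g.attrs["directions"] = img.scheme.direction_matrix
            g.attrs["pixel_spacing_mm"] = img.pixel_spacing_mm
            for key in _META_KEYS:
                val = img.meta.get(key)
                if val is None and key == "reference_angle_deg":
                    val = sl.contours.reference_angle_deg
                g.attrs[key] = "" if val is None else val
            if sl.truth_displacement is not None:
                tg = truth.create_group(f"slice_{k}")
                tg.create_dataset("displacement", data=sl.truth_displacement.u)
                for name, arr in (sl.truth_strain or {}).items():
                    tg.create_dataset(f"strain_{name}", data=arr)


def read_subject_h5(path) -> Subject:
    import h5py

    slices = []
    with h5py.File(path, "r") as f:
        subject_id = str(f.attrs["subject_id"])
        group = str(f.attrs["group"])
        n_slices = int(f.attrs["n_slices"])
        fractions = np.asarray(f["truth/scar_fractions"])
        for k in range(n_slices):
            g = f[f"slice_{k}"]
            scheme = EncodingScheme(
                ke_cycles_per_pixel=float(g.attrs["ke_cycles_per_pixel"]),
                directions=tuple(map(tuple, np.asarray(g.attrs["directions"]))))
            phases = np.stack([np.asarray(g[f"phase_dir{d + 1}"])
                               for d in range(scheme.n_directions)])
            mask = np.asarray(g["mask"]).astype(bool)
            spacing = float(g.attrs["pixel_spacing_mm"])
            meta = {}
            for key in _META_KEYS:
                val = g.attrs.get(key, "")
                if isinstance(val, bytes):
                    val = val.decode()
                meta[key] = None if val == "" else val
            if meta.get("reference_angle_deg") is not None:
                meta["reference_angle_deg"] = float(meta["reference_angle_deg"])
            images = ComplexImageSet(phases, np.asarray(g["magnitude"]), mask,
                                     scheme, spacing, meta)
            contours = ContourSet(np.asarray(g["contour_endo"]),
                                  np.asarray(g["contour_epi"]),
                                  slice_kind=meta["slice_kind"],
                                  level=meta.get("level") or "mid",
                                  view=meta.get("view"),
                                  reference_angle_deg=meta.get("reference_angle_deg", 90.0))
            truth_disp = None
            truth_strain = None
            tkey = f"truth/slice_{k}"
            if tkey in f:
                tg = f[tkey]
                truth_disp = DisplacementField(np.asarray(tg["displacement"]), mask,
                                               spacing, provenance="ground-truth")
                truth_strain = {name[len("strain_"):]: np.asarray(tg[name])
                                for name in tg if name.startswith("strain_")}
            slices.append(PhantomSlice(geom=None, deform=None, contours=contours,
                                       mask=mask, images=images,
                                       truth_displacement=truth_disp,
                                       truth_strain=truth_strain))
    return Subject(subject_id, group, slices, fractions)


def contours_to_csv(contours: ContourSet, path) -> None:
    rows = [{"x_mm": x, "y_mm": y, "role": "endo"} for x, y in contours.endo]
    rows += [{"x_mm": x, "y_mm": y, "role": "epi"} for x, y in contours.epi]
    pd.DataFrame(rows).to_csv(path, index=False)


def contours_from_csv(path, **kwargs) -> ContourSet:
    df = pd.read_csv(path)
    endo = df[df["role"] == "endo"][["x_mm", "y_mm"]].to_numpy()
    epi = df[df["role"] == "epi"][["x_mm", "y_mm"]].to_numpy()
    return ContourSet(endo, epi, **kwargs)


def export_nifti(array: np.ndarray, pixel_spacing_mm: float, path) -> None:
    """Write a 2-D map (or stack) as NIfTI for viewing in standard tools."""
    import nibabel as nib

    data = np.asarray(array, dtype=np.float32)
    if data.ndim == 2:
        data = data[..., None]
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
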