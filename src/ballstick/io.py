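"""NIfTI and FSL-dialect bvals/bvecs input, and result-map output.

bvecs are interpreted in the image coordinate frame exactly as given: no
gradient-table reorientation of any kind is applied.  If your bvecs were
produced in scanner coordinates, reorient them before fitting.
"""

from __future__ import annotations

import os
import warnings

import nibabel as nib
import numpy as np

from .model import B0_THRESHOLD, AcquisitionScheme
from .summaries import VolumeResult

__all__ = ["read_inputs", "read_scheme", "write_results", "write_phantom"]


def read_scheme(bvecs_path: str, bvals_path: str) -> AcquisitionScheme:
    """Load an acquisition scheme from FSL-style text files.

    bvecs may be 3 rows x K columns or the transpose (auto-detected);
    bvals is a whitespace-separated list of K values.  Non-unit gradient
    directions are renormalised with a warning; measurements with
    b < 50 s/mm^2 are flagged as unweighted.
    """
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.ndim != 2:
        raise ValueError(f"bvecs file {bvecs_path!r} is not a 2D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"bvecs must be 3xK or Kx3, got {bvecs.shape}")
    if bvals.shape[0] != bvecs.shape[0]:
        raise ValueError(
            f"bvals has {bvals.shape[0]} entries but bvecs has {bvecs.shape[0]} rows"
        )
    b0 = bvals < B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    fix = (~b0) & (np.abs(norms - 1.0) > 1e-6)
    if fix.any():
        warnings.warn(
            f"renormalising {int(fix.sum())} non-unit gradient directions",
            stacklevel=2,
        )
        bvecs[fix] /= norms[fix, None]
    bvecs[b0 & (norms == 0)] = 0.0
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs, b0_mask=b0)


def read_inputs(
    data_path: str, mask_path: str, bvecs_path: str, bvals_path: str
) -> tuple[np.ndarray, np.ndarray, AcquisitionScheme, nib.Nifti1Image]:
    """Load a 4D acquisition, its brain mask and gradient table.

    Returns (data4d, mask, scheme, reference image); the reference image
    carries the affine/header that result maps are written with.
    """
    img = nib.load(data_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got shape {data.shape}")
    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match data spatial dims {data.shape[:3]}"
        )
    scheme = read_scheme(bvecs_path, bvals_path)
    if scheme.n_measurements != data.shape[3]:
        raise ValueError(
            f"gradient table has {scheme.n_measurements} entries but data has "
            f"{data.shape[3]} volumes"
        )
    return data, mask, scheme, img


def _save(arr: np.ndarray, ref: nib.Nifti1Image | None, path: str) -> None:
    affine = ref.affine if ref is not None else np.eye(4)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
    nib.save(img, path)


def write_results(
    result: VolumeResult, out_dir: str, ref: nib.Nifti1Image | None = None
) -> list[str]:
    """Write posterior summary maps as 32-bit float NIfTI volumes.

    Produces mean_S0samples, mean_dsamples and, per stick j,
    mean_f{j}samples, dyads{j} (a 4D volume whose last axis holds the
    direction components) and dispersion{j}; plus merged retained-sample
    4D volumes for any parameter kept in ``result.samples``.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def save(arr: np.ndarray, name: str) -> None:
        path = os.path.join(out_dir, name + ".nii.gz")
        _save(arr, ref, path)
        written.append(path)

    save(result.mean_S0, "mean_S0samples")
    save(result.mean_d, "mean_dsamples")
    for j in range(result.n_sticks):
        save(result.mean_f[j], f"mean_f{j + 1}samples")
        save(result.dyads[j], f"dyads{j + 1}")
        save(result.dispersion[j], f"dispersion{j + 1}")
    for name, arr in result.samples.items():
        save(arr, f"merged_{name}samples")
    return written


def write_phantom(
    data4d: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    truth: dict[str, np.ndarray],
    out_dir: str,
) -> dict[str, str]:
    """Write a synthetic phantom in the same formats :func:`read_inputs` reads.

    data.nii.gz + mask.nii.gz + bvals/bvecs text files, with ground-truth
    sidecar volumes (truth_*.nii.gz) alongside.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "data": os.path.join(out_dir, "data.nii.gz"),
        "mask": os.path.join(out_dir, "mask.nii.gz"),
        "bvals": os.path.join(out_dir, "bvals"),
        "bvecs": os.path.join(out_dir, "bvecs"),
    }
    _save(data4d, None, paths["data"])
    _save(mask.astype(np.float32), None, paths["mask"])
    np.savetxt(paths["bvals"], scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(paths["bvecs"], scheme.bvecs.T, fmt="%.8f")  # FSL 3xK layout
    for key in ("S0", "d", "label"):
        p = os.path.join(out_dir, f"truth_{key}.nii.gz")
        _save(truth[key].astype(np.float32), None, p)
        paths[f"truth_{key}"] = p
    for j in range(truth["f"].shape[0]):
        p = os.path.join(out_dir, f"truth_f{j + 1}.nii.gz")
        _save(truth["f"][j], None, p)
        paths[f"truth_f{j + 1}"] = p
        p = os.path.join(out_dir, f"truth_dyads{j + 1}.nii.gz")
        _save(truth["dirs"][j], None, p)
        paths[f"truth_dyads{j + 1}"] = p
    return paths
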