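"""NIfTI / gradient-table I/O for the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import read_bvals, read_bvecs


def read_dwi(dwi_path, bval_path, bvec_path, mask_path=None, noise_path=None,
             bvec_tol: float = 1e-3) -> dict:
    """Load a 4D DWI dataset with its gradient table.

    Returns a dict with ``dwi`` (X,Y,Z,N float array), ``affine``,
    ``bvals`` converted to ms/um^2, ``bvecs`` (3,N, unit vectors in the
    image frame), and optional ``mask`` / ``sigma`` volumes. Volume-count
    mismatches and non-unit bvecs (beyond ``bvec_tol``) raise.
    """
    img = nib.load(str(dwi_path))
    dwi = np.asarray(img.get_fdata(), dtype=float)
    if dwi.ndim != 4:
        raise ValueError(f"expected a 4D DWI volume, got shape {dwi.shape}")
    bvals = read_bvals(bval_path) / 1000.0  # s/mm^2 -> ms/um^2
    bvecs = read_bvecs(bvec_path)
    n_vol = dwi.shape[-1]
    if bvals.size != n_vol:
        raise ValueError(f"bval count {bvals.size} != volume count {n_vol}")
    if bvecs.shape[1] != n_vol:
        raise ValueError(f"bvec count {bvecs.shape[1]} != volume count {n_vol}")
    norms = np.linalg.norm(bvecs, axis=0)
    dw = bvals > 0.05
    bad = dw & (np.abs(norms - 1.0) > bvec_tol)
    if np.any(bad):
        raise ValueError(
            f"{bad.sum()} diffusion-weighted bvecs deviate from unit norm "
            f"beyond tolerance {bvec_tol}"
        )
    out = {"dwi": dwi, "affine": img.affine, "bvals": bvals, "bvecs": bvecs}
    if mask_path is not None:
        out["mask"] = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    if noise_path is not None:
        out["sigma"] = np.asarray(nib.load(str(noise_path)).get_fdata(), dtype=float)
    return out


def save_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D/4D parameter map carrying the input affine."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
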