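"""NIfTI and b-value file helpers.

Thin wrappers around nibabel that preserve the input affine/header when
writing derived parameter maps.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .ivim import BValueScheme, VolumeFitResult

__all__ = ["load_nifti", "save_like", "read_bvals", "save_parameter_maps"]


def load_nifti(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img


def save_like(data: np.ndarray, reference: nib.Nifti1Image, path) -> None:
    """Write ``data`` with the reference image's affine and header."""
    out = nib.Nifti1Image(np.asarray(data, dtype=np.float32), reference.affine, reference.header)
    out.header.set_data_dtype(np.float32)
    nib.save(out, str(path))


def read_bvals(path) -> BValueScheme:
    return BValueScheme.from_file(path)


def save_parameter_maps(
    fit: VolumeFitResult, reference: nib.Nifti1Image, prefix
) -> dict[str, str]:
    """Write D, D*, f, and validity maps next to ``prefix``; returns paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("D", fit.d),
        ("Dstar", fit.d_star),
        ("f", fit.f),
        ("valid", fit.valid.astype(np.float32)),
    ):
        p = f"{prefix}_{name}.nii.gz"
        save_like(arr, reference, p)
        paths[name] = p
    return paths
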