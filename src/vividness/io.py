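"""File formats: TSV trial tables, HDF5 epoch containers, NIfTI beta volumes.

Epoch container layout (HDF5): ``/data`` (float32, trials x sensors x
samples), ``/time_ms`` (float64), ``/labels/<column>`` (one dataset per trial
-table column, strings as UTF-8), root attributes ``subject_id`` and
``sfreq_hz``.  Round trips are bit-exact (data are stored and compared as
float32).

Beta volumes: one NIfTI-1 4D image (x, y, z, trial) plus a NIfTI-1 mask and a
TSV label table; the affine is stored as the NIfTI sform and voxel indices
are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import SFREQ_HZ, EpochedRecording, TrialBetaVolume

__all__ = [
    "save_trial_table", "load_trial_table",
    "save_epochs", "load_epochs",
    "save_beta_volume", "load_beta_volume",
]


def save_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_epochs(rec: EpochedRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("time_ms", data=rec.time_ms.astype(np.float64))
        grp = f.create_group("labels")
        for col in rec.labels.columns:
            values = rec.labels[col].to_numpy()
            if values.dtype.kind in ("O", "U"):
                grp.create_dataset(col, data=[str(v) for v in values],
                                   dtype=h5py.string_dtype("utf-8"))
            else:
                grp.create_dataset(col, data=values)
        grp.attrs["columns"] = list(rec.labels.columns)
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["sfreq_hz"] = SFREQ_HZ


def load_epochs(path: str | Path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()].astype(np.float32)
        time_ms = f["time_ms"][()]
        cols = list(f["labels"].attrs["columns"])
        frame = {}
        for col in cols:
            v = f["labels"][col][()]
            if v.dtype.kind in ("O", "S"):
                v = np.array([s.decode() if isinstance(s, bytes) else s for s in v])
            frame[col] = v
        labels = pd.DataFrame(frame, columns=cols)
        subject_id = f.attrs["subject_id"]
    return EpochedRecording(data, time_ms, labels, str(subject_id))


def save_beta_volume(vol: TrialBetaVolume, prefix: str | Path) -> None:
    """Write ``<prefix>_betas.nii``, ``<prefix>_mask.nii`` and ``<prefix>_labels.tsv``."""
    prefix = Path(prefix)
    grid = np.zeros(vol.grid_shape + (vol.betas.shape[0],), dtype=np.float32)
    grid[vol.mask] = vol.betas.T.astype(np.float32)
    img = nib.Nifti1Image(grid, vol.affine)
    img.set_sform(vol.affine)
    nib.save(img, str(prefix) + "_betas.nii")
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), str(prefix) + "_mask.nii")
    save_trial_table(vol.labels, str(prefix) + "_labels.tsv")


def load_beta_volume(prefix: str | Path) -> TrialBetaVolume:
    img = nib.load(str(prefix) + "_betas.nii")
    mask = nib.load(str(prefix) + "_mask.nii").get_fdata().astype(bool)
    labels = load_trial_table(str(prefix) + "_labels.tsv")
    betas = np.asarray(img.dataobj)[mask].T
    return TrialBetaVolume(betas, mask, img.get_sform(), labels)
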