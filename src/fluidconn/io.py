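"""File I/O: delimited-text signal matrices, EDF recordings, cohort tables,
and NIfTI volumes/masks.

Signal text format: tab-separated, one region per row, first column the
region label, preceded by ``# key=value`` header lines carrying the sampling
rate and optional metadata. EDF reading goes through MNE; signal *writing* is
text-only (the EDF export backend is a separate optional dependency of MNE).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lc_contrast import LCVolume
from .signals import RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_signals",
    "read_signals_text",
    "read_signals_edf",
    "write_signals_text",
    "read_cohort",
    "write_cohort",
    "save_lc_volume",
    "load_lc_volume",
]


def write_signals_text(ts: RegionTimeSeries, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={ts.fs}\n")
        if ts.subject_id:
            fh.write(f"# subject_id={ts.subject_id}\n")
        if ts.band:
            fh.write(f"# band={ts.band}\n")
        for label, row in zip(ts.region_labels, ts.data):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_signals_text(path, fs: float | None = None) -> RegionTimeSeries:
    path = Path(path)
    meta = {}
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    fs = fs if fs is not None else float(meta.get("fs", 0) or 0)
    if fs <= 0:
        raise ValueError("sampling rate missing: no '# fs=' header and no fs given")
    return RegionTimeSeries(
        data=np.array(rows),
        fs=fs,
        region_labels=labels,
        band=meta.get("band") or None,
        subject_id=meta.get("subject_id") or None,
    )


def read_signals_edf(path) -> RegionTimeSeries:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RegionTimeSeries(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        region_labels=list(raw.ch_names),
        subject_id=Path(path).stem,
    )


def read_signals(path, fs: float | None = None) -> RegionTimeSeries:
    """Dispatch on suffix: ``.edf`` via MNE, anything else as delimited text."""
    if str(path).lower().endswith(".edf"):
        return read_signals_edf(path)
    return read_signals_text(path, fs=fs)


def write_cohort(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_lc_volume(vol: LCVolume, out_dir) -> dict:
    """Write intensities and masks as NIfTI files; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    paths = {}

    def _save(name, arr, dtype):
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), p)
        paths[name] = p

    _save("volume", vol.intensities, np.float64)
    _save("pt_mask", vol.pt_mask, np.uint8)
    for side, mask in vol.lc_search_masks.items():
        _save(f"lc_mask_{side}", mask, np.uint8)
    if vol.ventricle_mask is not None:
        _save("ventricle_mask", vol.ventricle_mask, np.uint8)
    return paths


def load_lc_volume(
    volume_path,
    lc_mask_left,
    lc_mask_right,
    pt_mask,
    ventricle_mask=None,
    slice_axis: int = 2,
    rostral_positive: bool = True,
) -> LCVolume:
    img = nib.load(str(volume_path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])

    def _mask(p):
        return np.asarray(nib.load(str(p)).dataobj) > 0

    return LCVolume(
        intensities=np.asarray(img.dataobj, dtype=float),
        voxel_size=voxel_size,
        lc_search_masks={"left": _mask(lc_mask_left), "right": _mask(lc_mask_right)},
        pt_mask=_mask(pt_mask),
        ventricle_mask=None if ventricle_mask is None else _mask(ventricle_mask),
        slice_axis=slice_axis,
        rostral_positive=rostral_positive,
    )
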