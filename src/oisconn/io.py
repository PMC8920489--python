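"""File formats: TIFF / HDF5 stacks in, HDF5 + TIFF + CSV artifacts out.

Conventions: image stacks are (frames, rows, cols); HDF5 series live in a
dataset named ``series`` with ``fs`` and provenance stored as attributes;
masks and parcellations are single-frame TIFF label images; pixel order is
row-major over the mask everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .preprocess import BrainMask, NormalizedSeries, Parcellation, RawSeries
from .synthetic import SyntheticDataset

__all__ = [
    "load_mask",
    "save_mask",
    "load_run",
    "save_run",
    "save_normalized",
    "load_normalized",
    "save_dataset",
    "save_matrices",
    "save_json",
]

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _read_stack(path: Path) -> tuple[np.ndarray, dict]:
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "series" not in f:
                raise ValueError(f"{path}: no 'series' dataset")
            ds = f["series"]
            return np.asarray(ds), dict(ds.attrs)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return np.asarray(tifffile.imread(path)), {}
    raise ValueError(f"{path}: expected a TIFF or HDF5 stack")


def load_mask(path: str | Path) -> BrainMask:
    img = tifffile.imread(Path(path))
    return BrainMask.from_image(np.asarray(img) > 0)


def save_mask(mask: BrainMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.image.astype(np.uint8))


def load_parcellation(path: str | Path, mask: BrainMask) -> Parcellation:
    labels = np.asarray(tifffile.imread(Path(path)), dtype=int)
    return Parcellation.from_labels(labels, mask)


def save_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    tifffile.imwrite(Path(path), parcellation.labels.astype(np.int32))


def load_run(path: str | Path, mask_path: str | Path,
             fs: float | None = None, run_id: str | None = None) -> RawSeries:
    """Read a multi-frame TIFF/HDF5 stack into a masked pixel×time matrix.

    ``fs`` is taken from the HDF5 attributes when present; for TIFF input
    it must be given explicitly.
    """
    path = Path(path)
    frames, attrs = _read_stack(path)
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a (frames, rows, cols) stack, "
                         f"got shape {frames.shape}")
    mask = load_mask(mask_path)
    if frames.shape[1:] != mask.shape:
        raise ValueError(f"{path}: frame shape {frames.shape[1:]} does not "
                         f"match mask shape {mask.shape}")
    fs = attrs.get("fs", fs)
    if fs is None:
        raise ValueError(f"{path}: sampling rate not in attributes; pass fs=")
    rid = run_id or attrs.get("run_id", path.stem)
    return RawSeries(data=mask.extract(frames), fs=float(fs), mask=mask,
                     run_id=str(rid))


def save_run(raw: RawSeries, path: str | Path) -> None:
    """Write a raw series as an HDF5 stack (zeros outside the mask)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("series", data=raw.to_frames(fill=0.0))
        ds.attrs["fs"] = raw.fs
        ds.attrs["run_id"] = raw.run_id
        ds.attrs["provenance"] = json.dumps(list(raw.provenance))
        f.create_dataset("mask", data=raw.mask.image.astype(np.uint8))


def save_normalized(series: NormalizedSeries, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        ds = f.create_dataset("data", data=series.data)
        ds.attrs["fs"] = series.fs
        ds.attrs["provenance"] = json.dumps(list(series.provenance))
        ds.attrs["run_boundaries"] = list(series.run_boundaries)
        if series.parcel_ids is not None:
            ds.attrs["parcel_ids"] = list(series.parcel_ids)
        f.create_dataset("mask", data=series.mask.image.astype(np.uint8))


def load_normalized(path: str | Path) -> NormalizedSeries:
    with h5py.File(Path(path), "r") as f:
        ds = f["data"]
        mask = BrainMask.from_image(np.asarray(f["mask"]) > 0)
        parcel_ids = ds.attrs.get("parcel_ids")
        return NormalizedSeries(
            data=np.asarray(ds), fs=float(ds.attrs["fs"]), mask=mask,
            provenance=tuple(json.loads(ds.attrs["provenance"])),
            run_boundaries=tuple(int(b) for b in ds.attrs["run_boundaries"]),
            parcel_ids=None if parcel_ids is None else tuple(
                int(i) for i in parcel_ids))


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                 fmt: str = "hdf5") -> dict[str, Path]:
    """Write a synthetic run: series stack, mask/parcel TIFFs, truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    frames = dataset.raw.to_frames(fill=0.0)
    if fmt == "hdf5":
        paths["series"] = out / "series.h5"
        with h5py.File(paths["series"], "w") as f:
            ds = f.create_dataset("series", data=frames)
            ds.attrs["fs"] = dataset.raw.fs
            ds.attrs["run_id"] = dataset.raw.run_id
            ds.attrs["seed"] = dataset.seed
    elif fmt == "tiff":
        paths["series"] = out / "series.tif"
        tifffile.imwrite(paths["series"], frames.astype(np.float32))
    else:
        raise ValueError("fmt must be 'hdf5' or 'tiff'")
    paths["mask"] = out / "mask.tif"
    save_mask(dataset.mask, paths["mask"])
    paths["parcellation"] = out / "parcellation.tif"
    save_parcellation(dataset.parcellation, paths["parcellation"])
    paths["truth_corr"] = out / "truth_corr.csv"
    pd.DataFrame(dataset.truth_corr).to_csv(paths["truth_corr"], index=False)
    paths["truth_tau"] = out / "truth_tau.csv"
    pd.DataFrame({"pixel": np.arange(dataset.mask.n_pixels),
                  "tau": dataset.truth_tau}).to_csv(paths["truth_tau"],
                                                    index=False)
    return paths


def save_matrices(path: str | Path, **matrices: np.ndarray) -> None:
    """Write named matrices (R, F, V, Z, P, ...) to one HDF5 file."""
    with h5py.File(Path(path), "w") as f:
        for name, arr in matrices.items():
            f.create_dataset(name, data=np.asarray(arr))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
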