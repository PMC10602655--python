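"""HDF5 / CSV persistence for recordings, matrices and feature tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bands import get_band
from .connectivity import ConnectivityMatrix
from .layout import ChannelLayout
from .synth import Recording, SyntheticDataset


def save_dataset(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write a dataset to one HDF5 container plus a manifest CSV.

    Layout: one group per subject holding ``data`` (channels x samples,
    float32) with attributes fs, group, seed; channel labels at the root.
    The manifest CSV is written next to the container.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        first = dataset.recordings[0]
        f.attrs["epoch_duration_s"] = dataset.epoch_duration_s
        f.create_dataset("channels", data=np.array(first.layout.labels, dtype="S"))
        f.create_dataset(
            "regions",
            data=np.array([first.layout.region_map[l] for l in first.layout.labels],
                          dtype="S"))
        for rec in dataset.recordings:
            g = f.create_group(rec.subject_id)
            d = g.create_dataset("data", data=rec.data.astype(np.float32))
            d.attrs["fs"] = rec.fs
            d.attrs["group"] = rec.group_label
            d.attrs["seed"] = rec.seed
    dataset.manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_dataset(path: str | Path) -> SyntheticDataset:
    path = Path(path)
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    recordings = []
    with h5py.File(path, "r") as f:
        labels = tuple(s.decode() for s in f["channels"][()])
        regions = tuple(s.decode() for s in f["regions"][()])
        layout = ChannelLayout(labels=labels,
                               region_map=dict(zip(labels, regions)))
        epoch_duration = float(f.attrs["epoch_duration_s"])
        for sid in manifest["subject_id"]:
            d = f[sid]["data"]
            recordings.append(Recording(
                data=d[()], fs=float(d.attrs["fs"]), layout=layout,
                group_label=str(d.attrs["group"]), subject_id=sid,
                seed=int(d.attrs["seed"]),
            ))
    return SyntheticDataset(tuple(recordings), manifest, epoch_duration)


def save_matrices(mats: list[ConnectivityMatrix], table: pd.DataFrame,
                  path: str | Path) -> None:
    """Write per-epoch connectivity matrices to HDF5 with provenance attrs."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, m in enumerate(mats):
            d = f.create_dataset(f"epoch_{i:06d}", data=m.values)
            d.attrs["method"] = m.method
            d.attrs["band"] = m.band.name
            d.attrs["subject"] = m.epoch_ref[0]
            d.attrs["epoch"] = m.epoch_ref[1]
            if m.threshold_provenance is not None:
                d.attrs["threshold_mode"] = m.threshold_provenance.mode
                d.attrs["threshold_value"] = m.threshold_provenance.value
    table.to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_matrices(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    path = Path(path)
    table = pd.read_csv(path.with_suffix(".manifest.csv"))
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("epoch_"))
        x = np.stack([f[k][()] for k in keys])
        band = get_band(f[keys[0]].attrs["band"])  # consistency check
        assert all(f[k].attrs["band"] == band.name for k in keys)
    return x, table


def save_feature_table(features: np.ndarray, table: pd.DataFrame,
                       names: list[str], path: str | Path) -> None:
    """Tidy CSV: subject, epoch, group, then one column per feature."""
    df = pd.concat(
        [table.reset_index(drop=True),
         pd.DataFrame(features, columns=names)], axis=1)
    df.to_csv(path, index=False)


def save_spectrogram_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] spectrogram image as 8-bit grayscale PNG
    (low frequencies at the bottom)."""
    from PIL import Image
    img8 = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img8[::-1], mode="L").save(Path(path))
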