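"""File-format helpers: float-TIFF image sets with CSV manifests and YAML
provenance, HDF5 movies/traces, CSV schedules and logs."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .stimuli import ImageSet, StimulusImage
from .synth import TrialSchedule

__all__ = [
    "save_image_set",
    "load_image_set",
    "save_movie_h5",
    "load_movie_h5",
    "save_traces_h5",
    "load_traces_h5",
    "save_schedule_csv",
    "load_schedule_csv",
]


def save_image_set(imgs: ImageSet, directory) -> pathlib.Path:
    """Write images as float TIFF plus a CSV manifest and YAML provenance."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in imgs:
        name = f"{im.family}_{im.stim_class}_e{im.exemplar_id:03d}_r{im.rotation_deg}.tiff"
        tifffile.imwrite(d / name, im.pixels.astype(np.float32))
        rows.append(
            dict(
                path=name, family=im.family, stim_class=im.stim_class,
                exemplar_id=im.exemplar_id, rotation_deg=im.rotation_deg,
                pixels_per_degree=im.pixels_per_degree,
            )
        )
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
    with open(d / "provenance.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(imgs.provenance), fh)
    return d


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_image_set(directory) -> ImageSet:
    d = pathlib.Path(directory)
    manifest = pd.read_csv(d / "manifest.csv")
    prov = {}
    if (d / "provenance.yaml").exists():
        with open(d / "provenance.yaml") as fh:
            prov = yaml.safe_load(fh) or {}
    images = [
        StimulusImage(
            pixels=tifffile.imread(d / r.path).astype(float),
            family=r.family,
            stim_class=r.stim_class,
            exemplar_id=int(r.exemplar_id),
            rotation_deg=int(r.rotation_deg),
            pixels_per_degree=float(r.pixels_per_degree),
        )
        for r in manifest.itertuples(index=False)
    ]
    return ImageSet(images, provenance=prov)


def save_movie_h5(path, rate_hz: float, **channels) -> None:
    """Store named frame-stack datasets plus the frame rate attribute."""
    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = rate_hz
        for name, data in channels.items():
            f.create_dataset(name, data=np.asarray(data), compression="gzip")


def load_movie_h5(path) -> tuple[dict, float]:
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate_hz"])
        return {k: f[k][()] for k in f.keys()}, rate


def save_traces_h5(path, soma: np.ndarray, neuropil: np.ndarray, rate_hz: float) -> None:
    save_movie_h5(path, rate_hz, soma=soma, neuropil=neuropil)


def load_traces_h5(path):
    data, rate = load_movie_h5(path)
    return data["soma"], data["neuropil"], rate


def save_schedule_csv(schedule: TrialSchedule, path) -> None:
    df = schedule.trials.copy()
    df.attrs = {}
    df.to_csv(path, index=False)
    meta = pathlib.Path(path).with_suffix(".yaml")
    with open(meta, "w") as fh:
        yaml.safe_dump(
            dict(stim_ms=schedule.stim_ms, iti_ms=schedule.iti_ms, lead_s=schedule.lead_s), fh
        )


def load_schedule_csv(path) -> TrialSchedule:
    df = pd.read_csv(path, keep_default_na=False)
    df["is_blank"] = df.is_blank.astype(bool)
    meta = pathlib.Path(path).with_suffix(".yaml")
    kw = {}
    if meta.exists():
        with open(meta) as fh:
            kw = yaml.safe_load(fh) or {}
    return TrialSchedule(trials=df, **kw)
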