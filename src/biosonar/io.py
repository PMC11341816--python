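"""On-disk artifacts: HDF5 datasets and images, WAV time series, YAML
configuration, PNG rendering, CSV results tables."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import yaml

from .forward import EchoDataset
from .processors import ProcessorOutput
from .scene import VoxelGrid

RENDER_PERCENTILES = (5.0, 99.5)


# ---------------------------------------------------------------------------
# HDF5 containers

def save_dataset(path, dataset: EchoDataset) -> None:
    """Persist an EchoDataset with named dimensions and provenance attrs."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=dataset.data)
        d.attrs["dims"] = "sensor,frequency,click"
        f.create_dataset("freqs", data=dataset.freqs)
        f.create_dataset("valid", data=dataset.valid)
        f.attrs["mode"] = dataset.mode
        f.attrs["meta"] = json.dumps(dataset.meta, default=str)
        f.attrs["format"] = "biosonar-echodataset-v1"


def load_dataset(path) -> EchoDataset:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "biosonar-echodataset-v1":
            raise ValueError("not a biosonar EchoDataset file")
        return EchoDataset(f["data"][()], f["freqs"][()],
                           str(f.attrs["mode"]), valid=f["valid"][()],
                           meta=json.loads(f.attrs.get("meta", "{}")))


def save_output(path, output: ProcessorOutput) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("h", data=output.h)
        f.attrs["processor"] = output.processor
        f.attrs["mode"] = output.mode
        f.attrs["diagnostics"] = json.dumps(output.diagnostics, default=str)
        grp = f.create_group("per_click")
        for k, g in enumerate(output.per_click):
            grp.create_dataset(str(k), data=np.asarray(g))
        f.attrs["format"] = "biosonar-output-v1"


def load_output(path) -> ProcessorOutput:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "biosonar-output-v1":
            raise ValueError("not a biosonar ProcessorOutput file")
        per_click = [f["per_click"][k][()]
                     for k in sorted(f["per_click"], key=int)]
        return ProcessorOutput(f["h"][()], str(f.attrs["processor"]),
                               str(f.attrs["mode"]), per_click,
                               json.loads(f.attrs["diagnostics"]))


def _h5_structure(path) -> list[str]:
    lines: list[str] = []
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            kind = "group" if isinstance(obj, h5py.Group) else \
                f"dataset {getattr(obj, 'shape', '?')} {getattr(obj, 'dtype', '')}"
            lines.append(f"/{name}: {kind}")
        f.visititems(visit)
        lines.extend(f"attr {k}={f.attrs[k]!r}" for k in f.attrs)
    return lines


def load_processed_dataset(path) -> EchoDataset:
    """Loader stub for deposited processed acoustic data.

    Recognizes this package's own HDF5 layout; any other layout raises an
    error that lists the structure actually found (no silent guessing), so
    an adapter can be written against the real archive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ds = load_dataset(path)
    except (OSError, ValueError) as exc:
        try:
            structure = _h5_structure(path)
        except OSError:
            raise ValueError(
                f"{path} is not an HDF5 file; cannot map it to an "
                "EchoDataset") from exc
        raise ValueError(
            "unrecognized processed-data layout; detected structure:\n  "
            + "\n  ".join(structure)) from exc
    print(f"loaded EchoDataset: M={ds.n_sensors} F={ds.n_freqs} "
          f"K={ds.n_clicks}")
    return ds


# ---------------------------------------------------------------------------
# WAV time series

def write_wav(path, ts: np.ndarray, sample_rate: float) -> None:
    """Write an (M, T) float time series as multichannel 32-bit float WAV."""
    from scipy.io import wavfile
    ts = np.atleast_2d(np.asarray(ts, np.float32))
    wavfile.write(path, int(sample_rate), ts.T.copy())


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile
    rate, data = wavfile.read(path)
    data = np.atleast_2d(np.asarray(data, float).T)
    return data, float(rate)


# ---------------------------------------------------------------------------
# Rendering

def render(h: np.ndarray, grid: VoxelGrid, out_path,
           title: str | None = None) -> tuple[float, float]:
    """Render an image with colour limits at the 5th / 99.5th percentiles
    of the voxel values; returns the limits used.  A constant image falls
    back to its full (degenerate) range with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    hv = np.asarray(h, float).ravel()
    lo, hi = np.percentile(hv, RENDER_PERCENTILES)
    if lo == hi:
        warnings.warn("constant image: percentile colour limits degenerate; "
                      "using full range")
        lo, hi = float(hv.min()), float(hv.max() + 1e-12)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(hv.reshape(grid.image_shape()), origin="lower",
                   extent=(grid.x_min, grid.x_max, grid.y_min, grid.y_max),
                   vmin=lo, vmax=hi, cmap="inferno")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return float(lo), float(hi)


def export_mask_csv(path, mask) -> None:
    """Shape mask as CSV rows (index, x, y, value)."""
    import pandas as pd
    grid = mask.grid
    idx = np.arange(grid.n_voxels)
    x, y = grid.index_to_xy(idx)
    pd.DataFrame({"index": idx, "x": x, "y": y,
                  "value": mask.values}).to_csv(path, index=False)


def append_results_csv(path, record: dict) -> None:
    """Append one discrimination record to a results table
    (columns: dataset_id, sample, R_bartlett, R_sa)."""
    import pandas as pd
    path = Path(path)
    df = pd.DataFrame([record])
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Serializable run configuration; unknown keys are rejected."""

    scene: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def log_effective(self) -> str:
        """Every effective value, printed into run logs for provenance."""
        return yaml.safe_dump(self.__dict__, sort_keys=True)
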