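"""Reading and writing image sequences and ground truth."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .feedforward import ImageSequence
from .synthetic import SequenceBundle

__all__ = ["load_sequence", "save_bundle", "load_truth"]

_STACK_EXTS = (".png", ".tif", ".tiff")


def _to_luminance(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3:  # RGB(A) -> ITU-R 601 luma
        arr = (
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        )
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_sequence(path, fs: float) -> ImageSequence:
    """Load a frame-stack directory (PNG/TIFF, lexicographic order) or video."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in _STACK_EXTS
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {p}")
        frames = np.stack([_to_luminance(iio.imread(f)) for f in files])
    elif p.is_file():
        frames = np.stack([_to_luminance(fr) for fr in iio.imiter(p)])
    else:
        raise FileNotFoundError(f"input path {p} does not exist")
    return ImageSequence(frames=frames, fs=fs)


def save_bundle(bundle: SequenceBundle, out_dir) -> Path:
    """Write a bundle as a PNG stack + ground_truth.csv + generation YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = (bundle.seq.frames * 255).round().astype(np.uint8)
    for t in range(frames.shape[0]):
        iio.imwrite(out / f"frame_{t:05d}.png", frames[t])
    bundle.truth_frame().to_csv(out / "ground_truth.csv", index=False)
    meta = dict(bundle.meta)
    meta["fs"] = float(bundle.seq.fs)
    with open(out / "generation.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, default_flow_style=True)
    return out


def load_truth(csv_path) -> np.ndarray:
    """Read a ground_truth.csv into the (n_frames, n_targets, 2) array."""
    df = pd.read_csv(csv_path)
    T = int(df["frame"].max()) + 1
    K = int(df["target_id"].max()) + 1
    truth = np.full((T, K, 2), np.nan)
    truth[df["frame"], df["target_id"], 0] = df["x"]
    truth[df["frame"], df["target_id"], 1] = df["y"]
    return truth
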