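"""File I/O: multi-page 16-bit TIFF stacks and commented CSV tables.

Stacks are written one page per measuring round with the frame timestamp
stored as JSON in the page description tag. CSV tables carry ``#``-prefixed
metadata lines (protocol echo, config hash) above the header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from chlorokin.synthgen import SATURATION_VALUE, FrameStack


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a stack as a multi-page 16-bit grayscale TIFF with timestamps."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for frame, t in zip(stack.data, stack.timestamps_min):
            tif.write(
                frame.astype(np.uint16),
                description=json.dumps({"time_min": float(t)}),
                contiguous=False,
            )


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Pages without a timestamp tag fall back to consecutive 2-min spacing.
    """
    path = Path(path)
    frames, times = [], []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            frames.append(page.asarray())
            t = None
            desc = page.description
            if desc:
                try:
                    t = json.loads(desc).get("time_min")
                except (json.JSONDecodeError, AttributeError):
                    t = None
            times.append(float(t) if t is not None else i * 2.0)
    return FrameStack(
        data=np.stack(frames).astype(np.uint16),
        timestamps_min=np.asarray(times, dtype=float),
        saturation_value=SATURATION_VALUE,
    )


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_table(path: str | Path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a CSV with ``#`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV, skipping ``#`` metadata lines."""
    return pd.read_csv(Path(path), comment="#")
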