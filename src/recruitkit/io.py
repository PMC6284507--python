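"""Reading/writing image stacks and trace tables; split-view channel handling.

Split-view acquisition places the two emission colours on two halves of
one camera frame in the same exposure.  ``split_channels`` cuts a stack
into its two halves and applies the fixed integer-pixel offset between
them (a per-hardware-session constant, estimated once with
``estimate_split_offset`` or supplied manually in the configuration).
Registration is integer-pixel by design: the medMax damage statistic is
robust to sub-pixel misalignment at this scale.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionMeta, TimeLapseMovie

TRACE_COLUMNS = [
    "cell_id",
    "channel",
    "frame",
    "time_s",
    "raw_medmax",
    "nucleus_mean",
    "corrected",
    "rfi",
    "fmr",
]


def read_movie(
    path: str | Path, meta: AcquisitionMeta, channel_label: str = ""
) -> TimeLapseMovie:
    """Read a multi-page TIFF / OME-TIFF stack as one channel.

    Stored integer samples are promoted to float64 bit-exactly
    (8/16-bit unsigned and 32-bit float are all exactly representable).
    """
    try:
        frames = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise ValueError(f"unreadable TIFF stack: {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"too few frames in {path}: need at least 2 pages")
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a T×H×W grayscale stack, got shape {frames.shape}")
    return TimeLapseMovie(frames.astype(np.float64), meta, channel_label)


def write_movie(movie: TimeLapseMovie, path: str | Path, dtype=np.float32) -> None:
    """Write a stack as a multi-page TIFF (float32 by default)."""
    tifffile.imwrite(str(path), movie.frames.astype(dtype))


def translate_frames(frames: np.ndarray, dx: int, dy: int, fill: float = 0.0) -> np.ndarray:
    """Integer-pixel translation of a T×H×W stack; vacated pixels get ``fill``."""
    T, h, w = frames.shape
    out = np.full_like(frames, fill)
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[:, ys_dst, xs_dst] = frames[:, ys_src, xs_src]
    return out


def _halves(frames: np.ndarray, layout: str) -> tuple[np.ndarray, np.ndarray]:
    if layout not in ("left-right", "top-bottom"):
        raise ValueError("layout must be 'left-right' or 'top-bottom'")
    axis = 2 if layout == "left-right" else 1
    dim = frames.shape[axis]
    half = dim // 2
    if dim % 2:
        warnings.warn(
            f"odd split dimension {dim}: dropping the last "
            f"{'column' if axis == 2 else 'row'} of the larger half",
            stacklevel=3,
        )
    if axis == 2:
        return frames[:, :, :half], frames[:, :, half : 2 * half]
    return frames[:, :half, :], frames[:, half : 2 * half, :]


def split_channels(
    movie: TimeLapseMovie,
    layout: str = "left-right",
    offset: tuple[int, int] = (0, 0),
    labels: tuple[str, str] = ("green", "red"),
) -> tuple[TimeLapseMovie, TimeLapseMovie]:
    """Split a split-view stack into two aligned channel stacks.

    ``offset = (dx, dy)`` is the position of second-half content
    relative to the first half: a feature at (x, y) in the first half
    appears at (x + dx, y + dy) in the second.  The second half is
    translated by (−dx, −dy) so homologous pixels align; both outputs
    share the first half's shape and the input metadata.
    """
    dx, dy = int(offset[0]), int(offset[1])
    first, second = _halves(movie.frames, layout)
    _, h, w = first.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"offset {offset} exceeds half-frame size {(w, h)}")
    aligned = translate_frames(second, -dx, -dy)
    return (
        TimeLapseMovie(first, movie.meta, labels[0]),
        TimeLapseMovie(np.clip(aligned, 0.0, None), movie.meta, labels[1]),
    )


def compose_splitview(
    first: TimeLapseMovie,
    second: TimeLapseMovie,
    layout: str = "left-right",
    offset: tuple[int, int] = (0, 0),
) -> TimeLapseMovie:
    """Inverse of :func:`split_channels` (up to border fill): place the
    second channel, translated by ``offset``, next to the first."""
    if first.frames.shape != second.frames.shape:
        raise ValueError("both channels must share shape")
    dx, dy = int(offset[0]), int(offset[1])
    moved = translate_frames(second.frames, dx, dy)
    axis = 2 if layout == "left-right" else 1
    return TimeLapseMovie(
        np.concatenate([first.frames, moved], axis=axis), first.meta, "split-view"
    )


def estimate_split_offset(
    movie: TimeLapseMovie,
    layout: str = "left-right",
    reference_frame: int = 0,
    max_shift: int = 10,
) -> tuple[int, int]:
    """Integer offset of the second half-image relative to the first.

    Exhaustive search over shifts in ±max_shift maximizing the Pearson
    (normalized cross-) correlation on the overlap of a pre-damage
    reference frame.  Ties are broken toward the smaller |shift|, then
    smaller dx, then smaller dy.
    """
    if reference_frame >= movie.meta.damage_frame:
        raise ValueError("reference_frame must be a pre-damage frame")
    first, second = _halves(movie.frames[reference_frame : reference_frame + 1], layout)
    a, b = first[0], second[0]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant half-images: split offset is undefined")
    h, w = a.shape
    candidates: list[tuple[float, int, int]] = []
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # hypothesis: b[y + dy, x + dx] == a[y, x]
            ys = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, -dx), min(w, w - dx))
            av = a[ys, xs].ravel()
            bv = b[ys.start + dy : ys.stop + dy, xs.start + dx : xs.stop + dx].ravel()
            if av.size < 16 or av.std() == 0 or bv.std() == 0:
                continue
            r = float(np.corrcoef(av, bv)[0, 1])
            candidates.append((r, dx, dy))
    if not candidates:
        raise ValueError("no valid overlap for any shift")
    rmax = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] >= rmax - 1e-12]
    _, dx, dy = min(tied, key=lambda c: (c[1] ** 2 + c[2] ** 2, c[1], c[2]))
    return dx, dy


def write_traces(records, path: str | Path) -> pd.DataFrame:
    """Write per-cell/channel traces as one long-format CSV.

    Columns: cell_id, channel, frame, time_s, raw_medmax, nucleus_mean,
    corrected, rfi, fmr.  Numbers are written with 17 significant digits
    so a read-back reproduces them exactly.
    """
    rows = []
    n_frames = None
    interval = None
    for rec in records:
        for channel in ("green", "red"):
            trace = rec.trace(channel)
            curve = rec.curve(channel)
            T = len(trace.time_s)
            if n_frames is None:
                n_frames, interval = T, trace.meta.frame_interval
            elif T != n_frames or trace.meta.frame_interval != interval:
                raise ValueError("all records must share frame count and interval")
            fmr_col = (
                curve.fmr if curve is not None and curve.fmr is not None else np.full(T, np.nan)
            )
            rfi_col = curve.rfi if curve is not None else np.full(T, np.nan)
            corrected = (
                trace.corrected if trace.corrected is not None else np.full(T, np.nan)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": rec.cell_id,
                        "channel": channel,
                        "frame": np.arange(T),
                        "time_s": trace.time_s,
                        "raw_medmax": trace.raw_medmax,
                        "nucleus_mean": trace.nucleus_mean,
                        "corrected": corrected,
                        "rfi": rfi_col,
                        "fmr": fmr_col,
                    }
                )
            )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    table.to_csv(path, index=False, float_format="%.17g")
    return table


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a traces CSV written by :func:`write_traces` (exact round-trip)."""
    return pd.read_csv(path, float_precision="round_trip")
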