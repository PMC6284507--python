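"""Cell-level QC and population analyses.

Covers the population stages of the workflow: intensity-range quality
control (bleed-through minimization), rank clustering by final FMR,
heatmap row ordering, initial-intensity / nuclear-size / cross-channel
regressions against kinetics, dual-channel FMR-ratio series, and
mean ± SEM summary curves.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .traces import IntensityTrace, RecruitmentCurve


@dataclasses.dataclass
class CellRecord:
    """Paired green/red traces and curves for one cell.

    ``i0_raw_green`` / ``i0_raw_red`` are pre-damage nucleus means on the
    unfiltered frames — the camera-count scale on which the QC intensity
    ranges (e.g. GFP 140–200, RFP 200–400) are defined.  The curves' own
    ``i0`` is the corrected (filtered, bleach-divided) pre-damage level
    used for RFI normalization.
    """

    cell_id: str
    green_trace: IntensityTrace
    red_trace: IntensityTrace
    green_curve: RecruitmentCurve | None
    red_curve: RecruitmentCurve | None
    i0_raw_green: float
    i0_raw_red: float
    nucleus_area_px: int
    nucleus_area_um2: float
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if len(self.green_trace.time_s) != len(self.red_trace.time_s):
            raise ValueError("green and red traces must share frame count")

    def trace(self, channel: str) -> IntensityTrace:
        return {"green": self.green_trace, "red": self.red_trace}[channel]

    def curve(self, channel: str) -> RecruitmentCurve | None:
        return {"green": self.green_curve, "red": self.red_curve}[channel]


@dataclasses.dataclass
class Cluster:
    """One rank cluster: members and their final-FMR range."""

    label: int
    cell_ids: list[str]
    fmr_range: tuple[float, float]


@dataclasses.dataclass
class PopulationResult:
    """Collected population outputs (filled by the analysis pipeline)."""

    clusters: dict[str, list[Cluster]] = dataclasses.field(default_factory=dict)
    heatmap_order: dict[str, list[int]] = dataclasses.field(default_factory=dict)
    regressions: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=dict
    )
    mean_sem: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=dict
    )
    ratio: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def qc_filter(
    cells: list[CellRecord],
    green_range: tuple[float, float] = (140.0, 200.0),
    red_range: tuple[float, float] = (200.0, 400.0),
    require_red_gt_green: bool = True,
) -> tuple[list[CellRecord], list[tuple[CellRecord, str]]]:
    """Select cells inside the per-channel initial-intensity ranges.

    The red-above-green requirement keeps green→red bleed-through small
    relative to the red signal.  Returns (passing, failing-with-reason);
    the records' ``qc_pass``/``qc_reason`` fields are updated in place.
    """
    passing: list[CellRecord] = []
    failing: list[tuple[CellRecord, str]] = []
    for cell in cells:
        reasons = []
        if not (green_range[0] <= cell.i0_raw_green <= green_range[1]):
            reasons.append("green i0 out of range")
        if not (red_range[0] <= cell.i0_raw_red <= red_range[1]):
            reasons.append("red i0 out of range")
        if require_red_gt_green and not (cell.i0_raw_red > cell.i0_raw_green):
            reasons.append("red i0 <= green i0")
        cell.qc_pass = not reasons
        cell.qc_reason = "; ".join(reasons)
        if cell.qc_pass:
            passing.append(cell)
        else:
            failing.append((cell, cell.qc_reason))
    return passing, failing


def _final_fmr(cell: CellRecord, channel: str) -> float | None:
    curve = cell.curve(channel)
    if curve is None or curve.final_fmr is None:
        return None
    return curve.final_fmr


def cluster_by_final_fmr(
    cells: list[CellRecord], channel: str = "green", k: int = 4
) -> list[Cluster]:
    """Split cells into ``k`` equally sized rank clusters by final FMR.

    Cells are sorted by final FMR descending and cut into contiguous
    rank groups whose sizes differ by at most one (larger groups first).
    """
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    defined = [(c, _final_fmr(c, channel)) for c in cells]
    defined = [(c, f) for c, f in defined if f is not None]
    if len(defined) < k:
        raise ValueError(f"need at least k={k} cells with defined final FMR")
    defined.sort(key=lambda cf: (-cf[1], cf[0].cell_id))
    n = len(defined)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    clusters = []
    start = 0
    for label, size in enumerate(sizes, start=1):
        members = defined[start : start + size]
        start += size
        values = [f for _, f in members]
        clusters.append(
            Cluster(
                label=label,
                cell_ids=[c.cell_id for c, _ in members],
                fmr_range=(min(values), max(values)),
            )
        )
    return clusters


def heatmap_order(
    cells: list[CellRecord],
    channel: str = "green",
    window: tuple[int, int] = (15, 150),
    descending: bool = True,
) -> list[int]:
    """Row order for FMR heatmaps: by mean FMR over a frame window.

    ``window`` is an inclusive pair of frame indices (default 15–150);
    it is clamped to the series length with a warning.  Ties keep the
    cell_id order (stable).  Returns a permutation of cell indices.
    """
    curves = [cells[i].curve(channel) for i in range(len(cells))]
    if any(c is None or c.fmr is None for c in curves):
        raise ValueError("all cells need a defined FMR curve for heatmap ordering")
    T = len(curves[0].fmr)  # type: ignore[union-attr]
    lo, hi = window
    if lo < 0 or hi >= T:
        lo, hi = max(lo, 0), min(hi, T - 1)
        warnings.warn(f"heatmap window clamped to frames {lo}-{hi}", stacklevel=2)
    if hi < lo:
        raise ValueError("empty heatmap window after clamping")
    means = [float(np.asarray(c.fmr)[lo : hi + 1].mean()) for c in curves]  # type: ignore[union-attr]
    order = sorted(
        range(len(cells)),
        key=lambda i: ((-means[i] if descending else means[i]), cells[i].cell_id),
    )
    return order


def fit_linear(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope·x + intercept with R².

    R² = 1 − SS_res/SS_tot; for a constant-y input R² is defined as 0.
    Requires n ≥ 3 and non-constant x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _scatter(
    xs: list[float | None], ys: list[float | None], ids: list[str]
) -> tuple[tuple[float, float, float], pd.DataFrame, int]:
    table = pd.DataFrame({"cell_id": ids, "x": xs, "y": ys})
    valid = table.dropna()
    n_excluded = len(table) - len(valid)
    if len(valid) < 3:
        raise ValueError("fewer than 3 cells with defined values")
    fit = fit_linear(valid["x"].to_numpy(), valid["y"].to_numpy())
    return fit, valid.reset_index(drop=True), n_excluded


def _kinetic_value(cell: CellRecord, channel: str, quantity: str) -> float | None:
    curve = cell.curve(channel)
    if curve is None:
        return None
    return {"t50": curve.t50, "final_fmr": curve.final_fmr, "t_max": curve.t_max}[
        quantity
    ]


def intensity_kinetics_scatter(
    cells: list[CellRecord], channel: str, y: str = "t50", x_source: str = "raw"
) -> tuple[tuple[float, float, float], pd.DataFrame, int]:
    """Initial intensity vs a kinetic scalar (t50 or final FMR) per cell.

    Cells with an undefined kinetic value are excluded listwise and
    counted in the returned exclusion count.
    """
    xs = [
        (cell.i0_raw_green if channel == "green" else cell.i0_raw_red)
        if x_source == "raw"
        else (cell.curve(channel).i0 if cell.curve(channel) else None)
        for cell in cells
    ]
    ys = [_kinetic_value(c, channel, y) for c in cells]
    return _scatter(xs, ys, [c.cell_id for c in cells])


def cross_correlation_scatter(
    cells: list[CellRecord],
    x_channel: str = "green",
    y_channel: str = "red",
    y: str = "t50",
    cells_y: list[CellRecord] | None = None,
) -> tuple[tuple[float, float, float], pd.DataFrame, int]:
    """Initial intensity of one channel vs the kinetics of the other.

    With a second record list the two sets are paired by cell_id and a
    mismatch is an error.
    """
    if cells_y is None:
        cells_y = cells
    if [c.cell_id for c in cells] != [c.cell_id for c in cells_y]:
        raise ValueError("mismatched cell sets for cross-correlation")
    xs = [
        c.i0_raw_green if x_channel == "green" else c.i0_raw_red for c in cells
    ]
    ys = [_kinetic_value(c, y_channel, y) for c in cells_y]
    return _scatter(list(xs), ys, [c.cell_id for c in cells])


def nuclear_size_scatter(
    cells: list[CellRecord], channel: str, y: str = "t50"
) -> tuple[tuple[float, float, float], pd.DataFrame, int]:
    """Nucleus area (µm²) vs a kinetic scalar per cell."""
    xs = [float(c.nucleus_area_um2) for c in cells]
    ys = [_kinetic_value(c, channel, y) for c in cells]
    return _scatter(xs, ys, [c.cell_id for c in cells])


def fmr_ratio(
    cells: list[CellRecord],
    numerator: str = "red",
    denominator: str = "green",
    start: int = 1,
    delta: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame mean ± SEM of the per-cell FMR ratio between channels.

    Frames earlier than ``start`` frames after damage, or where the
    denominator FMR is below ``delta``, are masked per cell: before
    recruitment both FMRs hover near 0 and the ratio is pure noise.
    Returns (masked n_cells×T ratio matrix, mean, sem, n per frame).
    """
    if start < 1:
        raise ValueError("start must be >= 1 frame after damage")
    usable = [
        c
        for c in cells
        if c.curve(numerator) is not None
        and c.curve(denominator) is not None
        and c.curve(numerator).fmr is not None  # type: ignore[union-attr]
        and c.curve(denominator).fmr is not None  # type: ignore[union-attr]
    ]
    if not usable:
        raise ValueError("no cells with defined FMR in both channels")
    T = len(usable[0].curve(numerator).fmr)  # type: ignore[union-attr]
    damage = usable[0].green_trace.meta.damage_frame
    ratios = np.full((len(usable), T), np.nan)
    for i, cell in enumerate(usable):
        num = np.asarray(cell.curve(numerator).fmr)  # type: ignore[union-attr]
        den = np.asarray(cell.curve(denominator).fmr)  # type: ignore[union-attr]
        ok = np.zeros(T, dtype=bool)
        ok[damage + start :] = den[damage + start :] >= delta
        ratios[i, ok] = num[ok] / den[ok]
    n = np.sum(~np.isnan(ratios), axis=0)
    if n.max() == 0:
        raise ValueError("denominator FMR below threshold everywhere")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        mean = np.nanmean(ratios, axis=0)
        sd = np.nanstd(ratios, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return ratios, mean, sem, n


def mean_sem_curves(
    cells: list[CellRecord], channel: str, quantity: str = "rfi"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame mean, SEM (sd/√n, ddof=1) and n over defined curves."""
    series = []
    for cell in cells:
        curve = cell.curve(channel)
        if curve is None:
            continue
        values = curve.rfi if quantity == "rfi" else curve.fmr
        if values is not None:
            series.append(np.asarray(values, dtype=np.float64))
    if not series:
        raise ValueError("no defined curves to average")
    data = np.vstack(series)
    n = np.full(data.shape[1], data.shape[0])
    mean = data.mean(axis=0)
    if data.shape[0] > 1:
        sem = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
    else:
        sem = np.full(data.shape[1], np.nan)
    return mean, sem, n


def t50_scatter(cells: list[CellRecord]) -> tuple[pd.DataFrame, int]:
    """Paired (green t50, red t50) table; pairs with an undefined t50
    are excluded and counted."""
    rows = []
    excluded = 0
    for cell in cells:
        tg = cell.green_curve.t50 if cell.green_curve else None
        tr = cell.red_curve.t50 if cell.red_curve else None
        if tg is None or tr is None:
            excluded += 1
            continue
        rows.append({"cell_id": cell.cell_id, "t50_green": tg, "t50_red": tr})
    return pd.DataFrame(rows, columns=["cell_id", "t50_green", "t50_red"]), excluded
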